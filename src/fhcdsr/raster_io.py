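"""Read/write hyperspectral cubes and change masks; band-exclusion preprocessing.

Supported containers
--------------------
* ENVI raster: a ``.hdr`` text header plus a flat binary file, honouring the
  ``samples``/``lines``/``bands``, ``interleave`` (bsq/bil/bip), ``data type``,
  ``byte order`` and ``header offset`` keys.
* GeoTIFF via :mod:`tifffile` (band axis located from the TIFF series axes).
* MATLAB MAT-files: v5 via :func:`scipy.io.loadmat`, HDF5-based v7.3 via
  :mod:`h5py` (MATLAB stores arrays column-major, so v7.3 payloads are
  transposed back to ``(row, col, band)``).
* Masks additionally as single-band PNG.

All readers return ``(row, col, band)`` double-precision arrays regardless of
the on-disk interleave or container.  Values are never rescaled; NaNs are
rejected at load rather than imputed.
"""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .cube import ChangeMask, HyperCube

__all__ = [
    "exclude_bands",
    "parse_band_ranges",
    "read_cube",
    "read_mask",
    "write_cube",
    "write_mask",
]

# ENVI numeric codes for the dtypes this reader supports.
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
    15: np.uint64,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_ENVI_DATA_EXTENSIONS = ("", ".img", ".dat", ".raw", ".bsq", ".bil", ".bip", ".bin")


def _parse_envi_header(path: Path) -> dict[str, str]:
    text = path.read_text()
    header: dict[str, str] = {}
    # "key = value" lines; brace-delimited values may span lines.
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE | re.DOTALL)
    for match in pattern.finditer(text):
        key = match.group(1).strip().lower()
        value = match.group(2).strip()
        if value.startswith("{"):
            value = value[1:-1].strip() if value.endswith("}") else value[1:].strip()
        header[key] = value
    return header


def _envi_paths(path: Path) -> tuple[Path, Path]:
    """Resolve (header, data) paths from either the .hdr or the data file."""
    if path.suffix.lower() == ".hdr":
        hdr = path
        candidates = [path.with_suffix("")]
        candidates += [path.with_suffix(ext) for ext in _ENVI_DATA_EXTENSIONS if ext]
        for cand in candidates:
            if cand.exists() and cand != hdr:
                return hdr, cand
        raise FileNotFoundError(f"no ENVI data file found alongside header {path}")
    hdr = path.with_suffix(path.suffix + ".hdr")
    if not hdr.exists():
        hdr = path.with_suffix(".hdr")
    if not hdr.exists():
        raise FileNotFoundError(f"no ENVI header (.hdr) found for {path}")
    return hdr, path


def _read_envi(path: Path) -> np.ndarray:
    hdr_path, data_path = _envi_paths(path)
    header = _parse_envi_header(hdr_path)
    try:
        samples = int(header["samples"])
        lines = int(header["lines"])
        bands = int(header["bands"])
        dtype_code = int(header["data type"])
    except KeyError as exc:
        raise ValueError(f"ENVI header {hdr_path} is missing required key {exc}") from exc
    interleave = header.get("interleave", "bsq").strip().lower()
    byte_order = int(header.get("byte order", "0"))
    offset = int(header.get("header offset", "0"))
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("big" if byte_order else "little")
    count = samples * lines * bands
    raw = np.fromfile(data_path, dtype=dtype, count=count, offset=offset)
    if raw.size != count:
        raise ValueError(
            f"ENVI data file {data_path} holds {raw.size} values, expected {count}"
        )
    if interleave == "bsq":
        arr = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        arr = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown ENVI interleave {interleave!r}")
    return np.ascontiguousarray(arr)


def _write_envi(path: Path, values: np.ndarray, interleave: str = "bsq") -> None:
    interleave = interleave.lower()
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[:, :, None]
    lines, samples, bands = values.shape
    dtype = values.dtype
    if dtype not in _ENVI_CODES:
        values = values.astype(np.float64)
        dtype = values.dtype
    if interleave == "bsq":
        flat = values.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = values.transpose(0, 2, 1)
    elif interleave == "bip":
        flat = values
    else:
        raise ValueError(f"unknown ENVI interleave {interleave!r}")
    data_path = path if path.suffix.lower() != ".hdr" else path.with_suffix(".img")
    np.ascontiguousarray(flat).tofile(data_path)
    hdr = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
    )
    Path(str(data_path) + ".hdr").write_text(hdr)


def _read_geotiff(path: Path) -> np.ndarray:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes
    if arr.ndim == 2:
        return arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError(f"GeoTIFF {path} holds a {arr.ndim}-D payload, expected 2-D or 3-D")
    # Move the non-spatial axis (pages or samples) to the back.
    try:
        y, x = axes.index("Y"), axes.index("X")
        band_axis = ({0, 1, 2} - {y, x}).pop()
        arr = np.moveaxis(arr, (y, x, band_axis), (0, 1, 2))
    except ValueError:
        # Axes metadata absent: assume band-first pages.
        arr = np.moveaxis(arr, 0, 2)
    return np.ascontiguousarray(arr)


def _write_geotiff(path: Path, values: np.ndarray) -> None:
    import tifffile

    values = np.asarray(values)
    if values.ndim == 3:
        values = np.ascontiguousarray(values.transpose(2, 0, 1))
    tifffile.imwrite(str(path), values, photometric="minisblack")


def _mat_candidates(path: Path, min_ndim: int, max_ndim: int) -> dict[str, np.ndarray]:
    import h5py

    if h5py.is_hdf5(str(path)):
        # MAT v7.3 is an HDF5 container; MATLAB stores arrays column-major,
        # so h5py sees the axes reversed.
        out: dict[str, np.ndarray] = {}
        with h5py.File(str(path), "r") as handle:
            for key, node in handle.items():
                if isinstance(node, h5py.Dataset) and min_ndim <= node.ndim <= max_ndim:
                    out[key] = np.asarray(node).transpose(tuple(range(node.ndim))[::-1])
        return out
    import scipy.io

    payload = scipy.io.loadmat(str(path))
    return {
        k: np.asarray(v)
        for k, v in payload.items()
        if not k.startswith("__")
        and isinstance(v, np.ndarray)
        and min_ndim <= v.ndim <= max_ndim
        and np.issubdtype(np.asarray(v).dtype, np.number)
    }


def _read_mat(path: Path, variable: str | None, ndim: int) -> np.ndarray:
    candidates = _mat_candidates(path, min_ndim=ndim, max_ndim=ndim)
    if variable is not None:
        if variable not in candidates:
            all_vars = _mat_candidates(path, min_ndim=1, max_ndim=10)
            if variable in all_vars:
                raise ValueError(
                    f"MAT variable {variable!r} in {path} is "
                    f"{all_vars[variable].ndim}-D, expected {ndim}-D"
                )
            raise KeyError(f"MAT variable {variable!r} not found in {path}")
        return candidates[variable]
    if not candidates:
        raise ValueError(f"no {ndim}-D numeric variable found in MAT file {path}")
    if len(candidates) > 1:
        names = ", ".join(sorted(candidates))
        raise ValueError(
            f"MAT file {path} holds multiple {ndim}-D candidates ({names}); "
            "pass mat_variable to disambiguate"
        )
    return next(iter(candidates.values()))


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix == ".mat":
        return "mat"
    if suffix == ".png":
        return "png"
    return "envi"


def read_cube(
    path: str | os.PathLike,
    format_hint: str = "auto",
    mat_variable: str | None = None,
) -> HyperCube:
    """Load a hyperspectral cube from ENVI, GeoTIFF or MAT containers.

    Returns a :class:`HyperCube` in ``(row, col, band)`` axis order regardless
    of the on-disk interleave, with values cast to double precision.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file does not exist: {path}")
    fmt = _detect_format(path) if format_hint == "auto" else format_hint
    if fmt == "envi":
        arr = _read_envi(path)
    elif fmt == "geotiff":
        arr = _read_geotiff(path)
    elif fmt == "mat":
        arr = _read_mat(path, mat_variable, ndim=3)
    else:
        raise ValueError(f"unknown cube format {fmt!r}")
    if arr.ndim != 3:
        raise ValueError(f"{path} holds a {arr.ndim}-D payload, expected a 3-D cube")
    return HyperCube(arr.astype(np.float64))


def write_cube(
    path: str | os.PathLike,
    cube: HyperCube,
    format_hint: str = "auto",
    interleave: str = "bsq",
    mat_variable: str = "cube",
) -> None:
    """Write a cube as ENVI (with the requested interleave), GeoTIFF or MAT v5."""
    path = Path(path)
    fmt = _detect_format(path) if format_hint == "auto" else format_hint
    if fmt == "envi":
        _write_envi(path, cube.values, interleave=interleave)
    elif fmt == "geotiff":
        _write_geotiff(path, cube.values)
    elif fmt == "mat":
        import scipy.io

        scipy.io.savemat(str(path), {mat_variable: cube.values})
    else:
        raise ValueError(f"unknown cube format {fmt!r}")


def read_mask(
    path: str | os.PathLike,
    format_hint: str = "auto",
    mat_variable: str | None = None,
) -> ChangeMask:
    """Load a binary change mask (nonzero entries map to 1) from a 2-D raster."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file does not exist: {path}")
    fmt = _detect_format(path) if format_hint == "auto" else format_hint
    if fmt == "png":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(str(path)))
        if arr.ndim == 3:  # collapse RGB(A) renderings of a binary map
            arr = arr[..., :3].max(axis=2)
    elif fmt == "geotiff":
        arr = _read_geotiff(path)
        arr = np.squeeze(arr, axis=2) if arr.shape[2] == 1 else arr
    elif fmt == "mat":
        arr = _read_mat(path, mat_variable, ndim=2)
    elif fmt == "envi":
        arr = _read_envi(path)
        arr = np.squeeze(arr, axis=2) if arr.shape[2] == 1 else arr
    else:
        raise ValueError(f"unknown mask format {fmt!r}")
    if arr.ndim != 2:
        raise ValueError(f"{path} holds a {arr.ndim}-D payload, expected a 2-D mask")
    return ChangeMask(arr)


def write_mask(path: str | os.PathLike, mask: ChangeMask, format_hint: str = "auto") -> None:
    path = Path(path)
    fmt = _detect_format(path) if format_hint == "auto" else format_hint
    labels = mask.labels.astype(np.uint8)
    if fmt == "png":
        import imageio.v3 as iio

        iio.imwrite(str(path), labels * np.uint8(255))
    elif fmt == "geotiff":
        _write_geotiff(path, labels)
    elif fmt == "envi":
        _write_envi(path, labels)
    elif fmt == "mat":
        import scipy.io

        scipy.io.savemat(str(path), {"mask": labels})
    else:
        raise ValueError(f"unknown mask format {fmt!r}")


def parse_band_ranges(spec: str | Iterable[str | int | tuple[int, int]]) -> list[tuple[int, int]]:
    """Parse 1-based band ranges such as ``"1-7,58-76,225-242"``.

    Accepts a comma-separated string, or an iterable of ``"start-end"``
    strings, single integers, or ``(start, end)`` pairs.
    """
    if isinstance(spec, str):
        items: Iterable = [s for s in spec.split(",") if s.strip()]
    else:
        items = spec
    ranges: list[tuple[int, int]] = []
    for item in items:
        if isinstance(item, str):
            parts = item.strip().split("-")
            if len(parts) == 1:
                start = end = int(parts[0])
            elif len(parts) == 2:
                start, end = int(parts[0]), int(parts[1])
            else:
                raise ValueError(f"cannot parse band range {item!r}")
        elif isinstance(item, (int, np.integer)):
            start = end = int(item)
        else:
            start, end = int(item[0]), int(item[1])
        if start > end:
            raise ValueError(f"band range start {start} exceeds end {end}")
        ranges.append((start, end))
    return ranges


def exclude_bands(
    cube: HyperCube,
    excluded: str | Sequence[str | int | tuple[int, int]],
) -> HyperCube:
    """Drop bands covered by 1-based ranges of original band identifiers.

    Ranges refer to the cube's original band labels (``B001``-style numbering),
    so re-applying a range set already applied is a no-op: surviving labels are
    recorded on the result and matched against on subsequent calls.
    """
    ranges = parse_band_ranges(excluded)
    labels = np.asarray(
        cube.band_labels if cube.band_labels is not None else range(1, cube.bands + 1)
    )
    upper = int(labels.max())
    for start, end in ranges:
        if start < 1 or end > upper:
            raise ValueError(
                f"band range {start}-{end} outside valid identifiers 1-{upper}"
            )
    if not ranges:
        return HyperCube(cube.values.copy(), band_labels=cube.band_labels)
    drop = np.zeros(labels.shape, dtype=bool)
    for start, end in ranges:
        drop |= (labels >= start) & (labels <= end)
    keep = ~drop
    if not keep.any():
        raise ValueError("band exclusion leaves no bands: no bands remain")
    return HyperCube(cube.values[:, :, keep], band_labels=tuple(int(b) for b in labels[keep]))
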