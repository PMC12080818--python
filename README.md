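# fhcdsr — fast hyperspectral change detection via spatial reconstruction

`fhcdsr` locates changed pixels between two co-registered hyperspectral
cubes of the same scene taken at different dates (T1, T2) — the typical
setting of agricultural monitoring, where crop transitions between two
acquisitions must be mapped without training data.  It is an unsupervised,
parameter-light pipeline aimed at bi-temporal benchmark scenes of the
Hermiston/Yancheng kind that circulate as ENVI rasters, GeoTIFFs or
MATLAB `.mat` files.

## Method

Each date's cube `I ∈ R^(rows × cols × bands)` is processed in three steps:

1. **Mirror boundary filling.**  Every band plane is enlarged by one pixel
   per side with edge-inclusive symmetric reflection, so a full 3×3 window
   exists at every original pixel.

2. **Spatial reconstruction under a weighted zero-Laplacian constraint.**
   For each pixel spectrum `X0` with 4-neighbours `X1..X4`, neighbour
   affinities are computed from a spectral similarity (cosine similarity by
   default; `1/(1+d)` for Euclidean `d`, or the cosine of the spectral
   angle) and normalized to `w̃ᵢ = wᵢ / Σwᵢ`.  Setting the weighted
   Laplacian `w0·X0 − Σ w̃ᵢ·Xᵢ` to zero and solving for `X0` replaces each
   spectrum by the similarity-weighted convex combination of its
   neighbours (`w0 = 1` by default) — smoothing homogeneous crop parcels
   while preserving parcel boundaries.  Both dates yield reconstructed
   cubes `Y_T1`, `Y_T2`.

3. **Windowed energy-difference detector.**  Per pixel, with 3×3 windows
   `x`, `y` taken from the re-padded reconstructed cubes,

       D = | Σ_{k=0..8} Σ_{b=1..B} (y_kb² − x_kb²) | · W,
       W = arctan( (⟨x0, y0⟩ / (‖x0‖·‖y0‖))² ),

   where `x0`, `y0` are the centre spectra.  `W ∈ [0, π/4]` for
   nonnegative spectra and is maximal for collinear spectra, so `D`
   responds to intensity/energy change among spectrally similar pairs.
   Pixelwise baselines are included: AD (`‖y0 − x0‖₂`) and AAD
   (band-mean `|y0 − x0|`).

Score maps are evaluated threshold-free with ROC curves and trapezoidal
AUC (equal to the Mann–Whitney statistic, ties at half credit); Otsu,
quantile and fixed thresholding produce binary change maps when needed.

A seeded scene simulator generates bi-temporal cubes with known
ground-truth change (contiguous class patches with smooth Gaussian-bump
signatures, planted change blobs, additive noise, inter-date radiometric
gain), so the whole pipeline is testable without external downloads.

## Worked example

```python
from fhcdsr import SceneSpec, generate_scene, detect_change, roc, auc_report

t1, t2, truth = generate_scene(SceneSpec())   # 64x64x40, 409 changed pixels
curves = [(m, roc(detect_change(t1, t2, m), truth)) for m in ("fhcdsr", "ad", "aad")]
print(auc_report(curves).to_text())
```

prints

```
method  AUC (%)
fhcdsr  82.023
ad      100.000 *best*
aad     100.000 *best*
```

i.e. on this synthetic scene — whose second date carries a 5% global
radiometric gain — the reconstruction-based detector reaches 82% AUC while
the pixelwise difference baselines saturate.  The gain sensitivity of the
energy-difference statistic is analysed in `docs/methods.md`; with unit
gain the windowed detector scores ≈ 98.8% and the same scene becomes
trivially separable for all methods.

The same pipeline is scriptable from the shell:

```sh
fhcdsr simulate --out-dir scene --seed 17
fhcdsr detect --t1 scene/t1.img --t2 scene/t2.img \
              --out scene/score.img --mask scene/mask.png
fhcdsr eval --scores scene/score.img --truth scene/truth.png --roc-csv scene/roc.csv
# AUC = 82.023%  (409 positive of 4096 pixels)
```

For real benchmark pairs, pass the uncalibrated-band ranges at load time,
e.g. `--exclude-bands 1-7,58-76,225-242` for a 242-band Hyperion scene
(leaving 198 bands).

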