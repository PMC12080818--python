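# Methods

## Model and assumptions

The package detects bi-temporal change in hyperspectral cubes under three
assumptions: the two acquisitions are geometrically co-registered; changed
ground objects occupy spatially contiguous regions at roughly field scale;
and within an unchanged homogeneous region the two dates differ only by
noise and a possible global radiometric factor.  No radiometric
calibration, atmospheric correction or unit interpretation is attempted —
values are treated as opaque radiance/reflectance numbers and are never
rescaled on load (integer digital numbers stay integers in double
precision).

### Boundary filling

A 1-pixel edge-inclusive symmetric (mirror) border is added to every band
plane before any 3×3 windowing, so all original pixels have full
neighbourhoods.  "Mirror" is ambiguous between edge-inclusive and
edge-exclusive reflection; the edge-inclusive convention is used because
at pad width 1 it equals nearest-edge replication and remains defined on
1-pixel-wide scenes.  One consequence worth knowing: a border pixel's
reflected neighbour is its own spectrum, so reconstruction at the border
is biased toward the pixel itself.

### Weighted zero-Laplacian reconstruction

For each pixel, affinities to the four nearest neighbours are computed
with one of three metrics (`cosine`, `euclidean`, `sam`) in one of two
modes.  The default, `similarity`, uses cosine similarity, `1/(1+d)` for
Euclidean distance `d`, or the cosine of the spectral angle; similar
neighbours then dominate the normalized weights `w̃ᵢ = wᵢ/Σwᵢ`, and the
reconstructed spectrum `(1/w₀)·Σ w̃ᵢ Xᵢ` averages noise inside a
homogeneous parcel while drawing little from across a parcel boundary.
The alternative `distance` mode uses the raw distances themselves as
weights — a literal "normalize the distances into weights" reading — but
it anti-smooths (dissimilar neighbours dominate) and is kept only as an
explicit flag.  Reconstruction is a single Jacobi-style pass over
original-cube neighbours: deterministic, order-independent, and not
iterated to a global Laplacian solution, which would progressively blur
parcel boundaries.

Numerical details: cosine affinities are clipped to [−1, 1] and negative
similarities clamped to 0 so weights stay nonnegative; a zero-norm
spectrum gets affinity 0 with a logged warning rather than a
division-by-zero; if all four affinities vanish the weights fall back to
uniform 1/4 (again with a warning).  `w₀` defaults to 1 — then the
reconstruction is a convex combination and every output band value lies
within the [min, max] of its four neighbours — and `w₀ = 0` is rejected.

### Detector

With 3×3 windows `x`, `y` from the re-padded reconstructed cubes, the
change score is `|Σ_k Σ_b (y_kb² − x_kb²)| · W` with
`W = arctan(cos²(x₀, y₀))` from the centre spectra (an option uses the
original cubes' centres instead).  The absolute value makes the score a
magnitude: radiance decreases and increases rank equally.  The windowed
sum includes the centre (9 terms).  Two structural properties follow
directly and are tested: swapping the dates leaves scores unchanged, and
scaling both cubes by `s` scales scores by `s²` while `W` is invariant.

`W` deserves emphasis: it is *largest* when the two centre spectra are
positively collinear and zero when they are orthogonal.  It therefore
amplifies energy changes among spectrally similar pairs (brightness
changes of the same material) and suppresses pure spectral-shape changes.
This is implemented exactly as defined; its consequences are measured
below.

Pixelwise baselines: AD = `‖y₀ − x₀‖₂`, AAD = band-mean `|y₀ − x₀|` (the
most common readings of those names).

### Thresholding and evaluation

ROC curves sweep all distinct score values (prediction: score ≥ t), with
tied scores grouped at one threshold; AUC is the trapezoidal integral,
identical to the Mann–Whitney statistic with half credit for ties, so a
constant map scores exactly 0.5 and any strictly increasing transform of
the scores changes nothing.  AUC is reported as a percentage with three
decimals.  For binary maps, Otsu's criterion is applied to a 256-bin
histogram of the min-max-normalized map (a constant map yields an all-zero
mask with a warning); `quantile` marks exactly the top fraction of pixels
(ties broken by array order); `fixed` compares against a given value.

## Synthetic scenes

`SceneSpec` defaults define the standard benchmark: 64×64 pixels, 40
bands, 4 classes in contiguous Voronoi patches of characteristic size 16
pixels, 10% of pixels switching class at T2 inside randomly grown
4-connected blobs, additive Gaussian noise at 5% of the mean signal
amplitude drawn independently per date, a global ×1.05 radiometric gain
on T2 (inter-date illumination drift), seed 17.  Class signatures are
sums of three Gaussian bumps (amplitudes 0.5–1.2, widths bands/12 to
bands/5) over a 0.15 baseline — smooth, nonnegative, spectrally
correlated curves that stand in for vegetation signatures without
shipping a spectral library.  All draws flow from the single seed in a
fixed order (signatures, layout, blobs, noise), so specs differing only
in `noise_sigma` share layouts and unit-noise patterns; the planted truth
mask marks exactly `⌊change_fraction·N⌋` pixels.

What the generator does **not** emulate: sensor-specific noise (striping,
bad bands), subpixel mixing, misregistration, per-class phenological
drift, and spatially varying illumination.  Passing tests on these scenes
therefore demonstrate algorithmic correctness and relative detector
behaviour under controlled conditions, not performance on any real
sensor's data.

## Measured behaviour of the detector on the standard scene

The test suite and `scripts/acceptance.py` compute, rather than assume,
the benchmark numbers; the main findings at seed 17 are:

* With the standard ×1.05 gain, the windowed energy detector reaches
  AUC ≈ 0.820, clearly above the same scorer without reconstruction
  (≈ 0.716), but *below* the pixelwise AD baseline (1.000).
* With unit gain it reaches ≈ 0.988 at all tested noise levels
  (σ ∈ {0, 0.05, 0.1, 0.2}, degrading monotonically), and AD/AAD are
  exactly 1.0 on noise-free scenes.

The gain sensitivity is structural, not a bug: the statistic
`Σ(y² − x²)` assigns every *unchanged* pixel an offset `(g² − 1)·E`
proportional to its class energy `E` (≈ 10% of energy at `g = 1.05`),
which is comparable to the between-class energy contrasts that changed
pixels produce — and the weight `W` is maximal precisely for gain-scaled
unchanged pixels, since their spectra stay collinear across dates.
Depending on which class pairs happen to switch (i.e. on the seed), the
changed-pixel signal can even fall below the unchanged gain floor, pushing
AUC below 0.5.  Conversely, even on noise-free unit-gain scenes the
windowed detector cannot reach AUC 1.0 on irregular change blobs: an
unchanged pixel in a concave notch of a blob has up to five changed
window members, a convex-corner changed pixel only four, so their scores
interleave (hence 0.988, not 1.0).  Users targeting scenes with
appreciable inter-date radiometric drift should normalize the dates first
or rely on the scale-invariant part of the statistic; the drift itself is
exactly what the `gain_t2` parameter exists to probe.

## Numerical choices

* All arithmetic in double precision; loaders reject NaN/Inf at the door
  (the reconstruction and detector formulas have no NaN semantics).
* The weighted combination is evaluated with a pairwise-grouped
  4-term product-sum, which makes reconstruction an exact fixed point on
  spatially constant cubes (uniform weights are exactly 1/4 and the
  grouped sum reproduces the value bit-for-bit).
* `sam`-metric angles pass through `arccos`, which is ill-conditioned
  near zero angle; loop-oracle agreement for the `sam`/`distance`
  combination is therefore ~1e-8 relative rather than 1e-10.
* Scale covariance (`s²`) is bit-exact for power-of-two `s` and holds to
  rounding otherwise.
* Problem sizes in the tests (20×20×30 reconstruction oracle, 15×15×20
  detector oracle, 64×64×40 benchmark scenes) were chosen so the naive
  per-pixel reference implementations stay readable Python loops.

## Known limitations

* Single-pass 4-neighbour reconstruction only; no 8-neighbour stencils,
  multi-scale windows or iterative solvers.
* Binary change only: multi-class change-type labels are collapsed.
* Scenes are processed in memory; no tiling for scenes larger than RAM.
* CRS/georeferencing metadata is not interpreted, and ENVI header support
  covers the interleave/data-type/byte-order/offset core, not vendor
  extensions.
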