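# Methods

## Model

A hyperspectral SRS image is a rows × cols × bands volume; each pixel
holds one Raman spectrum sampled at the acquisition bands (default
emulation: 75 bands from 2700 cm⁻¹ at 6 cm⁻¹ spacing, i.e. the
CH-stretching window). A reference library holds pure-standard spectra.
Both sides go through one preprocessing chain so that their inner product
compares spectral shape only:

1. **Baseline**: none (default), subtraction of a measured background, or
   arPLS estimation (see below). Order is baseline first, everything else
   after.
2. **Interpolation** to a common uniform grid, default 2700–3150 cm⁻¹ at
   1 cm⁻¹ (451 points), by linear interpolation. Grid points outside the
   source spectrum's coverage are set to 0 and flagged; the flag
   propagates so masked statistics never mistake zero-fill for signal.
3. **Min–max scaling** (I − I_min)/(I_max − I_min), computed over covered
   grid points only. This removes any affine intensity transform
   aI + b (a > 0): per-pixel gain (laser power, focus) and offset cannot
   change the score. A constant pixel has no shape and is *degenerate*:
   the reference path raises, the pixel path masks the pixel with score 0
   (never NaN, so ratio images stay finite).
4. **Euclidean normalization** to unit norm, making the dot product a
   cosine similarity.

**Scoring.** For offsets Δx on ±`max_shift` (default 30 cm⁻¹) at
`shift_step` (default 1 cm⁻¹, must be an integer multiple of the grid
step), the reference vector is displaced along the axis — vacated leading
entries zero-padded, overhanging entries trimmed, no renormalization —
and the penalized similarity u·v(Δx) − αΔx² is evaluated; the maximum
over Δx is the score and its argument the best shift. Positive shift
means the reference moved toward higher wavenumber. Displacing the
reference rather than the pixel is an implementation choice (the two are
equivalent up to the sign of Δx) that lets pixel preprocessing be done
once per pixel and reused across an entire library.

Bounds: preprocessed spectra are nonnegative, so the Δx = 0 term is ≥ 0
and Cauchy–Schwarz bounds every term by 1; scores live in [0, 1]. At
α → ∞ the method degenerates to unshifted cosine matching; at α = 0 the
shift is free. For a pixel that is an exact displaced copy of the
reference (support not clipped) the score is exactly 1 − αk², *provided*
the reference decorrelates fast enough along the axis: if its
autocorrelation drops by less than α(2k − 1) over one grid step, the
penalized maximum lands short of the true offset. With α = 1 × 10⁻⁴ and
shifts up to 30 this needs roughly 1 − ρ(1 cm⁻¹) > 6 × 10⁻³, i.e.
Gaussian bandwidths σ ≲ 6 cm⁻¹; validation fixtures for the closed form
use σ ≤ 5 cm⁻¹.

**Ties** at equal penalized maxima are broken toward the smallest |Δx|,
then the negative offset — deterministic, and favoring the unshifted
interpretation.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| α (`alpha`) | 1 × 10⁻⁴ | cm² | offset penalty; 4 × 10⁻⁴ over-penalizes (genuine jitter taxed), 0.25 × 10⁻⁴ under-penalizes (free-shift false positives) |
| `max_shift` | 30 | cm⁻¹ | offset search bound; at the default α the edge penalty (0.09) already dominates |
| `shift_step` | 1 | cm⁻¹ | offset grid; fixed to the interpolation step |
| grid | 2700–3150, step 1 | cm⁻¹ | CH-stretching analysis window |
| arPLS λ | 1 × 10⁵ | — | baseline smoothness |
| arPLS ratio / max_iter | 10⁻⁶ / 50 | — | convergence control |
| ratio ε | 10⁻⁶ | — | denominator floor; smaller denominators mask the pixel |

arPLS iterates Whittaker smoothing with a second-difference penalty,
re-weighting each point by a logistic function of its residual so that
peaks are progressively excluded from the baseline. Settings are typical
published values; non-convergence returns the best estimate rather than
failing.

## Numerical and design choices

- **Determinism.** Per-shift dot products are computed as elementwise
  products reduced row-by-row (numpy pairwise summation), not one BLAS
  matrix product: each pixel's score then depends only on its own row,
  and chunked execution is bit-identical to a single pass (BLAS GEMM is
  not, which was measured directly).
- **PINV baseline** solves min‖Rc − s‖₂ per pixel via the Moore–Penrose
  pseudo-inverse of the unit-norm reference matrix, after the same
  preprocessing chain; rank deficiency warns and returns the minimum-norm
  solution. Per-pixel solving makes a pixel's coefficients independent of
  the image it is embedded in. Coefficients are unbounded and can be
  negative — the qualitative contrast with PRM's [0, 1] scores that the
  baseline exists to demonstrate.
- **uint8 score export** uses the fixed mapping round(score·255) (numpy
  half-even at exact ties), not per-image min/max, so 8-bit maps are
  comparable across references.
- **Percentile selection** uses linear-interpolation percentiles over
  unmasked scores; top-percentile spectra are averaged *after*
  preprocessing, so the mean is a mean of unit-norm shapes.
- **Agreement metrics**: structural similarity with standard constants
  (Gaussian-free 7-pixel window, inputs jointly rescaled to [0, 1]) and
  NMSE = ‖a − b‖²/‖b‖². The exact similarity-index variant is a choice;
  defaults are documented here rather than configurable magic.
- **Four-Gaussian decomposition** fits amplitude/center/σ per component by
  bounded nonlinear least squares (centers inside the window, amplitudes
  ≥ 0, σ ∈ [2, 100] cm⁻¹), initialized at the canonical CH bands
  2850/2880/2935/3065 cm⁻¹ with σ = 15 cm⁻¹; components are reported
  sorted by center. "Width" means the Gaussian σ throughout.

## Synthetic fixtures

The generator emulates the acquisition conditions the pipeline targets:
mixtures of Gaussian-peaked lipid-like standards on the dense 1 cm⁻¹
grid, per-pixel brightness randomization (uniform 0.5–2×), rigid spectral
jitter N(0, jitter_sd) applied by interpolation, additive Gaussian noise
on raw intensities, then sampling at 75 bands / 6 cm⁻¹ so the pipeline's
re-interpolation path is exercised end to end. Layouts: `two_phase`
(left/right pure phases), `droplets` (random disks on a background
phase), `fraction_ramp` (mixture fraction 0 → 1 across columns). All
outputs are pure functions of the seed, and ground-truth weight, shift
and brightness maps accompany every stack.

The built-in standards are *caricatures*: a CH₂-dominant
triacylglyceride-like profile, a CH₃-dominant phosphatidylethanolamine-
like profile with an olefinic shoulder, and a sterol-like 2870 cm⁻¹
profile. They reproduce the discriminability structure of real lipid
CH-region spectra (pairwise cosine < 0.95) but not congested fingerprint
bands, Fermi-resonance lineshapes, detector nonlinearity or structured
(non-white) noise — so passing tests demonstrate algorithmic
correctness, not instrument-level performance on tissue.

`make_regime_pair` is a purpose-built pair for penalty-regime
experiments: a matched standard with sharp bands (σ = 5 cm⁻¹) and a
confounder consisting of the same bands broadened (σ = 25 cm⁻¹) plus a
half-weight copy of the sharp bands offset +25 cm⁻¹. Scored against the
matched standard, confounder pixels respond almost flatly to small
offsets but gain from a ~+23 cm⁻¹ shift; matched pixels pay the full
penalty of their genuine jitter. Matched-vs-confounder contrast therefore
peaks at intermediate α and degrades at both 0.25 × 10⁻⁴ (the confounder
exploits the offset copy — the free-shift false positive, e.g. a
reference band matching a displaced pixel band) and 4 × 10⁻⁴ (genuine
jitter over-taxed). A plain two-standard phase pair whose dominant bands
are further apart than `max_shift` does not show the under-penalization
arm, because no reachable offset aligns them.

## Problem sizes

Validation runs small: stacks of 8×8 to 16×16 pixels at 75 bands, 451
grid points, 61 shift evaluations, 10–20 noise replicates — sizes at
which the naive per-pixel/per-shift oracle is still affordable for exact
comparison. The implementation itself is vectorized over pixels and
handles 512×512 stacks; memory is bounded by chunked execution, which is
guaranteed output-identical.

## Known limitations

- Offsets are rigid (one Δx per pixel) and on-grid; sub-step or
  band-dependent shifts are not modeled.
- α is global; no per-pixel or per-reference adaptation.
- Library content is user-supplied; the built-ins are synthetic
  stand-ins, not measured standards.
- arPLS on a large stack is a per-pixel loop (sparse solves) and
  dominates runtime when enabled.
- ROI/nucleus segmentation is out of scope; externally produced masks are
  accepted instead.
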