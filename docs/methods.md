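# Methods

This note documents the models implemented in `vascniche`, the parameter
choices that matter, what the synthetic world does and does not emulate,
and the numerical conventions. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Grid conventions

All volumes are voxel-centered scalar fields in (z, y, x) axis order with
0-based indices and per-axis physical spacing in µm. The default spacing
is (2.0, 0.5, 0.5) µm — a two-photon z-stack geometry where the axial step
is four times the lateral pixel — so every distance-based operation is
exercised under anisotropy by default. Voxel index `i` sits at physical
coordinate `i * spacing`.

## The leakiness statistic

Given a binary vascular mask M (segmented from the retained, high-
molecular-weight tracer) and the leaky-tracer volume I, the statistic is

    OUT/IN = sum_{x not in M} I(x) / sum_{x in M} I(x).

Properties relied on throughout:

* **Intensity invariance.** Scaling I by any c > 0 leaves the ratio
  unchanged (exactly so for power-of-two c in IEEE arithmetic; to ~1e-9
  relative otherwise). This is the reason the statistic is a ratio rather
  than an absolute extravascular sum.
* **Conservation.** IN + OUT equals the total stack intensity.
* **Mass bookkeeping.** On a phantom whose leaky channel deposits a known
  fraction f of its mass outside the true mask, OUT/IN = f/(1−f). This
  closed form is the primary oracle for the statistic.
* An all-zero IN sum raises an undefined-ratio error; it is never
  silently reported as zero leakiness.

A dilated mask can only move intensity from OUT to IN, so the ratio
decreases monotonically under dilation. This sensitivity is exposed
(`dilate_mask`), not hidden. The command-line leakiness stage pads the
Otsu surface by one voxel by default: the PSF pushes a few percent of
purely intravascular signal beyond the half-max iso-surface, and without
padding a zero-leak stack scores ≈ 0.18 rather than ≈ 0.008. Setting
`mask_dilate_voxels: 0` restores the raw surface.

## Segmentation

* **Background subtraction.** `out = max(in − cp · B, 0)` where B is the
  local dynamic range: the maximum of the 1-voxel-presmoothed signal in a
  window of half-width `scale` (default 20 µm), and `cp` defaults to
  0.075, the midpoint of the conventional manual 5–10% setting. With
  cp = 0 the input is untouched; with cp = 1 a constant volume is zeroed.
  Diffuse haze below cp of the local peak is removed while structures at
  the local peak are reduced by at most cp. A cp·Gaussian-baseline variant
  was rejected: it cannot remove a realistic diffuse background at
  cp ≈ 0.075 (it subtracts only ~7.5% of it).
* **Iso-surface.** Voxels strictly above an Otsu (default) or absolute
  threshold, with 26-connected components smaller than 64 voxels removed.
  Otsu replaces the manual threshold of interactive practice because
  reproducibility requires an automatic default; the absolute override
  preserves fidelity to manual workflows. An empty result warns rather
  than silently returning.

## Morphometry

* **Distance maps** use the exact anisotropic Euclidean distance
  transform (`scipy.ndimage.distance_transform_edt` with per-axis
  sampling); the test suite verifies exact agreement with an all-pairs
  brute-force oracle on random grids.
* **Centerlines** come from topology-preserving 3D thinning. Fragments
  are the connected components left after removing junction voxels (> 2
  neighbors under 26-connectivity); dangling spur fragments shorter than
  5 µm are pruned as thinning artifacts (without pruning, fragment and
  sprout counts inflate). A single-voxel fragment is assigned one voxel
  of nominal length.
* **Diameters** are 2 × (EDT of the mask at each centerline voxel),
  averaged along a fragment. This is the standard surrogate for a
  proprietary interactive filament tool; it scales exactly linearly with
  voxel spacing and recovers analytic cylinder diameters within 10% for
  radii ≥ 3 voxels (the EDT measures to the nearest *background voxel
  center*, a ≤ half-voxel bias that shrinks with radius).
* **Per-vessel hypoxia distance**: each vessel is a 26-connected mask
  component; its distance is the minimum over its voxels of the distance
  map of the hypoxia mask ("distance to the closest hypoxic pixel").
  Per-fragment variants would be possible but the per-component minimum
  is the documented default reading.
* **Hypoxia density** is total reporter intensity divided by the voxel
  count of the stack.
* **Spot detection** is a Laplacian-of-Gaussian filter at
  σ = diameter/2.355 per axis (FWHM matching) with ellipsoidal
  non-maximum suppression of half a spot diameter; blobs closer than that
  may merge into one detection (documented contract, not a defect).
* **Microvascular density**: endpoints (exactly one 8-neighbor) of the
  pruned 2D skeleton per mm², optionally as fold over a control density.
  A closed loop has no endpoints; a line has two.
* **Histograms** of distance distributions use fixed-width bins (default
  5 µm) from 0 to the observed maximum; relative frequencies sum to 1.

## Flow statistics

Geometric MFI is `exp(mean(log(I + ε)))` with ε = 10⁻³ × the smallest
positive intensity in the column (0 when the column is all-positive), so
zero intensities from compensation do not blow up the log while
all-positive columns are exact. The normalized readout
`gMFI_sample / gMFI_control` is invariant to common positive rescaling of
both tables — the detector-gain contract that motivates geometric-mean
normalization. Gates are explicit user-supplied thresholds (conjunctions
of >, <, between); there is no automatic gating, mirroring manual
cytometry practice, and the normalizing control is always an explicit
input.

## Cohort inference

Patient outcomes are the four joint states of {NO persistent, NO
decreased} × {failure, response}, in the fixed order (persistent∧failure,
persistent∧response, decreased∧failure, decreased∧response). Counts n are
multinomial with probabilities θ on the 3-simplex.

* **Importance sampling**: θ is drawn
  uniformly on the simplex — which is the uniform prior — and weighted by
  the multinomial likelihood, computed in log space and normalized.
  Default N = 10⁶ samples; tests use 10⁵.
* **Analytic oracle**: the same posterior is Dirichlet(n + 1) by
  conjugacy; an equal-weight Dirichlet sampler cross-checks every
  importance-sampling summary but never replaces it.
* **Conditionals** P(event|condition) are per-sample ratios of summed θ
  components with weights carried through. Aggregation of a Dirichlet is
  Dirichlet, so such a conditional is exactly Beta(n_event + 1,
  n_rest + 1) distributed.
* **MAP**: the generic estimator is a 200-bin weighted histogram on
  [0, 1] with local quadratic peak interpolation (boundary peaks: if the
  fitted parabola still rises at the edge, the mode is the edge). Its
  Monte-Carlo error at the effective sample sizes the importance sampler
  attains (~10⁴ at N = 10⁵ for realistic cohort sizes) is ~0.03, so
  conditional summaries default to a moment-matched Beta fit of the
  weighted samples, whose analytic mode has error < 0.01 in the same
  regime. A flat posterior (no data) returns 0.5 with a flatness flag by
  convention. Summaries with effective sample size < 100 raise an
  unreliable-estimate error rather than returning a number.
* **CI95**: equal-tailed weighted quantiles (midpoint rule).

## The synthetic world

The phantom generator emulates: recursive binary branching tube networks
(child radius = parent × taper, default 0.8; children diverge 25–50° so
sibling tubes separate), a retained tracer filling the lumen, a leaky
tracer depositing fraction f of its mass outside the vessels as an
exponential halo with 10 µm decay length, hypoxia
h(d) = h_max(1 − exp(−d/λ)) with λ = 30 µm (hypoxia concentrates away
from perfused vessels; an AML-like niche is modelled by a smaller λ),
point-like parenchymal cells, leak kinetics f(t) = 1 − exp(−k·t) (the
simplest saturating law consistent with a monotone rise over minutes),
Gaussian PSF blur (default σ = 1.5/0.4/0.4 µm z/y/x) and Poisson shot
noise plus Gaussian read noise.

It does **not** emulate: blood flow or red-blood-cell shadows,
photobleaching, depth-dependent attenuation, second-harmonic bone
physics, vessel wall thickness, or motion artifacts. A green test on a
phantom therefore establishes the correctness of the *quantification*
given an image of known composition — not robustness to every
acquisition artifact of real intravital data.

Numerical caveats, stated deliberately:

* Pre-blur mass bookkeeping is exact; after PSF blur, channel totals are
  preserved to within 1% (reflect-mode filtering near boundaries).
* Poisson noise is mean-preserving exactly. Additive zero-mean Gaussian
  read noise is clipped at zero (intensities are non-negative), which
  biases near-zero background upward by σ/√(2π) per voxel; the
  mean-preservation property is therefore only claimed, and tested,
  where the clamp is inactive.
* All generators are bit-reproducible from (parameters, seed); one
  integer seed drives every stage, with per-timepoint seeds derived via
  `numpy.random.SeedSequence`.

## Known limitations

* The fragment/segment correspondence on dense trees is approximate near
  junctions; fragment counts are validated to ±2 of the planted segment
  count, not voxel-for-voxel.
* Diameter recovery degrades below ~3 voxel radii (quantization), and in
  strongly anisotropic grids the thinnest axis dominates the error.
* The importance sampler's effective sample size collapses for cohorts
  much larger than a few dozen patients (the uniform proposal is far from
  a concentrated posterior); the conjugate sampler is the practical route
  there, and large-cohort recovery tests use it.
* The acceptance pipeline's 73%/100% cohort numbers are computed on a
  synthetic stand-in tabulation bundled with the tests (see the file
  name); a real clinical per-patient table is always accepted as input,
  never hard-coded.
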