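# vascniche

Quantification of bone-marrow vascular dysfunction in acute myeloid
leukemia (AML) from intravital two-photon microscopy, with a fully
synthetic phantom world for validation.

AML remodels the bone-marrow vascular niche: vessels become leaky, the
niche becomes hypoxic, and nitric-oxide (NO) overproduction by endothelial
cells persists after chemotherapy in patients who go on to fail treatment.
This package re-implements the image- and cohort-level quantifications
behind those observations as a tested, reusable pipeline:

* **Vascular leakiness (OUT/IN).** Two vessel-pooling tracers are injected
  together: a high-molecular-weight tracer retained in the lumen defines
  the vascular iso-surface *M*; a medium-molecular-weight dextran-like
  tracer extravasates. The leakiness statistic at a timepoint is

  `L = OUT / IN = (Σ_{x∉M} I(x)) / (Σ_{x∈M} I(x))`

  where *I* is the leaky-tracer channel. Being a ratio of sums of the same
  channel, *L* is exactly invariant to the tracer's global fluorescence
  intensity.

* **3D morphometry.** Filament-style vessel centerlines (topology-
  preserving 3D thinning), per-fragment mean diameters from the
  anisotropic Euclidean distance transform (EDT), per-vessel distances to
  hypoxic areas, hypoxia reporter intensity per voxel, spot-detected
  cell-to-vessel distances, and microvascular density as skeleton sprout
  tips per mm² of a 2D section.

* **Flow-cytometry statistics.** Threshold gating, geometric mean
  fluorescence intensity `gMFI = exp(mean(log I))`, control-normalized
  uptake `gMFI_sample / gMFI_control`, population fractions and absolute
  counts.

* **Bayesian cohort inference.** The joint distribution of two Boolean
  patient variables — NO persistence after induction therapy and treatment
  response — is multinomial with probabilities θ on the 3-simplex. A
  uniform prior is updated by importance sampling (θ drawn uniformly,
  weighted by the multinomial likelihood; default N = 10⁶), and
  conditionals such as P(failure | NO persistent) are summarized by MAP
  and 95% credible intervals. The conjugate Dirichlet(n+1) posterior is
  implemented alongside as an independent analytic oracle.

* **Phantoms.** Branching tube networks rasterized onto anisotropic voxel
  grids (default spacing 2.0 × 0.5 × 0.5 µm in z/y/x), a retained-tracer
  channel, a leaky-tracer channel depositing a controllable mass fraction
  `f(t) = 1 − exp(−k·t)` outside the vessels as an exponential
  perivascular halo, a hypoxia field `h(d) = h_max·(1 − exp(−d/λ))` of
  distance-to-vessel *d*, point-like cells, Gaussian PSF blur and
  Poisson/Gaussian noise — with all ground truth exported.

## Worked example

Simulate a leaky-vessel phantom, score it, and run the cohort inference:

```sh
vascniche simulate --out /tmp/t0 --seed 1 --leak-fraction 0.0
vascniche simulate --out /tmp/t1 --seed 1 --leak-fraction 0.3
vascniche leakiness --stack /tmp/t0 --stack /tmp/t1 --out /tmp/leak
```

prints one OUT/IN ratio per timepoint (t=0: no extravasation, t=1: 30% of
the tracer mass outside the vessels):

```
t=0 OUT/IN=0.0076
t=1 OUT/IN=0.3972
```

The zero-leak stack stays near 0 (the residual is PSF spill), and the
30%-leak stack lands near the mass-bookkeeping value f/(1−f) = 0.4286 —
slightly below it because the padded Otsu surface swallows a little of
the perivascular halo. On pre-blur fields against the truth mask the
ratio equals f/(1−f) to voxel quantization.

```sh
vascniche cohort --counts 8 3 2 5 --seed 1 --out /tmp/cohort
```

```json
{
  "conditional": "P(failure | NO stable/increased)",
  "counts": [8, 3, 2, 5],
  "MAP": 0.728,
  "CI95": [0.428, 0.901]
}
```

With 8 of 11 NO-persistent patients failing therapy, the posterior mode of
P(failure | persistent) is 73% with a wide CI95 — eleven patients carry
little information, which is exactly what the credible interval shows.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch: it simulates a dual-tracer
timecourse phantom (blur and noise on), scores the leakiness series
through the segmentation route, runs the morphometry stage (diameters,
vessel-to-hypoxia distances, hypoxia density, cell spots), recovers a
planted three-fold uptake from synthetic event tables, and runs the
importance-sampling cohort inference (N = 10⁶) on a bundled synthetic
stand-in tabulation, printing a summary of every stage.

## Layout

```
src/vascniche/
  phantom.py      synthetic trees, stacks, kinetics, cohorts, event tables
  imgseg.py       background subtraction, iso-surfaces, OUT/IN leakiness
  morphometry.py  skeletons, diameters, distance maps, spots, MVD
  flowstats.py    gating, geometric MFI, normalized uptake, fractions
  cohort.py       importance-sampling posterior, conditionals, MAP, CI95
  io.py           TIFF + JSON sidecar stacks, CSV tables, manifests
  cli.py          simulate / leakiness / morpho / flow / cohort commands
docs/methods.md   models, assumptions, parameter choices, limitations
```
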