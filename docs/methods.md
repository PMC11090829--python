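# Methods

## Model and procedure

The pipeline reduces each tissue section (or tile) to a single value,
`x = log2(K8+ area / K14+ area)`, and each experimental condition to a
probability 4-vector over quartile bins of the normal-tissue reference
distribution.  Conditions are compared with the base-2 Jensen–Shannon
divergence of their bin vectors, rescaled to a 0–100 similarity score
anchored so that the most disparate comparison in the data set (pooled
ER+ vs TNBC starting tissue, raw JSD ≈ 0.56) maps to 0.

Assumptions worth stating explicitly:

* **Area ratio as phenotype.** The K8/K14 area ratio is treated as a
  sufficient one-dimensional summary of epithelial phenotype.  Markers
  shown to be redundant with K8 or K14 (K18, ERα; CD10, SMA, p63) are
  handled by the correlation module, not added to the ratio.
* **Four bins, not densities.** Divergence is computed on the 4-bin
  discretization, never on kernel-density estimates; the KDE in the
  density figure is visualization only, and its histogram is always
  written alongside.
* **Base-2 logarithms.** The divergence is bounded by [0, 1] only in
  base 2; the 0.56 anchor and all scores assume this base.
* **Sections are exchangeable draws.** The sample-size rule
  `N_min = min{N : 1−(1−f)^N ≥ c}` models sections as independent draws
  from the condition's bin distribution.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `min_tissue_frac` | 0.05 | fraction of tile area | retention rule: tiles must exceed 5 % tissue (strict `>`) |
| `tile_side_px` | derived | px | `round(sqrt(mean organoid image area))` over the run's organoid set, so ST tiles match organoid footprints; fallback 256 px when no organoids are present |
| `threshold_method` | `otsu` | — | parameter-free bimodal split; `fixed` override available |
| `min_object_px` | 25 | px | speckle removal floor for area masks |
| `nucleus_px_range` | (50, 5000) | px | size window for nucleus counting |
| `pseudocount_px` | 1 | px | added to *both* areas only when either is zero (symmetric, no directional bias); a section with no K8, no K14 and no tissue is rejected |
| `quantile_method` | `linear` | — | numpy's interpolated quantiles for the bin boundaries |
| `norm_constant` | 0.56 | raw JSD | similarity-score anchor; re-derivable via `calibrate_norm_constant` |
| `least_bin_freq`, `confidence` | 0.08, 0.85 | probability | give `N_min = 23` sections per condition |

Bin-interval closure is left-open/right-closed with bin 1 closed at Q25,
so every value maps to exactly one bin and assignments are invariant
under a common shift of values and boundaries.

## Numerical choices

* `0·log(0/m) := 0`; bins empty in both distributions are skipped (their
  mixture mass is zero and never divides).  The JSD sum is clipped to
  [0, 1] against floating-point drift; probability inputs must be
  non-negative and sum to 1 within 1e-9.
* The normalization `(1 − JSD/0.56)×100` may legitimately go below zero
  when a comparison exceeds the anchor.
* Otsu thresholds for ST images are computed once on the parent image
  and applied as fixed values to its tiles: Otsu run on a
  mostly-background tile would split the noise distribution instead of
  separating signal from background and inflate the tissue fraction.
* The Mann–Whitney test enumerates the exact null when the combined
  sample is ≤ 16 and tie-free, otherwise uses the tie-corrected,
  continuity-corrected normal approximation.  Fully tied data return
  p = 1 with a warning.  The approximation agrees with enumeration to
  ~0.01 at n = 8 + 8; its worst case (~0.011, near p = 0.5) is a
  property of the normal approximation itself.
* Quartile degeneracy (all boundaries equal) warns rather than fails;
  conditions with fewer than `N_min` sections warn rather than fail,
  since real cohorts occasionally fall below the minimum.

## Synthetic-data generator

Each subtype's log-ratio distribution is a two-component normal mixture:
a K14-rich component (left) and a K8-rich component (right), with the
right component's weight `w` encoding subtype.  Defaults:

| subtype | component means | component sds | w |
|---|---|---|---|
| normal | (−1.5, +1.5) | (1.0, 1.0) | 0.5 |
| TNBC-like | (−2.4, +1.0) | (1.1, 1.0) | 0.2 |
| ER+-like | (−1.0, +2.4) | (1.0, 1.1) | 0.8 |

Patients within a subtype share the mixture plus a per-patient offset
(`patient_sd = 0.5` log2 units); cohorts default to 6–7 patients with 97
sections each, matching the scale of a typical clinical series for this
assay (a few thousand section images over ~26 tissues).  Organoid
cohorts may add a constant `culture_drift`; drug selection is a
`treatment_shift` added to `w` (K8-ward for positive shifts).  The
non-normal subtype parameters were chosen, via the closed-form bin
probabilities and a seed-sweep, so that the qualitative structure of the
real data holds robustly: within-subtype similarity exceeds every
cross-subtype similarity, and ER+-like vs TNBC-like is the most
disparate pair.  No published numeric distribution parameters exist to
match more closely, so the generator targets orderings, not printed
divergence values.

Draw order is patient-level then section-level from per-patient child
seed streams, so enlarging a cohort never perturbs existing patients,
and cohorts generated from the same seed are coupled by common random
numbers — a treated cohort differs from its untreated twin only where
treatment actually flips a section's mixture component, which makes
shift-monotonicity experiments sharp at realistic sample sizes.

Synthetic section images place random ellipses until the requested
positive-area fractions are met exactly (the last ellipse is trimmed rim
inward), then add Gaussian noise.  They emulate area fractions and
additive noise only: no tissue texture, point-spread blur, spectral
bleed-through, staining gradients or fixation artifacts.  Tests passing
on these images therefore validate the measurement chain (thresholding,
tiling, filtering, binning, divergence), not robustness to real-world
staining variability.

Closed-form bin probabilities (`analytic_bin_probs`) marginalize the
patient offset analytically (component sd inflated to
`sqrt(sd² + patient_sd²)`) and serve as the oracle for the generator and
for expected-divergence computations.

## Experiment sizes

The shipped experiments use 256×256 px images (50 of them in the
recovery experiment, noise at 10 % of foreground intensity), cohorts of
6–7 patients × 97 sections, and 1,000 random distribution pairs for the
divergence-oracle check; the self-quartile and calibration checks use up
to 50,000 sections where convergence to the closed form is the point.

## Known limitations

* Nucleus counting has no watershed splitting; touching nuclei count as
  one component within the size window.
* The "tissue area" of a section without a counterstain channel is the
  union of the K8 and K14 masks — the most conservative definition two
  mandatory channels allow; a dedicated tissue/nuclear channel is used
  when configured.
* Whether the 5 % tissue filter should also apply to organoid images is
  configurable (`tissue_filter_scope`); the default applies it to all
  quantified images.
* Global subtype scores support both `pooled` and `mean_pairwise`
  aggregation because either construction is defensible; `pooled` is the
  default and both are reported with `--mode both`.
* The 0.56 anchor is an empirical property of one breast-tissue data
  set, not a constant of the method; cohorts from other tissues should
  re-derive it.
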