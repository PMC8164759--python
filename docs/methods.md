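# Methods

This note records the models, parameter choices and numerical decisions
behind `ihctme`, and what the synthetic benchmarks do and do not show
about real tissue data.

## Detection model

A field image is an 8-bit RGB brightfield photomicrograph with a known
physical pixel size (reference geometry 2560 × 1920 px at 0.11 µm/px,
i.e. a 282 × 211 µm field at ×200 magnification).

**Stain separation.** Two chemistries are modeled. Nickel-enhanced DAB
without counterstain (`dab_ni_no_counterstain`, the FoxP3 protocol)
produces near-black nuclei on a light background; its OD map is the
mean gray optical density −log₁₀(I/255) over channels, which is robust
because the chromogen is the only absorber. Plain DAB over Mayer's
hematoxylin (`dab_with_hematoxylin`, the IDO protocol) is separated by
Ruifrok–Johnston color deconvolution (`skimage.color.rgb2hed`); the DAB
channel of the deconvolution runs on a compressed OD scale, so the
model-specific thresholds below differ between chemistries.

**Melanin rejection.** Melanin is a desaturated dark brown, occupying a
hue/saturation/value region distinct from both chromogens: the gate
flags pixels with hue inside a band that wraps around 0 (default
(0.92, 0.15], because brown-gray pixels under noise fall on both sides
of hue 0), saturation in [0.10, 0.55] (full-strength DAB brown is far
more saturated, ≥ 0.75) and value ≤ 0.50 (faint DAB is brighter). The
flagged mask is dilated by 2 px so noisy pigment borders do not leak
into segmentation; flagged regions of candidate size are reported as
candidates with a `rejected_melanin` verdict so all tallies reconcile.
Hue + minimum saturation alone cannot separate melanin from weak DAB —
both are low-saturation browns — hence the saturation ceiling and value
ceiling; this is a property of the color model, not of any particular
image set.

**Segmentation and measurement.** Candidates are 8-connected components
of pixels with OD at or above a detection floor (0.08 gray-OD units for
DAB-Ni, 0.04 deconvolved-DAB units), restricted to the retained mask.
Components under 5 px are discarded as noise specks. Area, ellipse axes
(second moments), centroid, solidity and mean OD come from
`skimage.measure.regionprops`; physical units scale with the pixel
size, so doubling the pixel size doubles measured axes and quadruples
areas.

**Exclusion rules.** Applied in fixed order size → aspect → edge →
intensity; a cell's verdict is its first failing rule. Defaults: area
window [10, 120] µm² (lymphocyte-nucleus scale; the acceptance window
is configurable since no canonical value exists), aspect ratio ceiling
2.0 with strict `>` rejection (a ratio of exactly 2.0 is accepted), an
object touches the edge if any pixel lies on the first/last row or
column (`edge_margin_px` widens the band), and the intensity threshold
is max(Otsu over the OD map, absolute floor) — the floor (0.20 DAB-Ni /
0.12 deconvolved DAB) keeps blank or faint-only fields from promoting
background. An alternative background-mean + k·SD rule (k = 3) is
selectable.

**QC flag.** A field needs manual review when the candidate count
before exclusions exceeds 3× the accepted count, or mean candidate
solidity drops below 0.8. This models the manual-verification step of
hotspot workflows without claiming any specific published criterion.
Two limitations are intrinsic: a deeply merged pair of round nuclei is
geometrically indistinguishable from a single nucleus (we measured
union solidity > 0.86 across simulated clumps, never below 0.8), so
silent under-counts of isolated pairs pass QC — which is precisely why
such workflows keep a human in the loop; larger clumps, by contrast,
breach the area window, get rejected for size and trip the ratio rule.

The same engine serves DAB-with-hematoxylin counting (e.g. IDO-positive
stromal cells), an extension beyond the nuclear-marker case it was
designed around.

## Hotspot aggregation

Per lesion, k = 3 fields for lesions under 2 mm² and 5 otherwise
(threshold configurable; the 3-versus-5 rule by lesion size is standard
practice, the numeric threshold is this package's choice). The k
tumor-containing fields with the largest accepted counts are selected,
ties broken by ascending field index; the per-sample value is the
arithmetic mean of the selected counts. The mean is chosen because it
is the simplest statistic that yields the half-integer per-sample
values (e.g. 56.5) characteristic of published hotspot medians computed
from integer counts; sum and median variants would also be trivial to
expose if needed.

## IDO tumor-cell scoring

Published coverage labels are integer-percent ranges (< 1 %, 1–5 %,
6–10 %, 11–20 %, > 20 %) that leave gaps on a continuous scale; the
implementation closes them with the half-open partition
[0, 1 %) → 0, [1 %, 5 %] → 1, (5 %, 10 %] → 2, (10 %, 20 %] → 3,
(20 %, 100 %] → 4, so every fraction maps to exactly one category and
the category is non-decreasing in the fraction. Intensity (1 weak,
2 moderate, 3 strong) is recorded only for IDO-positive tumors
(> 1 % coverage) as the modal per-cell category, ties resolved toward
the lower category (whether the original scoring was per-cell-then-
aggregated or holistic is unknowable from the published description;
the modal rule is our documented interpretation of "predominant
deposit"). Intensity groups collapse 2 and 3 into moderate_or_strong.
Median dichotomization assigns values equal to the threshold to "low"
(configurable), making the split deterministic under ties.

## Cohort statistics

- Pearson χ² for 2×2 tables is the uncorrected statistic
  N(ad − bc)²/(r₁r₂c₁c₂) with df = 1; no Yates correction, which is the
  variant consistent with the published p-values this package
  reproduces (e.g. [[11,10],[17,4]] → p = 0.050). Zero margins raise.
- Kruskal–Wallis uses the tie-corrected H with the χ² approximation;
  all-tied input is defined as H = 0, p = 1.
- Post-hoc pairwise comparisons are Dunn's z-tests on pooled ranks with
  the tie term Σ(t³−t)/(12(N−1)) and Bonferroni adjustment
  min(1, m·p) over m = k(k−1)/2 pairs — the de facto companion of the
  Kruskal–Wallis test in mainstream statistics packages; implemented
  directly since no installed library provides it.
- Mann–Whitney U is exact when both samples have ≤ 8 observations and
  no ties, otherwise the tie-corrected normal approximation.
- Survival: Kaplan–Meier product-limit curves and the two-group
  log-rank test; Cox proportional hazards via lifelines with Efron tie
  handling (the modern default). Non-convergence and separation raise
  an explicit error type.
- Missing data: complete-case per test; every TestResult carries the n
  actually used. The significance threshold is α = 0.050, inclusive.
  No multiple-testing correction is applied across the report's test
  families, matching the analysis plan the pipeline reproduces.

`run_full_analysis` emits all of the above as a JSON-ready report;
degenerate inputs on random cohorts (a zero χ² margin, an event-free
survival stratum) are reported per-test as errors rather than aborting
the run.

## Synthetic data: what it emulates, and what it does not

**Field images.** Positive nuclei are ellipses with major axis
6–10 µm and aspect ratio ≤ 1.7 (comfortably inside the acceptance
rules); each distractor class breaches exactly one rule: "too large"
objects have ≥ 2× the maximum acceptable area, "elongated" objects
aspect 2.5–4.0, "faint" objects are alpha-blended to sit between the
detection floor and the intensity threshold, "edge" objects are circles
whose center sits 0.35–0.6 radii inside a border so only a cap is
clipped (keeping size and aspect acceptable), and melanin granules have
acceptable geometry but pigment color. Objects are placed without
overlap (bounding-circle separation with a 5 px margin) unless the
overlap mode is enabled, which chains positives into clumps of
`overlap_clump_size` members at center distance
(1 − overlap_fraction)·(r₁ + r₂) to emulate touching nuclei; clumps
merge into single components, under-count the field and generally trip
QC. Gaussian pixel noise (SD 3 by default) is added throughout.
Determinism is pixel-exact in the seed.

Not emulated: tissue texture, uneven illumination, stain gradients,
out-of-focus blur, overlapping cell layers, whole-slide formats.
Passing detector tests on these images therefore demonstrates the
correctness of the rule logic, color gating and measurement chain — not
robustness to real-slide artifacts, which would require stain
normalization and texture models explicitly out of scope.

**Cohort tables.** Six histological groups (benign nevi, dysplastic
nevi, in situ melanoma, pT1 < 1 mm and pT4 > 4 mm primary melanoma,
nodal metastasis) with default sizes 25/27/15/36/39/41. Hotspot counts
are means of 3 (non-invasive) or 5 (invasive) per-field negative-
binomial draws (NB2, shared dispersion 4) with group-specific means
rising from benign to metastatic — overdispersed counts are the
standard choice for cell-count data, and the field-mean construction
reproduces the half-integer sample values real hotspot data show. IDO
coverage categories are drawn per group from 5-vector probabilities,
with the continuous fraction uniform inside the drawn bin. Recurrence
(invasive groups only) is logistic with a group baseline and an odds
ratio (default 4, the order of magnitude implied by published 2×2
recurrence tables) on IDO positivity; death times are exponential with
the hazard multiplied by a recurrence hazard ratio (default 2);
censoring is independent exponential calibrated to a 30 % rate;
recurrence-free survival takes the earlier of recurrence and death.
Covariate prevalences (ulceration, nodular growth, mitoses, capsule
rupture) are group-specific; ~2 % of covariate values are set missing
at random, emulating the small per-variable missingness of real cohort
tables.

`CohortSimParams.null()` flattens every group difference and effect —
equal count means, equal coverage distributions, OR = 1, HR = 1, equal
covariate prevalences — which is the configuration used for
type-I-error calibration.

Because both markers share the group structure, the default synthetic
cohort's between-marker correlation (r ≈ 0.85) is substantially higher
than typically reported for real marker pairs; the generator reproduces
the direction and machinery of such associations, not their published
magnitudes, which depend on unpublished patient data.

`simulate_survival()` is a separate, minimal benchmark (binary
covariate, exact exponential hazards with a programmed hazard ratio,
independent censoring) used for Cox parameter recovery. The full cohort
generator is unsuitable for that purpose by design: its observed
recurrence flag is a censored version of the latent recurrence driving
the hazard, which attenuates the estimable hazard ratio — a realistic
feature, but a confounded estimand for an estimator benchmark.

## Verification design

- Every statistic is checked against an independent oracle: exact
  rational rank arithmetic (Kruskal–Wallis), pair counting and label
  enumeration (Mann–Whitney), exact-fraction covariance (Pearson r),
  scipy's expected-count route (χ², whose implementation here is the
  closed-form margin formula), hand risk tables (Kaplan–Meier,
  log-rank) and direct partial-likelihood optimization (Cox).
- Detector validation compares accepted counts and per-object verdicts
  with construction-time ground truth across 200 seeded fields under
  both stain models, at quarter-scale geometry (1280 × 960 px at
  0.11 µm/px) with object counts scaled to the reference density —
  the physics is unchanged, the suite stays fast.
- Type-I-error calibration runs the full analysis on 1,000 null
  cohorts (30 per group) and requires every monitored test's rejection
  rate inside the 99 % binomial interval around α = 0.05
  ([0.032, 0.068]). Fourteen simultaneous 99 % checks carry a
  non-trivial chance of a false alarm from Monte-Carlo noise alone, so
  the check is sequential: a violation on the primary block must be
  confirmed on an independent 3,000-replicate block against the same
  numeric bounds. Genuine miscalibration fails both stages; a sampling
  excursion does not survive replication. (For the smallest subgroup
  test — intensity × capsule rupture at n ≈ 14 — large-replicate
  simulation puts the true size of the asymptotic χ² at ≈ 0.055:
  slightly anticonservative, inside the required band.)
- Parameter recovery: the median Cox hazard-ratio estimate over 200
  simulations (n = 500, programmed HR 2.0) must fall in [1.8, 2.2];
  Kruskal–Wallis must detect a 3-SD negative-binomial location shift
  (n = 40/group) in ≥ 95 % of 500 replicates.

Problem sizes throughout (field geometry, replicate counts, cohort
sizes) are the package's own benchmark design choices, selected to make
each check individually well powered.

## Known limitations

- The color model assumes the synthetic stain palette; real slides
  need per-batch tuning of the melanin band and OD floors (all
  criteria fields are configurable).
- No nucleus splitting beyond connected components: touching nuclei
  under-count, by design surfaced through QC rather than resolved.
- Tumor-versus-stromal cell identity for IDO scoring comes from ground
  truth or a supplied mask; the package does not discriminate melanoma
  cells from fibroblasts or endothelium.
- The survival generator uses exponential baselines; it calibrates
  estimators, not hazard-shape robustness.
- Overall- and disease-specific-survival analyses are implemented but
  have no numeric reference values.
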