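# Methods

`nptpredict` implements an analysis pipeline for predicting the outcome of a
grass-pollen nasal provocation test (NPT) in poly-sensitized pediatric
patients with seasonal allergic rhinitis, from component-resolved IgE
serology and season-windowed e-diary records. This note documents the model
choices, the tunable parameters, and the limits of what the synthetic data
can show.

## The clinical problem and the quantities computed

An NPT is the reference test for deciding which of several sensitizations is
clinically dominant, but it is demanding to perform. The pipeline evaluates
cheap predictors of its binary outcome:

* **IgE-specific activity.** For an analyte (an extract such as timothy
  grass, or a molecule such as Phl p 5), the specific activity is the share
  of the total IgE pool bound to it: `(sIgE / total IgE) * 100`, in percent.
  For a combination of analytes the kU/L levels are summed first, so the
  combined activity of Phl p 5 + Cyn d 1 equals the sum of the two component
  activities. Normalizing by total IgE makes patients with very different
  overall atopy comparable; in poly-sensitized children it discriminates the
  NPT outcome better than raw kU/L levels.
* **Season-windowed diary summaries.** Daily RTSS (0–18), CSMS (0–6) and VAS
  (0–10) scores are reduced, over the days with high airborne grass pollen
  (>30 grains/m³) inside the peak season, to the maximum and the coefficient
  of variation `CV = 100 * SD / mean` (sample SD, n−1). Restricting to high
  days limits confounding by co-seasonal pollens (olive, pellitory).
* **ROC / optimal cutoff.** Empirical AUC (ties 0.5), Hanley–McNeil standard
  error and a two-sided normal test against AUC = 0.5. Cutoff candidates are
  midpoints between adjacent distinct scores plus two sentinels; the optimum
  maximizes Youden's J = sens + spec − 1 under the rule "positive if score ≥
  cutoff", with ties broken by higher specificity, then lower cutoff.
* **Logistic model.** `P(NPT+) = expit(b0 + b1·VAS + b2·activity)` fitted by
  Newton–Raphson (score tolerance 1e-8, step tolerance 1e-10, max 25
  iterations), Wald inference from the inverse observed information,
  Nagelkerke R², likelihood-ratio model χ², classification accuracy at
  p ≥ 0.5, and the Box–Tidwell check (augment with `x·ln x`; a significant
  augmentation term flags non-linearity in the logit). Non-convergence or
  any |coefficient| > 15 raises a distinct separation error instead of
  returning meaningless estimates.
* **Combined decision rule.** Call NPT-positive when combined activity
  ≥ 7.25% OR retrospective severity VAS ≥ 7 (both inclusive; combinator and
  cutoffs configurable). Confusion-matrix metrics are reported as half-up
  percentages at one decimal; counts can also be reconstructed from printed
  sensitivity/specificity pairs by half-up rounding, the unique convention
  consistent with published PPV/NPV columns of this kind.

## Statistical primitives

The two-group and 2×2 tests are implemented from first principles so every
p-value is auditable; library implementations appear only as oracles in the
test suite.

* **Mann–Whitney U**: ties count 0.5. Exact two-sided p by enumeration of
  all rank assignments when the pooled sample has ≤ 12 observations and no
  ties; otherwise the normal approximation with tie-corrected variance and a
  0.5 continuity correction.
* **Fisher exact (2×2)**: two-sided by the probability-mass method, computed
  in exact integer arithmetic over the hypergeometric family with fixed
  margins. A zero margin gives p = 1 with a warning.
* **Yates-corrected χ² (2×2)**: |O−E| reduced by 0.5 per cell, 1 df. The
  group-comparison stage uses Fisher when any expected cell is below 5
  (Cochran's rule) and Yates otherwise, since "χ² with Fisher's correction"
  is ambiguous in common clinical usage.

## Pollen season handling

Days are classed low (<10 grains/m³), medium (10–30, both ends inclusive)
and high (>30, strict) using central-Italian aerobiological cut-offs. Season
windows come from a run rule: the season starts on the first day of the
first run of R consecutive days at or above T and ends on the last day of
the last such run (defaults R = 3, T = 10 for the whole season, T = 30 for
the peak). Published station calendars usually provide precomputed dates,
so fixed window overrides are accepted and returned verbatim; the 2016 Rome
windows (13 Apr–28 Jul whole, 4 May–28 Jun peak) ship as constants.

## The synthetic cohort generator

The study population is not publicly deposited, so the generator emulates
its structure; its defaults are the study conditions:

* 72 patients, NPT-positive prevalence 0.847; age ≈ N(14.3, 2.8) clipped to
  4–18; male fraction 46/72.
* Total IgE lognormal with median 421 kU/L and log-scale SD 0.97 (chosen so
  the quartiles sit near the reported 199–737 kU/L), floored at 2 kU/L.
* Per analyte: sensitization is Bernoulli with a group-specific rate
  (e.g. Phl p 5: 64% in NPT-positives vs 18.2% in negatives); sensitized
  patients draw a lognormal level around a group-specific median with shape
  sigma = 1.5 (serum IgE spans decades), clipped to the semi-quantitative
  assay range [0.1, 100] kU/L; non-sensitized patients are coded exactly at
  the 0.1 floor, matching the "0.10 (0.10–0.10)" pattern of such assays.
  Levels are additionally kept below the patient's total IgE, and the sum
  over all analytes is scaled to at most 90% of total IgE so that every
  combined activity is a valid percentage.
* Retrospective VAS scores are rounded truncated normals (SD 2) around group
  medians 7/5 (severity, positive/negative) and 8/7 (drug efficacy).
* The pollen series is a Gaussian-in-time hump (peak day 65, width 22 days,
  height 120 grains/m³) with lognormal day-to-day noise (sigma 0.35), rounded
  and capped at 199 grains/m³ — the recorded range of the emulated season.
* Diaries: each score is `baseline + slope · log1p(pollen) + scale · latent +
  noise`, rounded and clipped to its instrument range, where the per-patient
  latent is normal with mean 1.2 for NPT-positives and 0 otherwise (SD 0.8).
  Medication intake is Bernoulli with probability rising in the day's VAS.
  Slopes (RTSS 1.6, CSMS 0.5, VAS 0.9 per log-unit of pollen) were chosen
  once so that high-day VAS maxima fall near the observed group medians.
* One master seed; each stage (cohort, pollen, diary) uses a named
  substream, so stages regenerate independently and output tables are
  byte-identical across runs.

What the generator does **not** model: medication effects on symptoms, any
SPT–IgE discordance mechanism beyond shared NPT-group membership, joint
correlation between SPT wheal and IgE levels, dose-response of the NPT, or
diary non-adherence (every patient fills every day). Passing tests on
synthetic data therefore demonstrate the correctness and calibration of the
*computations*, not the clinical performance of the predictors on real
patients.

## Numerical conventions and edge cases

* Percentages are rounded half-up (Decimal, not banker's rounding) to one
  decimal in tables; full precision is kept internally.
* Quantiles/IQRs use linear interpolation.
* CV of an all-zero vector is 0 (0/0 convention); fewer than two observed
  high days give a missing CV and exclude the patient from CV-based
  comparisons — diary non-entry is not imputed as symptom-free.
* Below-LOD IgE enters the activity formula at the 0.1 kU/L floor by
  default (configurable to zero); the emulated assay codes undetectable
  responses at the floor.
* The combined rule decides on the single observed criterion when one input
  is missing (counted and reported); patients missing both are excluded.
* Degenerate inputs: constant ROC predictors are flagged, not fatal; a
  constant comparison variable skips its test; zero-margin 2×2 tables warn
  (Fisher) or raise (χ²).
* In the orchestrated pipeline a quasi-separated logistic fit (possible in
  small cohorts with ~15% negatives) is reported as "not estimable" while
  the remaining stages complete; calling `fit_logistic` directly raises.

## Known limitations

* The "OQM" (overall quality of the model) column style of some published
  ROC tables has no stated formula and is not reproduced.
* AUC inference is Hanley–McNeil against 0.5 only; correlated-ROC
  comparisons (DeLong) and bootstrap cutoff CIs are out of scope.
* The logistic model treats VAS as continuous; Wald (not profile) CIs.
* Fixtures and acceptance runs use the study-scale cohort (n = 72) for the
  ROC and rule stages and n = 200 for logistic summaries, where the fit is
  reliably estimable.
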