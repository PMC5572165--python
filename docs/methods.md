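# Methods

This note documents the statistical procedures, conventions and design
choices implemented in `ocpanel`, and what the synthetic-data experiments
do and do not establish.

## Data model and conventions

A cohort is a set of women (cases with a tumour subtype, matched controls)
each contributing serial serum samples indexed by time to diagnosis (tDx,
days). Conventions fixed once and used everywhere:

- **Month length** 30.4375 days (365.25/12); **year** 365.25 days. The
  discovery split keeps, per woman, the nearest-to-diagnosis sample with
  tDx < 14 months (426.125 d) and the nearest-to-diagnosis sample with
  tDx > 32 months (974.0 d); women lacking a window keep what they have,
  with a logged warning.
- **Borderline tumours are grouped with Type I** at ingest; the raw label
  is preserved on the subject.
- Controls have no diagnosis of their own; their samples carry a
  **pseudo-tDx** inherited from the matched case's diagnosis reference,
  which enables time-binned control comparisons. Pooled controls (ignoring
  pseudo-tDx) are the default specificity denominator; per-bin control
  specificity is available.
- Time bins are half-open `[lower, upper)`; the default screening bins are
  yearly up to 4 years with everything beyond pooled into one open bin.
- Missing values are explicit (empty cells), never zeros.

## Threshold panels

A marker rule is a directional cutoff in native units; breach is a
**strict** inequality (a value exactly at the cutoff is negative, matching
the published "> / <" operating points). A panel ORs its rules.

Calibration at target FPR α places the cutoff at an order statistic of the
n control values: the ⌈(1−α)n⌉-th for up-regulated markers, the
(⌊αn⌋+1)-th for down-regulated ones. With strict breach this makes the
in-sample FPR at most α by construction, and the out-of-sample FPR
converges to α (verified by Monte-Carlo in the tests). CA125 keeps its
fixed 35 U/ml referral cutoff by default; the published fixed thresholds
(78.5 / 8.831 / 16.1 / 35) are first-class and can be applied verbatim.

Sensitivity is **per sample** within a stratum × bin cell by default
(binned tables count samples); a per-woman mode (any sample in the cell
positive) exists because the per-sample/per-woman choice is a genuine
reporting ambiguity in this kind of analysis. Missing marker values
contribute a negative call under the default policy (logged), or raise in
strict mode. Empty cells are emitted with n = 0 and undefined rates rather
than dropped.

ROC for an OR panel is not canonically defined; the implemented sweep
parameterizes *all* rules by a common calibration FPR α (CA125 swept
through its own control quantiles), evaluates the panel at each α, anchors
the empirical (FPR, TPR) staircase at (0,0) and (1,1), and integrates by
trapezoid. This one-parameter family contains the α = 0.05 operating
point used everywhere else.

## Significance machinery

All tests are two-tailed. Mann–Whitney uses the exact null distribution
when n₁·n₂ ≤ 400 and the pooled sample is tie-free, else the tie-corrected
normal approximation. Fisher's exact test sums hypergeometric
probabilities ≤ the observed table's. McNemar's test on the discordant
counts is the exact binomial(b+c, ½) version when b+c < 25, else the
continuity-corrected chi-square. Lead-time comparisons use a paired t-test
on first-breach tDx over the both-detected intersection. Survival curves
are compared by the standard two-group log-rank test (the natural
companion to Kaplan–Meier when no test is otherwise specified). No
multiple-testing correction is applied by default (raw p-values are
reported); Benjamini–Hochberg is available as a helper.

The implementations delegate to scipy.stats, statsmodels and lifelines;
the test suite verifies them against independent enumeration oracles
(exhaustive assignment enumeration for Mann–Whitney, hypergeometric and
binomial tail sums for Fisher/McNemar, a hand O−E tabulation for the
log-rank statistic, label permutation for p-value accuracy). At n = 10
with all events the 1-df chi-square reference for the log-rank test is
accurate only to several percentage points against the exact permutation
law; the tests bound that gap at 0.08.

## Lead time

A woman's lead time under a panel is the tDx of her **earliest** breaching
serial sample (the largest breaching tDx). Women never detected are
excluded from means, never imputed as zero. Model-level means average over
each model's own detected set by default; an "either-detected" mode is
provided (for an OR-superset panel the two modes differ only in the
reference's averaging set, since the superset detects every woman the
reference does). A woman counts as detected earlier than the reference if
the reference missed her entirely or her first breach precedes the
reference's; detection gains are reported as whole-number percentages of
the stratum's case count. Pooled means are subject-weighted,
Σ(meanᵢ·nᵢ)/Σnᵢ — exactly the mean over the concatenated detected women.
Note the per-model averaging set caveat: a panel that detects *additional*
late-detected women can show a diluted stratum mean even though it
first-breaches no later than the reference on every shared woman.

## Prognosis

A woman is a breacher if **any** of her serial samples is positive
(pre- or post-calibration samples are not distinguished; "samples that
breached" is read as any serial sample). Post-diagnosis survival (days
from diagnosis to death, right-censored) is estimated per arm by the
Kaplan–Meier product-limit estimator (deaths precede censorings at tied
times) and compared by log-rank. Women without survival data are excluded
with a logged count; an empty arm returns a single curve and skips the
test.

## Synthetic cohort generator

The generator emulates the *structure* of a nested case-control serial
collection, not real concentrations. Defaults (chosen once):

- **Design**: 19 Type I (10 borderline) + 30 Type II cases, 31 controls
  matched round-robin to the Type II women; serial samples on a jittered
  grid (first sample uniform in 30–420 d, subsequent steps 430 d × U(0.7,
  1.3)) truncated at 84 months, guaranteeing every woman a <14-month
  sample; ~480 samples per cohort.
- **Markers**: log-normal. Control log-means are anchored so that the
  published cutoffs sit at the 5%/95% control quantiles (e.g. IGFBP2
  log-mean = log 78.5 − z₀.₉₅·0.5); CA125 controls have median 13 U/ml so
  the 35 U/ml referral cutoff is its ~97th percentile. Case log-means
  drift linearly from a marker-specific change-point to a full effect at
  diagnosis, in control-SD units with per-subtype scaling: IGFBP2 +1.2 SD
  (change-point 900 d), LCAT −1.0 SD (800 d), SHBG −0.9 SD (1100 d),
  CA125 +2.0 SD (550 d; ×1.2 in Type II, ×0.8 in Type I), GRP78 and
  calprotectin null. IGFBP2/LCAT drifting *earlier* than CA125 is what
  gives the combined panel its lead-time advantage. Effect magnitudes are
  loosely anchored to the per-woman detection fractions the motivating
  analysis prints (roughly 40–60% of case women detected by the combined
  panel).
- **Within-woman correlation**: each woman draws a per-marker baseline;
  80% of the log-SD is between-women (`subject_sd_frac = 0.8`), the rest
  is serial noise. The split leaves each sample's marginal distribution
  unchanged — so the closed-form sensitivity below stays exact — while
  keeping per-woman false-breach accumulation over ~6 serial samples at a
  realistic level. With fully independent draws, ~85% of Type II women
  breach the reference panel and the prognosis analysis degenerates.
- **Markers are independent given subtype and tDx** (a Gaussian-copula
  correlation hook is a possible extension, off by default): this keeps
  the analytic oracle exact.
- **Survival**: exponential per subtype (baseline medians ≈ 8.2 y Type I,
  3 y Type II), a ×3 hazard for women whose generated trajectory breaches
  the analytic reference panel (IGFBP2/LCAT at exact α = 0.05 control
  quantiles, CA125 at 35), and independent exponential censoring (median
  ≈ 11 y). This plants the prognostic signal the Kaplan–Meier stage is
  meant to recover.
- **One seed** drives a single `numpy` generator; identical seeds give
  byte-identical cohorts.

### Closed-form sensitivity oracle

With thresholds at exact α control quantiles and independent Gaussian
log-levels, a case sample at tDx breaches rule i with probability
Φ(|δᵢ(tDx)| − z₁₋α), where δᵢ is the standardized mean shift implied by
the marker model, so the OR panel's per-sample sensitivity is

    1 − Πᵢ (1 − Φ(|δᵢ(tDx)| − z₁₋α)).

The tests verify simulated sensitivities against this closed form within
3 binomial standard errors across a grid of effect sizes and α values.

### What the synthetic experiments show — and don't

Passing tests establish that the pipeline recovers planted structure:
calibrated FPRs, analytic sensitivities, lead-time direction (the
combined panel beats CA125's mean lead in ≥95% of replicate cohorts), and
the prognostic direction. They do **not** validate the clinical claims on
real sera: real marker levels are correlated across markers, assay noise
is heteroscedastic, real trajectories are not log-linear, and diagnosis
times interact with screening schedules. Reported example p-values on
synthetic cohorts are illustrations, not evidence about the markers.

A power note: with 30 Type II women split ~2:1 by breach status and a
hazard ratio of 3, the log-rank test's power is intrinsically ~0.6–0.7
(even a balanced clean two-sample benchmark at these sizes reaches only
~0.74), so the prognosis direction-recovery suite asserts rejection "in
most replicates" and a below-lying breacher curve, not near-certain
rejection.

## Numerical choices

- Log-scaling for display uses natural logs and the **population** SD
  (ddof = 0) of the reference stratum (all samples by default,
  controls-only as a sensitivity analysis), so the reference stratum has
  variance exactly 1. Non-positive concentrations are floored at half the
  smallest positive observed value (logged), or rejected in strict mode.
- Rank tests run on raw concentrations: Mann–Whitney is invariant to the
  monotone log/z display transform, so this is consequence-free.
- Ties at a threshold are negative; ties in survival put deaths before
  censorings; the degenerate all-zero Fisher table and the
  zero-discordance McNemar both return p = 1 with a warning.
- The pooled lead-time arithmetic reproduces the worked figures
  (454 d, 8) + (272 d, 17) → 330.24 → 330 and (315 d, 8) + (165 d, 17) →
  213; the corresponding difference is 117 days (the arithmetic value is
  reported as such).

## Known limitations

- No AND/weighted/logistic rule combinations and no longitudinal risk
  algorithms — OR-rule threshold panels only.
- No Cox regression or covariate adjustment in the prognosis stage.
- No batch/plate normalization; the cohort table is assumed
  assay-harmonized.
- The generator's marker independence and exponential survival are
  deliberate simplifications chosen for oracle exactness, not realism.
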