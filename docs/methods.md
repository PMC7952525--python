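# Methods

This note documents the models, conventions and design choices behind the
package; the README covers usage. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Derived hemodynamics

Flows assume a circular vessel cross-section and are indexed to body
weight: `flow = (d²/4)·π·VTI·HR / weight`, with diameters and
velocity-time integrals in cm (so the product is mL), heart rate in
beats/min and weight in kg. The SVC uses the arithmetic mean of its
maximum and minimum M-mode diameters, since the vein is non-circular over
the cardiac cycle. Averaging over consecutive cardiac cycles (3–5 for SVC
diameter, 5–10 for SVC VTI, 3 for the aortic VTI) is done with
`cycle_average` *before* an `EchoExam` is constructed; the exam is a flat
record of already-averaged values. Units are deliberately mixed by
clinical convention: transductal diameter in mm (the staging unit),
LPA diastolic velocity in cm/s, vessel diameters/VTIs in cm. The CSV
reader accepts LPA velocity in m/s via `lpa_units="ms"` because published
tables use both conventions for this variable.

## The staging score

Four severity markers are staged ordinally and summed (maximum 11,
minimum 0). Boundary convention: the printed middle ranges ("1.5–3",
"1.5–2", "30–50") are **closed on both ends**; "<x" bins are open at x and
">y" bins open at y. This makes every numeric row an exact partition of
[0, ∞), and a measurement sitting on an upper boundary takes the milder of
the two adjacent categories. A diameter of exactly 0 encodes "no duct
visible" and forces a zero Vmax/Vmin ratio at the `EchoExam` level (the
two are measurements of the same structure); the staging code itself does
not force the aortic-flow component to "forward" for a closed duct — it
stages whatever is recorded. A missing staged measurement raises an error
naming the field; no imputation is attempted, because a patent duct with
an unmeasured Doppler ratio is not scorable without inventing data.

Alternative candidate schemes can be supplied as JSON (`load_scheme`),
which validates that bins neither gap nor overlap; scheme comparison is
done on discrimination (`compare_schemes`), not built in, because only the
final published component set is public.

## The closure model

`published_model()` carries the fixed coefficients
(−28.41, +1.23/week, −0.87/point). Gestational age is continuous decimal
weeks (27 weeks + 3 days → 27.43); the reader also accepts "27+3" text.
Because the printed coefficients are rounded to two decimals, exp(1.23) =
3.42 rather than the originally reported 3.44 per week; all odds-ratio
output is derived from the stored coefficients, and the discrepancy is
accepted rather than back-solved. The published model carries **no
covariance**: confidence-interval queries on it raise an error instead of
reconstructing intervals from printed, rounding-inconsistent bounds.
Fitted models (below) do carry a covariance and share the same container
and JSON format.

## Fitting and backward elimination

`fit_logistic` maximises the Bernoulli log-likelihood by IRLS
(Newton-Raphson), converging when the largest coefficient update is below
1e-8, capped at 50 iterations; the covariance is the inverse observed
information at the optimum. Covariates are used unstandardized so
coefficients stay on the clinical scale; standardization is internal to
the separation check only (|β·sd| > 30 flags complete or quasi-complete
separation as a warning — the fit is returned, not silently repaired).
Ties in backward elimination (largest Wald p ≥ `alpha_stay`, default
0.05) are broken toward the smaller squared Wald statistic, then the
lexicographically smaller name, so traces are deterministic. Single-
covariate removal per step is assumed; the model is refitted after every
removal. Note that with `alpha_stay = 0.05` each pure-noise covariate
survives the procedure with probability ≈ 0.05 by construction — backward
elimination does not control the family-wise false-selection rate.

## ROC and diagnostic performance

Candidate thresholds are the midpoints between adjacent distinct score
values plus ∓∞ sentinels, so integer scores yield half-point cut-offs
(e.g. 4.5). The trapezoidal area of this curve equals the Mann-Whitney
estimator P(score⁺ > score⁻) + ½P(tie) — both are implemented and asserted
equal to 1e-12. Youden's J is maximised with ties broken toward higher
sensitivity, then the lower threshold.

Orientation: the *positive* class is the treated (hsPDA) group and
test-positive means score **above** the cut-off. This is the only
orientation in which a sensitivity of ~0.90 and specificity of ~0.86 with
21/42 group sizes are jointly consistent with a PPV of ~0.76 and an NPV of
~0.95 (check: `predictive_values_from_rates(0.90, 0.86, 21/63)` →
(0.76, 0.95)); reporting layers re-express this as "a score below the
cut-off predicts early spontaneous closure". Proportion intervals use the
Wilson score method, which reproduces the reference 19/21 and 36/42
intervals (0.71–0.97, 0.72–0.93) at two decimals. PPV/NPV with an empty
margin are returned as NaN with a `defined=False` flag, never as 0. No
analytic CI for the AUC is produced (the method behind the published AUC
interval is unstated; DeLong/bootstrap variance is out of scope).

## Cohort statistics

Continuous variables: median and quartiles by inclusive linear
interpolation (numpy's default "linear" percentile method; printed IQRs
cannot discriminate between quartile conventions, so the common default is
used). Group comparison uses the two-sided Mann-Whitney U: exact
enumeration when n₁·n₂ ≤ 400 and the pooled sample is tie-free, otherwise
the normal approximation with tie-corrected variance and continuity
correction; a zero-variance pooled sample returns p = 1 with a flag.
Binary variables: Fisher's exact test when any expected count is below 5,
otherwise the Pearson chi-square (no continuity correction). The
Kruskal-Wallis test is omitted: only two groups are ever compared here.
Observer agreement uses ICC(2,1) — two-way random effects, absolute
agreement, single measurement — computed from the mean squares of the
two-way decomposition; this is the standard reliability form, chosen
because the source analysis does not specify one, and users should note
that the absolute-agreement form is sensitive to systematic rater offsets.

## Synthetic cohort generator

The generator emulates a two-group screening-echo study: 42 conservatively
managed (CM) infants with largely closing ducts and 21 ibuprofen-treated
(IBT) infants with significant ducts; group membership doubles as the
outcome label (treated = no early spontaneous closure), mirroring the
operational outcome definition. Defaults are the published per-group
summaries; they are study conditions, not tuning knobs.

**Marginals.** Each continuous variable is specified by its group median
and quartiles and sampled through a *quantile-spliced normal*: below the
median the quantile function is that of N(median, σ_lo), above it
N(median, σ_hi), with σ = (quartile distance)/0.6745, then clipped to a
physiologic window (GA ∈ [23, 29) weeks per the eligibility criterion,
screening age ∈ [18, 72] h per protocol, pH ∈ [6.9, 7.5], etc.). This
reproduces all three printed quartiles even when the IQR is asymmetric —
which a symmetric truncated normal with σ = IQR/1.349 provably cannot do
(e.g. treated LPA velocity 0.32 (0.17–0.38) m/s) — at the cost of a
density jump at the median and small boundary piles where clipping bites
(the pile at 18 h mimics the opening of the protocol window). Age at
closure uses a log-normal (right-skewed). The 5-min Apgar keeps its
printed q3 = median as a genuine ceiling mass at 8. Two printed rows are
internally inconsistent for any distribution — CM birth weight
"1056 (858–1056)" and treated cord pH "7.34 (7.31–7.34)", both with
q3 = median — and are repaired by mirroring the lower quartile distance
(q3 := median + (median − q1)); the calibration report checks against
these adjusted targets. LPA velocities are stored in cm/s (×100 from the
published m/s values, the unit the staging bins use).

**Dependence.** One latent severity per infant (standard normal within
group) drives the echo variables (diameter, velocity ratio, LPA velocity,
aortic flow direction, LA:Ao, LVO/SVC) through a Gaussian copula with
correlation ρ = `latent_correlation`; gestational age and birth weight
load on −severity (sicker infants are less mature). The default ρ = 0.5
is the largest value at which the *emergent* staged-score quartiles still
match their published group targets of 1 (0–4) and 7 (5–8.5) and the
population Youden cut-off sits at 4.5 (at ρ = 0.6 the CM score q3 drifts
to 5 and the cut-off to 3.5); higher ρ widens the score mixture because
severe components co-occur.

**Closed ducts.** In the CM group a closed-duct point mass (diameter =
ratio = 0, forward descending-aorta flow) is mixed with an open
"closing-duct" component; the weight solves
w + (1−w)·P_open(td ≤ 1.5) = 0.75 in closed form, so the group's published
diameter quartiles (0, 0, 1.5 mm) are reproduced exactly in distribution.
Closed CM infants keep a nonzero LPA diastolic velocity (the published CM
row prints diameter 0 but LPA 0.1 m/s), so their staged score is typically
1 — which is exactly what makes the published CM score median of 1
attainable. Descending-aorta direction is thresholded on its latent so
group reverse-flow prevalences hit 5% (CM) and 52% (IBT); the "absent"
prevalences (10% / 19%) and the SVC flow marginal (90 (70–110) mL/kg/min,
a typical neonatal range) are package choices, as is the open-component
tail shape beyond the published q3. LVO is derived as
LVO/SVC ratio × SVC flow rather than drawn independently.

**Calibration report.** `calibration_report` compares realized per-group
median/q1/q3 (or prevalence) to targets; the default tolerance is 15% of
the target IQR width per continuous variable, an absolute 1.0 for
integer-valued variables (score, Apgar), and an absolute 0.10 for
prevalences. At 5000 infants/group all 32 targets pass (asserted in the
test suite); at the 63-infant study size sampling noise dominates.

**What the generator does not emulate.** Serial (longitudinal) scans,
treatment response, measurement error/rater effects, the excluded
pulmonary-hypertension subgroup, and any real-data dependence structure
beyond the single-factor copula. Passing tests on these cohorts therefore
demonstrate correctness of the *analysis chain* and the self-consistency
of the published summary statistics — not external validity on clinical
data, which was never deposited.

## Problem sizes and seeds

Distribution-level checks use 5000 infants/group; discrimination and
cut-off behaviour use 20 study-sized cohorts (63 infants) with consecutive
seeds and are summarised by the median; parameter recovery simulates 2000
outcomes from the published equation on a scaled cohort. All randomness
flows through `numpy.random.default_rng` seeds recorded in the cohort's
`DataFrame.attrs`; identical seeds reproduce identical cohorts bit-for-bit.

## Known limitations

- The published-model round-off (3.42 vs 3.44 per-week odds ratio) is
  inherent to the two-decimal coefficients.
- The generator's CM score q1 realizes as 1 rather than the published 0
  (within the integer tolerance): a CM infant with *any* LPA diastolic
  flow scores at least 1, and the published marginals leave almost no mass
  at LPA = 0. A score of exactly 0 requires a fully silent duct, which the
  published CM LPA distribution essentially excludes.
- Empirical cohort-level p-values and the empirical AUC of the clinical
  study are not exactly reproducible (no deposited data); the synthetic
  cohort reproduces their statistical shape, not their realizations.
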