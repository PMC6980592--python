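# Methods

This note documents the models and procedures behind `traumastrat`: what
the score engine and statistics compute, what the synthetic cohort
generator emulates (and does not), the calibration, and the numerical
choices made where the design was genuinely open.

## Scope and data model

A patient record holds an admission physiology snapshot (blood pressure,
lactate, pH, base excess, platelets, fibrinogen, Quick value, INR,
transfusion counts at 2 h and 24 h, core temperature, regional injury
grades, GCS), anatomical severity (ISS, NISS, age), and the outcome
record: death with hour and cause (TBI, exsanguination, MOF, other) plus
adjudicated complication flags. Complication *diagnoses* are consumed as
recorded events, never derived from raw vitals; deriving them is out of
scope by design.

Units are fixed per field (mmol/L, g/L, mmHg, °C, Quick % of normal) and
readers never auto-convert. INR and Quick value are treated as two
independent coagulation measurements: both are accepted, neither is
derived from the other (the mapping between them is laboratory-dependent).
Missing measurements are represented as absent, never as sentinel values;
completeness is evaluated per score at stratification time.

**Early vs late complications.** Early: death within 72 h, death from
TBI, death from exsanguination. Late: pneumonia, sepsis, death from MOF.
The 72-hour boundary is closed (`death_hour <= 72.0` counts as early);
the convention is fixed here because the verbal definition "within 72
hours" does not decide the boundary case. Death hours are modelled as
continuous hours since admission.

## Score engine

Scores are declarative YAML documents: ordered strata, criteria grouped
by physiological pathway, per-criterion ordered cut values with explicit
inclusive/exclusive boundary flags (a band printed "< x" is exclusive,
"x or more" inclusive), and an aggregation policy. Cut values live in
versioned config files rather than code so that every threshold is
auditable and overridable; the shipped files are reconstructions of the
source publications' bands (the original grading tables are partly
ambiguous and partly overlapping) and are flagged as such in the file
headers.

Two aggregation policies are supported:

* **worst criterion** (CGS, mCGS, EAC): the patient's stratum is the most
  severe band reached by any single criterion. This is the only policy
  consistent with the monotone-severity property below when bands are the
  published "any of the following" type. A majority-vote policy is
  available as a config switch for sensitivity analyses.
* **point sum** (PTGS): each criterion's band awards points; the total is
  cut against a per-score point table. The shipped PTGS grades a patient
  borderline on any single borderline-band marker (1 point ≥ the
  borderline minimum) and unstable from 3 points.

A patient missing any *required* criterion parameter is
`not_stratifiable` and excluded from every downstream statistic; coverage
(stratified / total) is reported with each cohort stratification.

Structural properties, enforced by validation and checked by property
tests:

* cut values are strictly monotone in stratum severity, so worsening any
  single parameter never lowers the assigned stratum;
* stratification is a pure function of (patient, definition);
* the EAC stratum depends only on the three acid-base fields;
* the shipped mCGS never grades a patient more severely than the shipped
  CGS. The last guarantee needs one caveat: mCGS reads the 24-h
  transfusion count where CGS reads the 2-h count, and no choice of cuts
  can dominate pointwise for *arbitrary* count pairs (a patient with 0
  units at 2 h and 30 units by 24 h would break it). The shipped cuts
  (24-h bands at 10/20/60 vs 2-h bands at 2/5/>15) dominate whenever the
  transfusion trajectory satisfies `prbc_24h <= 3 * prbc_2h + 5`, i.e.
  massive late transfusion does not appear out of nowhere; the generator
  enforces this coupling and the property test samples under it. Late-
  only massive transfusion is outside the emulation.

## Statistics

All estimators are implemented from their defining formulas; scipy is
used only for distribution tails and mid-ranks. Established libraries
(scipy.stats, statsmodels, scikit-learn) appear in the test suite as
independent cross-checks, never as the implementation.

* **Odds ratio** (2×2): OR = ad/bc; 95% CI by the Woolf log-normal
  approximation, SE = √(1/a + 1/b + 1/c + 1/d); two-sided Wald p. If any
  cell is zero, 0.5 is added to every cell (Haldane–Anscombe) and the
  estimate is flagged. A zero margin is an error, not a number. The CI
  method is recorded in the result metadata because the choice is a
  convention, not a consequence.
* **Chi-square**: Pearson Σ(O−E)²/E with df = (r−1)(c−1); the Yates
  correction (|O−E| reduced by 0.5, floored at 0) is permitted only on
  2×2 tables. Zero expected counts raise with the offending cell named.
* **Krippendorff's alpha** (two ratings per unit): each unit contributes
  both ordered pairs to the coincidence matrix o_ck; with marginals n_c
  and N = Σn_c, α = 1 − D_o/D_e where D_o = Σ_{c≠k} o_ck δ_ck / N and
  D_e = Σ_{c≠k} n_c n_k δ_ck / (N(N−1)). Metrics: nominal (δ = 1 for
  c≠k), ordinal (squared span of marginal ranks), interval (squared value
  difference). The default for ordered strata is *nominal*, which matches
  the closed-form check used in the tests; ordinal and interval are
  options because agreement conventions differ between fields. Perfect
  agreement returns exactly 1; a single observed category makes D_e = 0
  and raises instead of returning a number.
* **Logistic regression**: maximum likelihood by iteratively reweighted
  least squares with internal predictor standardisation and
  back-transformed coefficients, Wald standard errors from the inverse
  Fisher information, step-halving to keep the likelihood monotone, and a
  tiny ridge fallback for exactly collinear designs. Convergence is
  declared when max|X'(y−p)| < 1e−8·n; the per-observation scaling is
  deliberate because an absolute score tolerance is not robustly
  attainable in double precision at n ~ 10⁵. Complete separation is
  detected (coefficient escape or saturated fit) and reported as a flag
  with `converged = False`, never as silent divergence.
* **ROC AUC**: the Mann–Whitney probability with ties counted ½,
  computed from mid-ranks; 95% CI from the DeLong variance of the
  placement values, clipped to [0, 1].
* **Multiple testing**: an optional Holm step-down adjustment over a
  user-declared family, off by default; no correction is imposed
  silently because the relevant test family is an analysis decision.

The prediction stage fits plain fixed-effects logistic models; no random
effects are included because no grouping factor exists in a single-centre
admission snapshot, and reported AUCs are in-sample (a cross-validated
variant can be built from the same pieces, but the shipped analyses
mirror a development-cohort design).

One documented discrepancy: the published 2155-patient mCGS×CGS
cross-tabulation yields a nominal coincidence-matrix alpha of 0.7666
(D_o = 646/4310, D_e = 1 − 6,643,388/18,571,790), and no standard alpha
metric (nominal, ordinal, interval) applied to those counts comes near
the coefficient printed alongside them (0.0459). The implementation
exposes the metric choice and the tests pin our value to the exact
rational oracle; the printed figure is treated as non-reproducible from
the published counts rather than chased.

## Synthetic cohort generator

The registry behind the validation is not publicly deposited, so the
package ships a generator that emulates the *statistical structure* the
analyses rely on, calibrated to the published cohort marginals. It is an
emulation declared as such — not an inference of the registry's true
generative process.

**Latent structure.** Each patient has an anatomical severity
S ~ Gamma(0.5, 25.93); ISS = min(round(16 + S), 75) (truncated mean 28.2,
sd 15.2), NISS = ISS plus a non-negative increment. Unit-variance
derangement axes are built from standardised severity: soft tissue
(loading 0.75), coagulation (0.65), hemorrhage (0.45), and a TBI proxy
(0.50). The acid-base axis has *zero* loading on severity and is instead
correlated (0.55) with the non-severity component of the hemorrhage axis:
acid-base derangement models a transient shock response that carries no
information about the slow, tissue-driven inflammatory pathways. This one
design choice encodes the central causal claim the pipeline is meant to
detect — acid-base derangement predicts early, shock-related outcomes and
nothing else — and makes the early/late signature hold by construction
rather than by numerical accident.

**Measurements** are monotone in their system's derangement with
realistic centres and noise (lactate log-normal around 1.6 mmol/L rising
with acid-base derangement; base excess falling; blood pressure falling
and transfusion counts rising with hemorrhage; platelets, fibrinogen and
Quick value falling and INR rising with coagulation; regional injury
grades rising with soft tissue). The 24-h transfusion count is the 2-h
count plus a bounded increment (the coupling above). Age is a normal
(μ = 32.72, σ = 28.25) resampled to ≥ 16 years, giving mean 45.8 and
sd 20.2 after truncation.

**Outcomes.** Early death (uniform hour in (0, 72]) is logistic in
(acid-base 0.85, hemorrhage 1.30); its cause is exsanguination with
probability logistic in (hemorrhage − TBI proxy), else TBI or other.
Among early survivors, MOF death is logistic in (soft tissue,
coagulation, severity, sepsis), and residual late death in (TBI proxy,
severity). Pneumonia is logistic in (soft tissue, coagulation, severity);
sepsis likewise with an additional +1.64 log-odds when pneumonia is
present, which produces the strong complication clustering needed for
the published "any complication" rate (24.7%) to sit far below the sum
of its parts (19.0% + 14.9% + 1.9%). Complication flags are sampled for
all patients, including early deaths, matching the registry convention
in which late-complication rates are tabulated over whole strata.
Missingness is applied last, independently per field
(missing-completely-at-random), with per-field rates chosen so the
per-score coverages land near the published ones (EAC ≈ 82.5%,
CGS ≈ 61%, mCGS ≈ 59%, PTGS ≈ 60%). Informative missingness is out of
scope.

**Calibration.** Severity and age parameters were solved analytically or
by bisection against the published moments; the outcome intercepts were
solved once by logit-step fixed-point iteration on cohorts of 600,000 and
frozen into `default_params()`. The early-death link strengths were
chosen so the nested-AUC profile reproduces the published pattern (acid-
base alone ≈ 0.71 here vs 0.67 published; full model ≈ 0.78 vs 0.76; the
gain is the structural point). Verification at n = 2,000,000: mortality
26.85%, pneumonia 19.05%, sepsis 14.93%, all complications 24.75%,
hemorrhagic-shock death 4.09%, MOF death 1.92%, mean ISS 28.19, mean age
45.78. A fixed seed yields a bit-identical cohort.

**What the generator does not emulate — and what tests therefore do not
show.** No time-series physiology (admission snapshot + outcome timing
only), no era effects or protocol changes over the registry period, no
informative missingness, no head-injury confounding of early death
beyond a severity-linked proxy, and no guarantee that the *registry's*
inter-score agreement or strata-wise odds ratios are reproduced
numerically — those depend on patient-level data that were never
published. Passing tests demonstrate that the pipeline computes the
right quantities and that the published *patterns* (unidirectional
mCGS shift, early-vs-late separation, AUC gain from multi-system
predictors, mortality monotone across grades) emerge from a cohort built
to contain them; they are not evidence about any real cohort.

## Analysis pipeline conventions

Every stage is complete-case for the scores or predictors it uses, so
different stages may analyse different subsets; subset sizes are always
reported. Odds-ratio tables use the score's lowest stratum as reference
and report empty strata as absent rather than OR 0. The nested prediction
models add predictor blocks in the fixed order acid-base → +coagulation →
+hemorrhage → +soft-tissue on the complete-case subset of the full set,
so the four AUCs are comparable. Strata-wise contingency ORs are plain
unadjusted contrasts; no model-based OR is attempted because any
covariate-adjusted registry model is unrecoverable from the published
material. Significance is two-sided at 0.05 throughout.

## Problem sizes

Default analysis sizes were chosen so the full suite runs comfortably on
one CPU: calibration checks use n = 100,000 (Monte-Carlo SE ≈ 0.14
percentage points on a 26.8% rate, well inside the ±1-point check), the
causal-signature analysis n = 50,000 (≈ 3,700 high-risk patients after
coverage, ample power for the early-death contrast while leaving the
null pneumonia/sepsis contrasts at chance level), and the exhaustive
estimator-vs-oracle sweeps enumerate all 2×2 tables with cells ≤ 5, all
two-category rating designs on ≤ 4 units, and all score/label
assignments on ≤ 5 patients over a tied grid.

## Known limitations

* Shipped cut values are reconstructions; users validating against a
  specific registry should supply their own definition files (the schema
  is one YAML document per score).
* In-sample AUC carries optimism of order √(k/events); the null-model
  test budgets for it explicitly.
* The Woolf CI and Wald p are poor for very sparse tables even with the
  0.5 correction; exact tests are deliberately out of scope.
* Krippendorff's alpha is implemented for the two-ratings-per-unit
  design only (the inter-score comparison); general m-rater incomplete
  designs are not supported.
* The generator's death-cause assignment resolves ties by a fixed
  priority (hemorrhage over TBI proxy over MOF); this is arbitrary and
  documented rather than estimated.
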