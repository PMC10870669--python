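# Methods

## Outcomes and cohort model

A cohort is a subjects × variables table with an explicit dictionary; every
variable carries a visit tag (`birth`, `admission`, `hospitalization`,
`discharge`, `6m`, `12m`, `24m`). Outcomes are defined on BSID-III
composite scores (population mean 100, SD 15):

* **delay** (CDelay/MDelay): score < 85 at 24 months CA, strict inequality;
  predictors restricted to visits ≤ 12 months.
* **regression** (CRegres/MRegres): decline ≥ 15 points (one SD) between
  the 6- and 24-month visits, inclusive at 15; predictors ≤ 6 months.

Boundary conventions follow the printed definitions literally (a score of
exactly 85 is negative; a decline of exactly 15 is positive). Subjects
missing an outcome-defining score are excluded per model, never imputed —
the score *is* the label. `assemble_features` drops every column whose
visit exceeds the model's horizon, which structurally excludes the
24-month scores from the predictor set (label-leakage guard, asserted in
tests for all four outcomes).

Anthropometric measures are discretized into 8 ordinal intervals bounded by
the seven z-score cuts (−3Z … +3Z) of a growth reference. Intervals are
lower-exclusive / upper-inclusive, so a value exactly at −3Z falls in bin 1
and a value exactly at the mean falls in bin 4. References are pluggable
tables keyed by (measure, visit context, sex); the packaged table
(`data/synthetic_growth_reference.csv`) is a synthetic stand-in with
plausible magnitudes — production use should load the INTERGROWTH-21st and
WHO charts through the same CSV interface.

## Preprocessing

* **Missingness filter**: variables missing in strictly more than 30% of
  subjects are dropped (a variable at exactly 30% is retained). Idempotent.
* **kNN imputation** (k = 5 default): distances are Euclidean on
  z-standardised columns, rescaled over mutually observed coordinates
  (scikit-learn's NaN-aware Euclidean). Continuous/score variables take
  the neighbour mean; binary/ordinal variables the neighbour mode, ties
  toward the smaller level. Observed cells are never altered. The mode
  aggregation for discrete variables is the reason this is a thin custom
  routine rather than a stock imputer, which averages everything.
* **Coarse-to-fine screen**: per variable, a Pearson (point-biserial) and a
  Spearman test against the 0/1 label; retained iff min of the two
  p-values ≤ α = 0.05. Constant variables are untestable and never
  retained. An optional `top_k` reproduces a fixed fine-feature count when
  a protocol dictates one. Because the two tests are highly correlated on
  the same data, the false-retention rate on pure noise sits near (slightly
  above) α; the calibration test measures it over 200 seeded cohorts.
* **Split**: stratified 7:3; the test set receives round(n·0.3) subjects
  (banker's rounding; 2,544 → 763) allocated across classes by largest
  remainder, so test prevalence tracks cohort prevalence within one
  subject. Stratification is a deliberate choice — the reference cohort
  tables show matching impairment rates between the full cohort and the
  independent test set, which an unstratified split would only achieve on
  average.
* **Balanced development cohort**: all cases plus an equal-size seeded
  without-replacement sample of controls; prevalence exactly 50% whenever
  cases ≤ controls, else an error. (One published balanced set shows 49.1%
  rather than 50.0%; the construction here enforces exact 1:1 and the
  discrepancy is treated as a reporting artefact of the source table.)

## The evolutionary search (IBCGA + intelligent crossover)

Chromosome = binary feature mask (exactly r ones) + two grid indices for
the RBF-SVM parameters, C ∈ {2⁻⁵ … 2¹⁵} and γ ∈ {2⁻¹⁵ … 2³} by powers of 4
(the classic libsvm grid; the kernel is RBF, the standard choice for a
(C, γ) parameterisation). Fitness is mean stratified 10-fold CV accuracy,
with features z-standardised inside each training fold; the fold plan is
fixed by the config seed, so fitness is deterministic and cacheable per
chromosome.

Per subset size r: elitism of 1, tournament selection of size 2,
orthogonal-array crossover with probability 0.5, count-preserving swap
mutation (rate 0.05 per chromosome) plus parameter-gene redraw (rate 0.1),
for a configured number of generations. Sizes sweep r_start → r_end; each
transition flips one additional random 0-gene on per chromosome
(inheritance), preserving parameter genes. The overall winner maximises
fitness with ties broken toward smaller subsets (the second objective,
resolved lexicographically).

Crossover detail: disagreeing genes (feature positions where the masks
differ, plus each parameter gene when it differs) become factors of a
two-level orthogonal array L_{2^m}(2^{2^m−1}) built from the parity design,
with 2^⌈log₂(k+1)⌉ rows for k factors — pairwise level balance is tested
directly. Every row is evaluated as a candidate chromosome; per-factor main
effects are the mean fitness difference between levels; the child takes the
better level per factor and is repaired to exactly r ones by flipping the
disagreeing genes of smallest |main effect|. The best evaluated row
(likewise repaired) is kept if it outperforms the composed child.

Population 50 × 30 generations × r ∈ 3…15 are the reference defaults
(sized so published model sizes 4–10 fall inside the sweep); the test
suite and the acceptance script use reduced settings (population 10–12,
4–5 generations, r ≤ 6, and for toy enumeration a 3 × 3 parameter grid) so
a full run stays desk-scale. At 8–12 candidates the search space is
enumerable and the search provably lands within 0.02 of the exhaustive
optimum; the equivalence is asserted at that scale rather than assumed at
full scale.

libsvm solver effort is capped (`svm_max_iter`, default 5000): the extreme
grid corners (very large C with mid-range γ) otherwise take two orders of
magnitude longer to converge, and the capped fits score poorly and are
discarded by selection anyway.

**MED ranking.** For each selected feature j, MED_j = |mean decision value
with column j set to its observed maximum − mean with j at its observed
minimum|, all other columns at observed values. Decision values (signed
margins) are used rather than thresholded classes, giving a continuous
effect measure; a constant feature has MED 0. On linear kernels MED is
proportional to |wⱼ|·range(xⱼ), which is what the ranking tests exploit.

## EL-LR and the published registry

`fit_el_lr` is a plain maximum-likelihood logistic fit (statsmodels) on the
selected subset, reporting coefficients in logit units with 95% Wald CIs.
Perfect or quasi-perfect separation (non-finite standard errors or
exploding coefficients) is flagged and resolved with a ridge-penalised
fallback so a usable formula is always returned.

The four published formulas are shipped verbatim as a JSON registry
(10 + 4 + 4 + 4 terms and four intercepts). The source prints no covariate
scaling; coefficients of magnitude 8–10 on Bayley scores are only coherent
if inputs are normalised, so the registry declares min–max [0, 1] scaling
per variable (anthropometric ordinals mapped over their 8 bins) as an
explicit, surfaced assumption. The probability threshold for risk classes
is 0.5, also an assumption. Baselines (lasso, logistic regression, linear
SVM, random forest) are a harness over scikit-learn estimators tuned by
repeated stratified CV — deliberately *not* bespoke code, mirroring the
original comparison design where only the evolutionary models are novel.

## Metrics

Threshold metrics use the standard formulas; ratios with zero denominator
are reported as "undefined" (None), never NaN-propagated.
`confusion_from_rates` reconstructs TP/FP/TN/FN from printed sensitivity,
specificity and class sizes, permitting fractional counts; a `rounded()`
mode recovers the underlying integer table. The published
cognitive-delay external column is internally consistent only under
integer counts (tp = 134, tn = 877 reproduce accuracy 75.1%, PPV 34.5%,
NPV 91.4% and MCC 0.321 exactly at printed precision; the fractional
reconstruction gives 75.0% / 0.320), so the worked-example test asserts
the rounded reconstruction and checks the fractional one to reporting
precision. The published motor-delay external accuracy (79.1%) is *not*
reproducible from its own printed rates (reconstruction gives ≈ 78.7%)
and is not asserted.

AUC is the Mann–Whitney concordance probability computed from midranks
(tie-corrected), asserted equal to the O(n²) pairwise oracle to 1e−12. The
95% CI uses the DeLong structural-components variance by default (the CI
method is unstated in the source; DeLong is the field default), with a
seeded stratified percentile bootstrap (2,000 resamples) as the
alternative. Coverage of the DeLong interval is verified at ≈ 95% ± 2% on
binormal score models with known AUC. DeLong is implemented in-package;
no installed Python dependency provides it.

## Synthetic cohort generator

The generator emulates the statistical shape of a national VPI registry,
not any real subject: GA ~ Normal(28, 2) truncated to [22, 31.86] weeks;
birth weight linear in GA over [401, 1500] g plus noise (SD 150 g),
clipped; a configurable set of informative clinical features (default:
ventilation days, severe IVH, neonatal sepsis, log-odds 1.2/1.4/1.1) and
25 mixed continuous/binary noise features spread over visits.

A single latent logistic risk links features to outcomes: risk =
σ(α + Σβx), and each Bayley score is `baseline − effect·loading·risk +
subject shift + visit noise`, with visit effects 14/24/34 points at
6/12/24 months, motor loading 1.15, subject shift SD 10 and visit noise SD
11 (total score noise ≈ 15, the composite SD, split so that repeated
scores of one child correlate). The intercept α is calibrated by root
finding so the 24-month cognitive threshold outcome hits the target
prevalence (default 16%) in expectation; an unreachable target raises a
convergence error. The zero-risk score baseline is 106 rather than 100:
with baseline 100 and 15 points of noise, pure noise alone already puts
~17% of scores below 85, leaving no room to calibrate a 15–16% target.
Under the defaults all four outcomes land in the 15–25% prevalence band
and the 6/12-month scores are the dominant predictors of every outcome —
the single-latent-factor design reproduces exactly that known feature of
real follow-up data. Missingness is injected MCAR per variable;
outcome-defining 6- and 24-month scores are never masked, keeping the
labellers total.

`simulate_logistic` is the second, direct generating process — labels ~
Bernoulli(σ(β·x)) on standard-normal features — used wherever a test must
recover *coefficients* (EL-LR CIs, MED ordering, feature-subset recovery):
through the Bayley-score pathway the feature–label association of a
binary predictor with odds ratio 3 attenuates to a point-biserial r ≈ 0.1,
which no subset-selection method recovers reliably at n = 600, so
coefficient-semantics tests use the generator whose coefficients *are*
log-odds.

What passing tests on generated data do **not** show: robustness to
informative (MNAR) missingness, site effects, measurement drift between
cohort eras, or non-linear feature–outcome relationships — all real
phenomena the generator deliberately omits. The correlation screen in
particular would discard purely non-linear predictors by construction.

## Numerical conventions and degenerate inputs

* Banker's rounding for split sizes; largest-remainder class allocation.
* Standardisation guards zero-variance columns (σ → 1).
* Mode imputation ties resolve toward the smaller level.
* Empty feature masks score fitness 0 rather than erroring inside the GA.
* All RNG flows through `numpy.random.default_rng` seeded per stage
  (pipeline sub-seeds are CRC-derived from the run seed, independent of
  execution order); fixed-seed runs are bit-reproducible, asserted on the
  serialized model card.

## Known limitations

* The balanced development cohort discards controls; no weighting or
  ensemble over multiple balanced draws is implemented.
* The GA's reference-scale defaults are compute-hungry; the reduced
  desk-scale settings explore far less and are only validated against
  exhaustive enumeration at toy scale.
* MED is a one-at-a-time effect measure; it understates features whose
  influence is purely interactive.
* The registry's input normalisation is an assumption; predictions from
  the published formulas are only meaningful on inputs scaled to [0, 1].
* Multiple-imputation uncertainty is not propagated (single kNN draw).
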