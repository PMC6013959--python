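# Methods

## Problem and outcome definition

The unit of analysis is the hospital admission. Every admission is an
index admission with potential for a readmission; it is flagged when the
next *countable* admission of the same patient begins within 30 days of
its discharge. Day differences are whole days on an integer-day axis
(`next.admit − index.discharge`); a same-day readmission (gap 0) counts,
and the boundary is inclusive (gap 30 flags, gap 31 does not). Planned
admissions, within-hospital transfers, and stays ending against medical
advice are excluded: they are never evaluated as indexes, never serve as
readmissions, and are invisible to the gap computation — the gap is taken
to the next countable admission, skipping excluded stays in between. This
last point is one reading of "excluded from the readmission counts"; an
alternative (an intervening excluded stay voids the pair) would lower
rates slightly and is not implemented. A readmission is itself evaluated
as an index for a subsequent readmission, and the running count of a
patient's earlier 30-day readmissions is exposed as a feature
(`cumulative_prior_30day_readmissions`). Two admissions starting the same
day are ordered by discharge date, then record order, and logged.

## Synthetic cohort generator

Real EMR extracts of this kind are not public, so the generator emulates
the cohort structure the method assumes. What it reproduces:

* **Marginal outcome rate.** Per-admission risk is
  `σ(b₀ + wᵀx + Σ interactions + ε)`, with `b₀` calibrated by bisection on
  a 4,000-draw covariate sample so the marginal risk equals
  `target_readmit_rate` (default 0.233, the published all-cause rate).
  `ε ~ N(0, noise_sd²)` is latent risk heterogeneity (default 0 — all
  structure is in the covariates).
* **Admission chaining.** Each countable stay draws
  Bernoulli(risk); on success a readmission stay is *inserted* 1–30 days
  after discharge (geometric gap, p=0.15, capped at 30) and is itself at
  risk, recursively, up to `max_admissions_per_patient` (default 30, which
  keeps the degenerate risk-1 configuration finite). Non-readmission gaps
  are uniform on 31–365 days. Because outcomes create the short-gap
  admissions, the realized flagged fraction among countable admissions
  converges to the target rate by construction, and relabeling from dates
  recovers exactly the sampled indicators.
* **Exclusions.** Planned / transfer / against-medical-advice flags are
  drawn at configured fractions (defaults 0.05 / 0.02 / 0.01 — the source
  study does not publish these; values chosen once as plausible hospital
  fractions). Flags are only drawn for stays that were not generated as
  readmission targets, so exclusions do not bias the realized rate.
* **Covariates and events.** `n_binary_codes` Bernoulli indicators plus
  `n_continuous_vars` uniforms. Binary covariates materialize round-robin
  as diagnosis / medication / procedure / abnormal-lab events inside the
  windows the feature extractor reads, so the planted signal must survive
  the full extraction path; continuous covariates surface as
  admission-level measures. Interactions are XOR for binary–binary pairs
  and products otherwise — the "linear plus nonlinear" risk mixture the
  architecture is designed for.
* **Notes.** Token streams per section, Zipf(1.3) over the vocabulary,
  mixed toward a designated low-index "signal" block with weight
  proportional to the admission's risk, so bag-of-words features carry
  outcome signal. One section per note type is deliberately rare (<50%
  presence) to exercise the section filter.

What it does **not** emulate: real code semantics (ICD/ATC/LOINC are
opaque identifiers), clinical plausibility of trajectories, free text,
seasonality, censoring, or inter-site linkage. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
signal — not clinical performance; published AUCs on private EMR data are
out of reach by construction.

Default scale parameters: `mean_admissions_per_patient = 2.4` (the
published cohort averages ≈2.37 admissions/patient); patient demographics
are age, gender, marital status.

## Feature pipeline

Windows per data type: diagnoses — binary occurrence in
[discharge − 730 d, discharge]; labs — abnormal-result counts in
[admit, admit + 7 d] and [discharge − 7 d, discharge] as two variables per
test; medications/procedures — counts in [admit, discharge]; demographics
— patient-level. Note sections are retained when present in ≥50% of the
notes of their note type; each retained section contributes bag-of-words
variables (per word: count and binary presence; words with corpus-wide
total count ≤5 removed), with binary presence used for all sections
except allergies, which keeps counts. The social-history window
"penultimate to admission" is implemented as (previous stay's discharge,
current admission] — an interpretation, flagged as such. Code mappings
(e.g. drug → ATC level 5) are injected lookup tables; unmapped codes pass
through under their raw identity and the coverage fraction is logged, not
asserted.

Encoding: categoricals are 1-of-K expanded; missing entries are zeroed
*before* scaling; each column is affinely mapped so training-min → 0 and
training-max → 1. Choices where the source is silent: constant columns
map to zeros; scaling parameters are fit on training folds only and test
values are clipped to [0, 1]; continuous variables are scaled, not binned
(the 1-of-K phrase is read as applying to categorical/discrete codes —
no bin count K is published for the alternative reading).

**Total KL divergence filter.** Per variable, class-conditional
distributions P (readmitted) and Q (not) are estimated as Bernoulli cells
for 0/1 columns and 10 equal-width bins over the pooled range otherwise,
each cell padded with ε = 1e-9 pseudo-mass so empty cells never yield
infinite divergence; `D = KL(P‖Q) + KL(Q‖P)` and the retention rule is
`D ≥ mean(D) + sd(D)/2` (population sd). The bin count, ε, and the choice
to estimate on the encoded matrix are implementation decisions — the rule
itself and the symmetrized statistic are the specified method. The
selector falls back to keeping all variables (with a warning) in the
degenerate case where the threshold exceeds every divergence.

## DUNs reconstruction

The published architecture description is survey-level; the exact
equations live in an appendix that is not part of the available text.
This implementation commits to the following reconstruction, which is the
module's central assumption:

* Harmonizing unit k consumes both the raw input and the previous data
  unit (`h_k = act(U_k h_{k−1} + V_k x + c_k)`). The alternative —
  previous layer only — would be an ordinary DNN and contradict the
  mesh-form description.
* The attention unit is a single linear map of the raw input followed by
  a normalized exponential, trained jointly; its outputs are nonnegative
  and sum to 1 per sample for any weights (a structural invariant tested
  to 1e-6).
* The decision unit sees the layers only through the attention mix
  `z = Σ a_k h_k` — two horizontal hops from any data unit to the output.

Loss is binary cross-entropy (implied by the sigmoid output); optimizer
is classical-momentum SGD (defaults 0.01 / 0.9 / batch 100 as published);
dropout is standard inverted dropout on the input and each data unit,
with expectation scaling at inference; weights initialize
symmetric-uniform scaled by 1/√fan-in. Training aborts with a diagnostic
if the loss goes non-finite. All gradients are hand-derived and checked
against central finite differences (1e-4 relative, p=5/m=4/K=3/batch=7)
for all four activation choices.

Maxout networks share the training loop; each neuron takes the maximum
over its affine pieces, and with one piece the hidden layers are affine,
so the forward pass coincides with a plain feed-forward network (tested
to 1e-10). Logistic regression delegates to scikit-learn (`lam` maps to
`C = 1/(lam·n)`), with |weight| as feature importance; gradient boosting
is an adapter over xgboost and is skipped with a warning when absent.

## Evaluation and operating point

ROC curves are built by sweeping the threshold over every distinct score
(ties enter together, predicted-positive rule `score ≥ θ`) and carry raw
TP/FP/predicted-positive counts so the cost model needs no re-scoring.
AUC is the trapezoid over FPR (equal to pairwise concordance with half
credit for ties — tested exhaustively at small n). The operating point
minimizes `√(FPR² + (1−TPR)²)`; ties break toward higher TPR then lower
threshold, logged. Precision at zero predicted positives is reported as 0
with a warning. Cross-validation is stratified (guaranteeing both classes
per fold, which plain k-fold does not); preprocessing (scaler, KL filter)
is fit per fold on the training portion only; the operating threshold is
selected on the held-out curve by default (`theta_on="train"` computes
the alternative). Hyper-parameter search is seeded random search over the
published ranges — a 10% stratified subset drawn once, each trial scored
by mean k-fold CV AUC on that subset.

## Cost model

`savings = readmission_cost·TP·response_rate − program_cost·PP`, with
published defaults \$9655 / \$1500 / 50%. The sweep evaluates every curve
point; because the all-negative endpoint (PP = 0, savings 0) is always
present, the per-fold maximum is never negative. Argmax ties break toward
the smaller program. Per-fold maxima are summarized as mean ± sd, using
held-out-fold counts (the source is ambiguous between held-out and
whole-dataset counts; held-out is the leakage-free reading). No
discounting or horizon modelling.

## Problem sizes used in the test suite

The distributed tests run the nonlinear-separation comparison at n=4,000
admissions / p=20 covariates over 5 seeds with 5-fold CV, the end-to-end
pipeline at ≈5,000 admissions, the rate-calibration check at 10,000
patients, and the weight-recovery check at n=20,000 — sizes at which the
statistical assertions are stable while the whole suite stays fast on a
single CPU. Model settings in those tests (3 layers × 64 tanh neurons for
DUNs; 2 layers × 48 neurons × 2 pieces for maxout) were chosen from the
published search ranges as configurations that train reliably at these
problem sizes.

## Known limitations

* The DUNs equations are a reconstruction (above); a different appendix
  parameterization of the attention unit would change layer-importance
  profiles, though not the simplex invariant.
* The KL filter's histogram scheme for continuous variables is a
  discretization choice; heavily skewed variables may deserve quantile
  bins.
* The generator's admission process is memoryless given covariates; real
  utilization has longer-range dependence.
* `rate_from_counts` reports one-decimal percentages; published figures
  sometimes round to integers (37.8% prints as 38%).
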