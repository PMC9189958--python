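# Methods

## The model

`seqsurv` implements a relative-risk extension of the Cox proportional
hazards model for 5-year cardiovascular-disease risk prediction from
longitudinal coded administrative health records. The hazard for person
*i* is

    h_i(t) = h_0(t) · exp(f(x_i, s_i))

where `x_i` is a vector of pre-specified covariates (centred age, centred
deprivation quintile, ethnicity indicators, condition and medication
flags, and six first-order interactions) and `s_i` is the person's
time-ordered sequence of coded events (diagnoses, procedures,
medications) in a 60-month lookback window. Two families of `f` are
provided:

* **Cox comparator** — `f = x'β`, fitted by Newton maximization of the
  partial likelihood on the pre-specified covariates alone (module
  `seqsurv.cox`).
* **Recurrent relative-risk network** — each coded event is embedded
  (code embedding + code-type embedding, summed) and concatenated with
  the inter-event gap Δt; three stacked bidirectional GRU layers with 10%
  inter-layer dropout process the sequence; dot-product attention with a
  single learned query pools the positions into a context vector; the
  context is concatenated with `x_i` and passed through a size-preserving
  fully connected ELU layer and a final linear map to the scalar log
  relative risk (module `seqsurv.network`). An empty history yields the
  zero context vector.

Both families are sex-stratified: separate models per stratum, never a
sex covariate.

### Training

Network parameters maximize the Cox partial likelihood via its sampled
risk-set reduction: each epoch iterates in shuffled order over all
persons with an event; every case is matched to one control drawn
uniformly from its risk set (follow-up ≥ the case's event day, sampled
with replacement across batches and epochs), and each pair contributes

    loss = log(1 + exp(−(f_case − f_control)))

— the negative log partial likelihood of a risk set of size two.
Optimization is Adam (β = (0.9, 0.999)) for exactly ten epochs, with no
early stopping. Ensembles repeat training from independent random
initializations and average the log risks.

The library defaults (`ModelConfig`) are learning rate 0.001, 256-case
batches and 10-member ensembles, appropriate for national-scale cohorts
(~10⁶ persons, ~10⁵ gradient steps). The bundled experiment harness
(`seqsurv.experiments.desk_model_config`) uses desk-scale values chosen
once during development: embedding dimension 16, learning rate 0.03,
16-case batches, 3-member ensembles. Desk cohorts (8 000–20 000 persons)
supply only a few hundred gradient steps per run, so a proportionally
larger step size is required for Adam to traverse the same loss
landscape; ten epochs then sit near the held-out optimum (fewer epochs
underfit, thirty overfit severely).

### Absolute risk and local hazard ratios

Relative risks are anchored at a *reference person* (stratum mean age,
deprivation quintile 3, reference ethnicity, all flags false, empty
history). The Breslow estimator gives the baseline cumulative hazard at
that person and `risk_i = 1 − S_ref(1826)^exp(f_i − f_ref)`.

Local hazard ratios perturb the reference person — flipping a flag,
switching ethnicity, shifting a continuous predictor by one unit, or
appending one coded event at the index month — and exponentiate the
change in `f`. K models trained from different initializations give the
spread; the mean and the 2.5/97.5 percentiles across replicates are
reported (the percentile construction is this package's choice; K
defaults to 10 at desk scale). Continuous predictors report per-unit
ratios averaged over a grid of observed values (age at its deciles,
deprivation at quintiles 1–4). Applied to the Cox model at the reference
person, the same machinery returns `exp(β̂_j)` exactly for a binary flag,
which serves as a closed-form harness check. Local hazard ratios are
model-explanation quantities, not causal effects.

The probe reads the network far off its training manifold: empty and
single-code histories essentially never occur in training data, so the
readout depends on how the head extrapolates to the zero-context region.
At desk scale two failure modes matter, and the bundled local-HR
experiment configuration is chosen to avoid both. First, a weak
single-code effect is only learned reliably under low-noise optimization
(learning rate 0.01 at 16-case batches; the higher rate used for the
discrimination experiments leaves the code effect at the noise floor).
Second, a wide ELU head (embedding dimension 16, context width 34)
inflates the lone-code readout roughly two-fold in log space, because
attention stays diffuse at this scale (weight on the probed code ~ its
uniform share) and in-distribution training pins down only the *pooled*
contribution of a code, not its isolated one. A 4-dimensional embedding
keeps the head close to the additive readout the training data
determine; with it, replicate probes cluster tightly around the planted
effect. Larger cohorts with sharper attention should relax this
constraint, and the replicate CI makes any residual extrapolation noise
visible rather than hidden.

## Evaluation

* **Harrell's C**: pairs (i, j) are comparable when `t_i < t_j` with an
  event at `t_i`, or `t_i = t_j` with exactly one event; score ties count
  ½. Checked against exhaustive pair enumeration.
* **Royston–Sauerbrei D and R²**: D is the Cox coefficient of the
  prognostic index's Blom rankits (constant 3/8) scaled by
  κ = √(8/π); R² = (D²/κ²)/(π²/6 + D²/κ²). Rank-based, hence invariant
  to monotone transforms; for a standard-normal index, D ≈ κ ≈ 1.596.
  An all-tied index returns D = 0 with a degeneracy flag.
* **Integrated Brier score**: Graf's IPCW weighting with the
  censoring-distribution Kaplan–Meier Ĝ, left-limit Ĝ(t⁻) for observed
  events, averaged by trapezoid over the distinct event times (thinned to
  at most 200 grid points by quantiles).
* **Decile tables**: deciles of predicted 5-year risk (stable ties);
  observed proportions default to 1 − KM(1826) within the decile to
  handle censoring, with the crude fraction available by flag.
* **Stratified 5×2 cross-validation**: five event-proportion-stratified
  random halvings; each half trains once and tests once. All data
  contracts — vocabulary, centering, Ĝ, Breslow baseline — come from the
  training half only. Fold differences feed the combined 5×2 F test,
  `F = Σd²/(2Σs_r²)` against F(10, 5). Note that this statistic is
  conservative by construction: its numerator decomposes as
  `2Σd̄_r² + Σs_r²` and therefore shares the denominator's
  within-replication variation, giving an exact null rejection rate of
  about 0.016 at the nominal 0.05 level for independent normal
  differences. Cross-validated metric summaries use t-based intervals
  over the ten fold values.

## The synthetic cohort simulator

The national linked data such models are built on is access-restricted,
so `seqsurv.simulate` generates cohorts with the structure the method
assumes, with known planted truth:

* covariates at roughly national frequencies (age uniform 30–74,
  deprivation uniform 1–5, five ethnicity levels, flag prevalences
  0.01–0.17);
* Zipf-distributed code popularity over ~160 diagnosis/medication codes,
  multi-month replicated listings (10% of events span 2–3 calendar
  months), and condition-linked codes whose occurrence odds are boosted
  several-fold when the matching flag is set (emulating flag/code
  redundancy, which makes the ablation experiment meaningful);
* true log hazard `η* = x'β* + Σ_c γ*_c w_c`, where `w_c` is 1 when the
  recency timescale τ = 0 and `exp(−Δm_c/τ)` otherwise (Δm months from
  the latest listing to the index date);
* event times exponential with rate `λ0·exp(η*)`; censoring is the
  minimum of non-CVD death, emigration (both exponential) and the
  administrative horizon of 1826 days; follow-up is rounded up to a whole
  day ≥ 1.

Independent per-person substreams derived from `(seed, person index)`
make cohorts bit-reproducible and prefix-stable under changes of
`n_persons`.

Chosen constants, and why:

* `β*` magnitudes follow published adjusted hazard ratios for this
  predictor set (≈1.09/year of age, ≈1.15/quintile, ~2 for diabetes,
  small negative interactions).
* `λ0 = 3.5e−5`/day gives a ~10–15% 5-year event fraction — several-fold
  the published national rate — so that desk-scale cross-validation
  halves retain enough events for stable fits of either model family.
* censoring hazards (non-CVD death 7e−6/day, emigration 4e−5/day) match
  the published ~1.3% death and ~7% lost-contact fractions.
* The **linear preset** (τ = 0, γ* = 0, a log-2 coefficient planted on
  the diabetes flag) makes the Cox comparator correctly specified: used
  for parameter-recovery checks and for verifying the network does not
  hallucinate sequence signal.
* The **nonlinear preset** (τ = 12 months, twelve planted code effects
  with recent-listing hazard ratios 1.8–4) is the designed nonlinearity a
  linear-in-covariates model cannot represent. The magnitudes are set so
  the code contribution to η* retains a standard deviation of about half
  the covariate contribution after recency dilution (mean recency weight
  ≈ τ/60); weaker effects leave no measurable discrimination headroom
  over the covariates-only ceiling, making the comparison uninformative.

The simulator emulates structure, not semantics: codes carry no medical
meaning, occurrence is conditionally independent given the flags, there
is no seasonality and no post-index information. The exponential baseline
is a simulator convenience (closed-form oracles), never exploited by the
models. Passing tests therefore demonstrate that the machinery recovers
known effects under the stated generative assumptions — not that the
models are well-calibrated on real administrative data.

## Numerical choices

* Cox fitting: Efron tie correction by default (day-resolution data tie
  heavily); Breslow retained for cross-checks. Convergence at relative
  log-likelihood change < 1e−9 or gradient max-norm < 1e−6, ≤ 100
  iterations, step-halving on non-increase. Standard errors from the
  inverse observed information. Collinear or constant columns are
  reported by name rather than silently dropped.
* Δt enters the recurrence in years (months/12). Raw month counts up to
  59 sit far outside the unit scale of the embeddings and saturate the
  GRU gates at initialization, which measurably slows learning.
* GRU hidden size equals the layer-0 input size (embedding_dim + 1) *per
  direction*; directions are concatenated between layers.
* Sequences longer than `max_sequence_length` (default 500) keep their
  most recent events, with the first retained Δt reset to 0.
* Padding token 0 never updates the hidden state and receives zero
  attention weight, hence no gradient.
* Embeddings initialize N(0, 1/√e); GRU and head weights uniform
  ±1/√fan-in; biases zero.
* The numerator guard in the Breslow and partial-likelihood sums shifts
  by max(η) before exponentiation.

## Known limitations

* No hyperparameter search; the desk-scale configuration was fixed once
  and is not tuned per dataset.
* The local-HR percentile intervals quantify initialization/batch noise
  across replicates, not sampling uncertainty of the data.
* The combined 5×2 F test is conservative (above); p-values near the
  threshold understate significance.
* At desk scale the network's advantage over the Cox comparator on the
  nonlinear preset is real but small (ΔC ≈ 0.005–0.01); ensembles of 3
  are needed to make it consistent across replications.
* The simulator's flag/code redundancy is a stylized stand-in; ablation
  results on it indicate direction, not magnitude, of real-data effects.
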