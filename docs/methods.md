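# Methods

## Model and assumptions

The package estimates individual causal effects of a binary genomic
intervention *t* on an integer clinical outcome *y* (Gleason Score, GS) from
observational data in which confounders are never observed directly, only
through noisy proxies: discrete features **x**₁ (aberration indicators,
categorical clinical fields) and continuous features **x**₂ (gene
expression, continuous clinical fields). The structural assumption is a
latent-confounder graph: Bernoulli latents **z**₁ generate **x**₁, Gaussian
latents **z**₂ generate **x**₂, and a joint Gaussian layer **Z** — a
nonlinear function of (**z**₁, **z**₂) — is the common cause of both *t* and
*y*. Identification of counterfactuals rests on this proxy structure: if the
posterior over **Z** can be recovered from (**x**₁, **x**₂, *t*, *y*), the
outcome head p(y|t′, **Z**) evaluated at the unobserved arm t′ = 1 − t is an
estimate of the counterfactual outcome. This assumption is untestable on
real cohorts; the synthetic generator exists precisely to verify the
machinery when it holds by construction.

## Variational objective

The joint density factorizes as
p(z₁)p(z₂)p(x₁|z₁)p(x₂|z₂)p(Z|z₁,z₂)p(t|Z)p(y|t,Z). Training maximizes a
Monte-Carlo evidence lower bound with:

- Bernoulli reconstruction likelihood for x₁, diagonal Gaussian with learned
  scale for x₂, Bernoulli for t, Gaussian (or softmax-categorical) for y;
- closed-form KL terms: KL(q(z₁|x₁,t,y) ‖ Bern(0.5)) and
  KL(q(z₂|x₂,t,y) ‖ N(0, I));
- a joint-layer divergence E_q[KL(q(Z|z₁,z₂,t,y) ‖ p(Z|z₁,z₂))], computed in
  closed form given sampled (z₁, z₂);
- auxiliary losses for predictors q(t|x) and q(y|t,x), trained jointly so
  that inference can proceed when *t* or *y* must be withheld at test time.

Discrete latents use relaxed-Bernoulli (concrete) samples at temperature 0.5
during training and hard Bernoulli samples at evaluation — the standard
gradient estimator for Bernoulli VAEs. Gaussian heads squash their raw
log-variance through `4·tanh(·/4)`, bounding variances to
(e⁻⁴, e⁴) for numerical stability. The `elbo` evaluator reports the mean
per-patient bound over hard-sample draws; the test suite checks it against a
dense enumeration (z₁) + Gauss–Hermite quadrature (z₂, Z) oracle at
2-dimensional latents.

## Counterfactual inference

The posterior over **Z** is conditioned, by default, on the proxies plus the
factual (t, y) ("train-style" inference); a proxies-only mode seeds the
encoder with the auxiliary predictors instead. Both are exposed because
either reading of the protocol is defensible; train-style is the default
since the estimands contrast model estimates with *observed* factual
outcomes. Inference uses common random numbers: one noise stream per sample
index shared across all patients. This makes estimates exactly equivariant
under row permutations and reduces Monte-Carlo variance of group contrasts;
it introduces cross-patient correlation of MC error, which is irrelevant for
the per-patient posterior means reported.

## Hyperparameters

Reference configuration (`DLVMConfig()` defaults, intended for real
cohorts): latent dimensions |Z| = 50, |z₁| = |z₂| = 160; three sigmoid
hidden layers of 300/300/100 units; Adam with learning rate 1e−5, weight
decay 1e−5 (the "decay rate" is taken as an L2 coefficient, the natural
reading in an Adam context, not a learning-rate schedule); batch size 10; up
to 300 epochs with best-validation-ELBO checkpointing.

Desk-scale configuration (`DLVMConfig.desk_scale()`), used throughout the
tests, examples and the reproduction script: 16/16/16 latents, tanh hidden
layers (64, 32), Adam at 3e−3, batch 100, 60 epochs, 100 posterior samples.
These sizes were fixed once by preliminary validation runs on the synthetic
generator — they train in seconds per fold on one CPU while recovering a
constant +1 GS effect to within ±0.1 on average — and match the generator's
small true dimensionality; they are a modeling choice for the synthetic
regime, not a tuned-to-test artifact.

The outcome head defaults to Gaussian on the GS scale with unrounded
predictions (effects are real-valued, consistent with reporting non-integer
group effects); an ordinal-categorical head over the observed GS levels is
available by configuration.

## Synthetic data-generating process

`generate_cohort` forward-simulates the model's own graph with ground truth:

- z₁ ~ Bern(0.5)⁵, z₂ ~ N(0, I₅); a single standardized confounder score
  c = w·(z₁ − ½, z₂);
- x₁: 20 binary copies of z₁ components, each bit flipped with probability
  0.1; x₂: 20 linear views of z₂ plus N(0, 0.5²) noise;
- t ~ Bern(sigmoid(λ·c + logit(0.35))) with confounding strength λ = 1 by
  default — the treated group's baseline outcome is genuinely shifted;
- latent outcomes y(0) = 7.2 + 0.8·c + N(0, 0.5²) and
  y(1) = y(0) + τ(effect model: zero; constant τ = 1; or heterogeneous
  τ·(1 + 0.5·tanh(c′)) with an independent projection c′), plus optional
  per-race effect shifts;
- observed GS = round(y(t)) clipped to [6, 10]. The integer potential
  outcomes satisfy the consistency invariant exactly; the continuous latent
  outcomes are retained (`y0_latent`, `y1_latent`) so that effect-recovery
  checks are free of discretization bias.

The anchor at 7.2 with ≈0.94 latent SD keeps clipping below ~4% of rows, so
discretization is approximately mean-preserving. What the generator does
*not* emulate: real expression covariance, linkage between specific
aberrations and expression programs, outcome ordinality beyond rounding,
missingness patterns, or cohort-specific marginal frequencies. Passing
effect-recovery tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions — not robustness to their
violation on real cohorts.

A separate fixture (`generate_prad_like_fixture`) mimics the motivating
prostate cohort's *layout* — 270 + 43 patients in two race strata, 13
canonical aberration columns, an expression block wired through the schema's
aberration→expression map, all grade strata populated — for IO and protocol
tests; it carries no truth block, like real data.

## Experimental protocol

Per aberration and racial group: R replications (default 10) of k-fold
(default 3) cross-validation, stratified by grade where cell sizes permit.
The non-test portion is split ≈70/30 into train/validation, giving the
≈47/20/33 overall design; pooling a replication's test folds covers each
patient exactly once, so each replication yields one AICE/RMSE per (race,
grade) cell. Cells empty in a replication are recorded as NaN, never
fabricated. Racial groups are modeled separately; the pairing unit of the
t-test is the replication index — the only index shared between two groups'
metric vectors. Grade stratification of test patients uses *observed* GS.
Raw per-comparison p-values are reported (α = 0.05, two-sided, with 95% CI);
Benjamini–Hochberg-adjusted values are emitted alongside, clearly labeled,
since the protocol itself applies no correction.

AICE is implemented with a root convention by default: the printed formula
aggregates squared ICE terms and the radical is typographically ambiguous in
the source material, so the root form is chosen for unit consistency with
RMSE and the GS scale; both conventions are computed and the choice is
recorded in every output row. Because AICE aggregates squares it orders
groups by effect *magnitude*; the signed mean ICE is reported alongside as a
clearly-labeled directional companion.

The genomic-risk-score stage maps estimated GS under the intervention arm to
[0, 1] through a monotone function; the default is logistic with midpoint
7.5 and unit scale — a stand-in chosen so that the intermediate-grade
boundary maps to risk 0.5 — and is *not* the published genomic risk model,
whose coefficients users can supply as a custom mapping (monotonicity is
verified on a probe grid).

## Race imputation

A softmax MLP (reference topology 112 inputs → 512 → 512 PReLU → 3 classes)
is trained with cross-entropy on patients with self-reported race and used
to label the rest, with per-class probabilities and a provenance column
distinguishing self-reported from imputed labels. No class reweighting by
default; inverse-frequency weighting is available behind a flag. Which 112
features feed the reference topology is cohort-specific, so the input width
is inferred from the encoded feature table unless pinned explicitly.

## Numerical and design choices

- All networks run on a small reverse-mode autodiff engine over float64
  numpy arrays; gradients are verified against central finite differences.
- One master seed fans out through `numpy.random.SeedSequence` to
  initialization, batching, sampling and evaluation streams; every pipeline
  stage is bit-deterministic given its seed, and the CLI's simulate→run path
  produces byte-identical report tables across reruns.
- Categorical discrete features are one-hot expanded in lexicographic level
  order (reproducible input dimension); continuous features are standardized
  and mean-imputed with training-split statistics (imputation counts
  logged); the outcome is standardized for the Gaussian head and mapped back
  for reporting.
- Missing/unrecognized race labels normalize to `unknown` at read time;
  `unknown` rows are excluded from group modeling and imputer training.
- Checkpoints embed the configuration and a schema fingerprint and refuse to
  load against a mismatched schema.
- Degenerate paired tests (zero-variance differences) report the limiting
  p-value with an explicit degeneracy flag rather than NaN.
- Training on a single-arm cohort (all t = 0 or all t = 1) warns that the
  counterfactual arm is unidentifiable but proceeds, since the factual
  machinery remains well-defined.

## Problem sizes

The test suite and the reproduction script run the effect-recovery studies
at n = 2000 patients × 5 seeds per effect model with the desk-scale network,
the metric oracles at ≥1000 random groups, t-test calibration at 200
simulated experiments × 10 replicates, and the protocol checks at n = 300 —
sizes chosen so the full verification cycle completes in a few minutes on a
single CPU while keeping Monte-Carlo bands meaningfully tight.

## Known limitations

- Identification rests on the latent-confounder proxy assumptions; nothing
  in the package can detect their violation on real data.
- The ELBO uses single-sample Monte-Carlo gradients and a relaxed discrete
  estimator; training is a non-convex stochastic ascent and the
  effect-recovery tolerances (±0.25 GS on a τ = 1 effect at desk scale)
  reflect that, rather than estimator bias alone.
- AICE's squared aggregation cannot distinguish effect direction; directional
  claims should rely on the signed mean ICE it is reported with.
- The GRS stage is a stand-in mapping; absolute risk values are only
  meaningful relative to a user-supplied published model.
- Real-cohort ingestion is limited to delimited files in the documented
  layout; no external data sources are fetched.
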