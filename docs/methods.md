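# Methods

This note records the model, the evaluation protocol, the synthetic data
generator, and the numerical and design choices the implementation makes
where the procedure left room for interpretation.

## Model

**Per-feature embedding.** Each of the n selected continuous features owns an
independent two-layer network 1 → d/2 → d with relu after both layers and
dropout (p = 0.1) after the second. There is no weight sharing across
features and no positional encoding: feature identity is carried entirely by
the per-feature weights, which makes the encoder stack permutation-equivariant
across features (a property the tests check).

**Encoder blocks.** Post-norm residual layout (the original transformer
ordering): E₁ = LN(E + Dropout(MHSA(E))), E_out = LN(E₁ + Dropout(FF(E₁))).
Multi-head attention uses k = v = d/h per head and scaling 1/√k inside the
softmax. The feed-forward net is d → ρ·d → d with relu; with d = 64 and
ρ = 32 its hidden width is 2048. Layer-norm gains and biases are trainable
and included in parameter counts; ε = 10⁻⁵.

**Head.** Flatten n × d → FC(2048) → relu → dropout → FC(1) → sigmoid. For
training, the loss is binary cross-entropy computed on the logit
(softplus(z) − y·z) for numerical stability; the sigmoid is applied only
when probabilities are reported.

**Parameter count.** Closed form:
n·[(d/2 + d/2) + (d/2·d + d)] + L·[4(d² + d) + (d·ρd + ρd) + (ρd·d + d) + 2·2d]
+ (n·d·H + H) + (H + 1). At the defaults (n = 96, d = 64, L = 6, h = 1,
ρ = 32, H = 2048) this is 14,482,817 ≈ 14.5 M, dominated by the head's
flatten projection (12.6 M). The count is asserted equal to framework
introspection for randomized configurations.

**Initialisation and optimisation.** All dense layers use fan-in uniform
init U(−1/√fan_in, 1/√fan_in) for weights and biases, from the run seed.
Adam (β = 0.9/0.999, ε = 10⁻⁸), lr 8 × 10⁻⁴, batch 32, 20 epochs, final-epoch
weights (no early stopping). Everything is float64 numpy; gradients are
verified against central differences to ~10⁻⁶ relative error.

## Evaluation protocol

- **Standardization** χ = (x − μ)/σ uses the population convention
  (divide by m; configurable ddof). σ = 0 columns map to 0 with a warning
  rather than erroring, since constant columns are plausible in subsets.
- **Fold plans** stratify at subject level: within each class, subjects are
  shuffled with the plan seed and dealt round-robin into k folds, so all
  recordings of a subject stay together and per-fold class counts differ by
  at most one subject. Sample-level stratification was the other option; the
  protocol description does not distinguish them, and subject-level is the
  variant compatible with the grouping constraint.
- **Historical vs leakage-safe modes.** The original protocol standardizes
  the complete table and fits the feature selector on the complete dataset
  before splitting; both leak test statistics. The defaults reproduce that
  (`scaler_scope="global"`, `select_scope="global"`); per-training-fold
  refits are available via the `per-fold` scopes and are what the leakage
  tests exercise (mutating test rows provably leaves trained weights
  unchanged).
- **ADASYN** runs on each fold's training rows only, after selection (fewer
  dimensions for the neighbour search; the opposite order is configurable by
  composing the pieces). `balance_ratio` β is the *target minority/majority
  ratio*: the synthesis budget is G = round(β·m_maj) − m_min, so β = 1 fully
  balances. (The classical parameterisation G = (m_maj − m_min)·β coincides
  at β = 1; the target-ratio form is the one whose β = 0.5 behaviour —
  minority ≈ half of majority — matches the documented contract.) Density
  weights rᵢ = Δᵢ/K come from the K = 5 nearest neighbours over all classes;
  interpolation partners come from the K nearest *minority* neighbours
  (min(K, m_min − 1) of them), so synthesis never leaves the minority point
  cloud. If every rᵢ is zero (fully isolated minority) the budget is spread
  uniformly with a warning. Per-point budgets are rounded with `rint`, so
  totals can miss G by at most one per minority seed.
- **Metrics.** ROC-AUC via the Mann-Whitney rank statistic with midranks
  for ties; precision/recall at the fixed threshold 0.5 with PD = 1 as the
  positive class. If no sample clears the threshold, precision is reported
  as 0 with a warning. Fold metrics are averaged per seed; the report gives
  mean ± sd across seeds (default 3).
- **Determinism.** Every stochastic component (cohort generation, fold
  shuffling, ADASYN, weight init, epoch shuffling, dropout) draws from
  generators derived via `SeedSequence` from the run seeds, so identical
  configurations reproduce reports bit for bit.

## Baselines

The MLP baseline is four FC layers (2048/1280/1024/1 by default, ~5.5 M
parameters at 753 inputs) with relu and dropout 0.1 after each hidden layer,
trained identically to the transformer. Classical baselines (gradient
boosting, AdaBoost, random forest, decision tree, SVM, k-NN, logistic
regression, Gaussian NB) use scikit-learn defaults; XGBoost uses the tuned
values colsample_bytree 0.3, γ 0, lr 0.2, depth 10, min_child_weight 1.

## Depth experiment

The depth sweep varies the transformer's encoder-block count against an MLP
whose depth is counted in *hidden units*, where one hidden unit is a stack
group of three FC+relu+dropout layers of fixed width (default 256) —
mirroring the base MLP, which is itself a three-hidden-layer FC stack. This
reading matters: a plain MLP of eight single layers remains trainable under
Adam (its per-parameter step normalisation compensates for the ~6× per-layer
activation-variance decay of fan-in uniform init + relu), and probing widths
32–2048 and effect sizes 0.5–2 never produced chance-level performance at
eight single layers. At eight three-layer units (24 layers) the forward
signal decays by ~6²⁴ and minibatch gradient noise dominates: the loss stays
at log 2 and AUC sits at chance, while the transformer — whose residual
paths and layer norms preserve signal scale — is flat in depth from 1 to 8
encoders. This is the regime the depth-robustness tests pin down.

## Synthetic cohorts

`CohortSpec` defaults describe the study population: 188 case and 64 control
subjects, three recordings each (m = 756), 753 features in category blocks
(21 baseline / 84 MFCC / 182 wavelet / 432 TQWT / 22 vocal-fold / 12 other —
implementation-chosen sizes summing to the real total; the true per-category
counts are not public as text). Each block is an equicorrelated Gaussian
(ρ_block = 0.3), each subject adds a N(0, 0.5²) scalar effect shared across
recordings (inducing within-subject correlation), residual noise is
N(0, 1), and the first `informative_count` features gain an
`effect_size`·(marginal sd) mean shift for cases. Gender is uninformative
per-subject metadata, optionally emitted as a feature column to exercise the
zero-importance path.

The generator reproduces the *structural* assumptions the pipeline relies on
— grouping, imbalance, block correlation, sparse signal — not the marginal
distributions of real dysphonia measures (skewness, heavy tails,
heteroscedastic measurement noise) nor nonlinear or interaction effects.
Passing tests therefore demonstrate that the machinery is correct and that
signal of the planted form is recovered; they do not certify clinical
performance on real voice data.

Test and acceptance runs use a reduced cohort — 45 case / 15 control
subjects × 3 recordings, 100 features in 3 blocks, 20 informative — and a
narrow transformer (d = 16, L = 2, ρ = 2, head 64, top-N 20–32, ≤ 20
epochs). These sizes are the package's chosen desk-scale study conditions;
the full-size default configuration is exercised where training is not
required (parameter counting, shape checks).

## Known limitations

- The numpy training loop is single-threaded and unsuitable for the
  full-size network on large tables; it is meant for desk-scale studies and
  verification.
- Feature selection before ADASYN and the global (leaky) default scopes
  reproduce the historical protocol; for honest generalisation estimates use
  the `per-fold` scopes.
- The permutation ranker interprets "objective score" as held-in accuracy
  drop of the linear SVC, one of several defensible readings.
- Timing/throughput measurements are hardware-dependent and deliberately
  out of scope.
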