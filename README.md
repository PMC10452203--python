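# vocaltab

Transformer-based classification of Parkinson's disease (PD) from tabular
dysphonia measures — the numeric features (jitter and shimmer variants,
harmonic-to-noise ratios, MFCCs, wavelet and TQWT coefficients) extracted
from sustained-phonation voice recordings. The package is aimed at
researchers working with multi-recording voice cohorts: a few hundred
subjects, several recordings per subject, hundreds of correlated features,
and a marked class imbalance between PD cases and healthy controls.

## The method

Given a table θ = {(χᵢ, yᵢ)}ᵢ₌₁..ₘ of m recordings with n continuous
features each, the pipeline is:

1. **Standardization** per feature: χᵢⱼ = (xᵢⱼ − μⱼ)/σⱼ.
2. **Feature selection**: a gradient-boosted tree classifier (XGBoost,
   gbtree, 100 estimators, η = 0.3, depth 6) is fit and features are ranked
   by mean split gain; the top N (default 96) are kept. Linear-SVC weights
   and permutation score drops are available as alternative rankers.
3. **Per-feature embedding**: each selected scalar feature has its *own*
   two-layer network, FEᵢⱼ = Dropout(relu(FC₂^d(relu(FC₁^{d/2}(fᵢⱼ))))),
   producing an n × d embedding matrix (d = 64) per sample.
4. **Transformer encoder stack**: L = 6 post-norm encoder blocks; each
   applies multi-head self-attention across the n feature embeddings,
   A = softmax(QKᵀ/√k), followed by a position-wise feed-forward net that
   expands d by ρ = 32 (hidden width ρ·d = 2048), with residual connections
   and layer normalization after each sub-layer.
5. **MLP head**: the n × d output is flattened, projected to 2048 units
   (relu, dropout), then to a single sigmoid probability of PD.

At the default configuration the network carries ~14.5 million trainable
parameters. Training uses Adam (lr 8 × 10⁻⁴), binary cross-entropy, batch
size 32.

Evaluation follows the multi-recording protocol: **subject-grouped
stratified k-fold** splits (all recordings of a subject stay on one side of
every split), **ADASYN** oversampling of the minority class applied to the
training rows of each fold only, and ROC-AUC / precision / recall per fold,
averaged and reported as mean ± sd across repeated seeds. Because no deep
learning framework is assumed, the network, backpropagation and Adam are
implemented directly in numpy and verified against numerical gradients.

A synthetic-cohort generator (`vocaltab.synthetic`) emulates the structure
such studies exhibit — repeated recordings per subject, ~3:1 case:control
imbalance, correlated feature blocks per measure category, a planted subset
of class-informative features — so the entire pipeline is testable without
any external download. Real tables in the standard CSV layout (id, gender,
features…, class) are read with `read_dysphonia_csv`.

## Worked example

```python
from vocaltab import (SelectorConfig, TrainConfig, ModelConfig,
                      generate_cohort, run_kfold_experiment)
from vocaltab.synthetic import small_cohort_spec

# 60 subjects x 3 recordings, 100 features, moderate class effect (1 sd)
table = generate_cohort(small_cohort_spec(effect_size=1.0))
report = run_kfold_experiment(
    table,
    SelectorConfig(method="gbdt_gain", top_n=20),
    "vocaltab",
    TrainConfig(epochs=10, seeds=(0, 1, 2), folds=10),
    model_config=ModelConfig(embed_dim=16, n_encoders=2, rho=2, head_hidden=64),
)
for metric, s in report.summary.items():
    print(f"{metric}: {s['mean']:.4f} +/- {s['sd']:.4f}")
```

prints

```
auc: 0.9469 +/- 0.0108
precision: 0.9467 +/- 0.0092
recall: 0.9017 +/- 0.0109
```

i.e. on a cohort where twenty features carry a one-standard-deviation class
shift, the ten-fold subject-grouped AUC is ~0.95, stable across three
training seeds. Replacing `"vocaltab"` with `"xgboost"`, `"mlp"`,
`"random_forest"`, … runs the baseline suite under the identical pipeline.

The same operations are exposed on the command line:

```sh
vocaltab synth --seed 0 --out cohort.csv
vocaltab select --data cohort.csv --method gbdt --top-n 96 --out ranking.json
vocaltab run --data cohort.csv --model vocaltab --top-n 96 --folds 10 --out report.json
vocaltab sweep --data cohort.csv --axis depth --grid 1,2,4,8 --out sweep.json
```

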