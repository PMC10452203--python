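"""Training loop, k-fold orchestration, baseline suite, and parameter sweeps.

The evaluation protocol mirrors multi-recording voice studies: subject-grouped
stratified k-fold splits, per-fold ADASYN balancing of the training rows, and
ROC-AUC / precision / recall per fold, averaged within a run and reported as
mean +/- sd across repeated seeds. Feature standardization and selection can
each be fitted globally (the protocol's historical default, which leaks test
statistics) or refitted per training fold (leakage-safe).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .adasyn import AdasynConfig, adasyn_oversample
from .data import (
    DysphoniaTable,
    FoldPlan,
    apply_standardizer,
    fit_standardizer,
    make_grouped_stratified_folds,
)
from .metrics import precision_recall, roc_auc
from .model import MLPConfig, MLPNet, ModelConfig, VocalTabTransformer
from .nn import Adam, bce_with_logits
from .selection import SelectorConfig, rank_features, select_top_n

NEURAL_KINDS = ("vocaltab", "mlp")
BASELINE_KINDS = (
    "xgboost",
    "gradient_boosting",
    "adaboost",
    "random_forest",
    "decision_tree",
    "svm",
    "kneighbors",
    "logistic_regression",
    "gaussian_nb",
)
MODEL_KINDS = NEURAL_KINDS + BASELINE_KINDS


@dataclass
class TrainConfig:
    """Optimisation settings: Adam, binary cross-entropy, fixed 0.5 threshold."""

    learning_rate: float = 8e-4
    batch_size: int = 32
    epochs: int = 20
    threshold: float = 0.5
    seeds: tuple = (0, 1, 2)
    folds: int = 10

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate must be > 0 and epochs >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


def _child_seed(*keys: int) -> int:
    """Deterministic sub-seed below 2^31 from a tuple of integers."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig | MLPConfig,
    train_config: TrainConfig | None = None,
    seed: int = 0,
):
    """Minibatch-Adam training; returns (model, per-epoch mean loss history).

    The run ``seed`` controls weight initialisation, epoch shuffling and
    dropout, so identical inputs reproduce identical loss histories.
    """
    train_config = train_config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    config = replace(config, seed=_child_seed(seed, 0))
    model = VocalTabTransformer(config) if isinstance(config, ModelConfig) else MLPNet(config)
    opt = Adam(model.parameters(), lr=train_config.learning_rate)
    rng = np.random.default_rng(_child_seed(seed, 1))
    m = X.shape[0]
    bs = train_config.batch_size
    history = []
    for _ in range(train_config.epochs):
        perm = rng.permutation(m)
        losses = []
        for start in range(0, m, bs):
            idx = perm[start : start + bs]
            logits = model.forward_logits(X[idx], training=True, rng=rng)
            loss, dlogits = bce_with_logits(logits, y[idx])
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def make_baseline(kind: str, seed: int = 0):
    """Classical classifiers at library defaults; XGBoost uses the tuned values."""
    if kind == "xgboost":
        return XGBClassifier(
            colsample_bytree=0.3,
            gamma=0.0,
            learning_rate=0.2,
            max_depth=10,
            min_child_weight=1,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    factories = {
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
        "random_forest": lambda: RandomForestClassifier(random_state=seed, n_jobs=1),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "svm": lambda: SVC(probability=True, random_state=seed),
        "kneighbors": lambda: KNeighborsClassifier(),
        "logistic_regression": lambda: LogisticRegression(max_iter=1000, random_state=seed),
        "gaussian_nb": lambda: GaussianNB(),
    }
    if kind not in factories:
        raise ValueError(f"unknown baseline {kind!r}; expected one of {MODEL_KINDS}")
    return factories[kind]()


@dataclass
class EvalReport:
    """Per-(seed, fold) metrics plus per-seed and overall aggregates."""

    rows: list = field(default_factory=list)  # dicts: seed, fold, auc, precision, recall
    per_seed: dict = field(default_factory=dict)  # seed -> {metric: fold-mean}
    summary: dict = field(default_factory=dict)  # metric -> {"mean", "sd"}
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        for row in self.rows:
            for key in ("auc", "precision", "recall"):
                if not 0.0 <= row[key] <= 1.0:
                    raise ValueError(f"metric {key} out of [0,1]: {row}")
        for stats in self.summary.values():
            if stats["sd"] < 0:
                raise ValueError("negative sd")

    def to_json(self, path) -> None:
        payload = {
            "rows": self.rows,
            "per_seed": {str(k): v for k, v in self.per_seed.items()},
            "summary": self.summary,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _aggregate(rows: list, seeds) -> tuple[dict, dict]:
    per_seed = {}
    for s in seeds:
        sub = [r for r in rows if r["seed"] == s]
        per_seed[s] = {
            k: float(np.mean([r[k] for r in sub])) for k in ("auc", "precision", "recall")
        }
    summary = {}
    for k in ("auc", "precision", "recall"):
        vals = np.array([per_seed[s][k] for s in seeds])
        summary[k] = {"mean": float(vals.mean()), "sd": float(vals.std())}
    return per_seed, summary


@dataclass
class FoldData:
    """Materialised train/test arrays for one fold of the pipeline."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    features: list


def prepare_fold(
    table: DysphoniaTable,
    fold: int,
    plan: FoldPlan,
    selector_config: SelectorConfig | None,
    adasyn_config: AdasynConfig | None,
    scaler_scope: str = "global",
    select_scope: str = "global",
    seed: int = 0,
    _global_table: DysphoniaTable | None = None,
    _global_features: list | None = None,
) -> FoldData:
    """Standardize -> select -> ADASYN for one fold.

    In ``per-fold`` scopes, statistics and rankings are fitted on the training
    rows only, so the test fold can never influence them.
    """
    train = plan.train_rows(table, fold)
    test = ~train

    if scaler_scope == "per-fold":
        std = fit_standardizer(table, rows=train)
        table_std = apply_standardizer(table, std)
    else:
        table_std = _global_table if _global_table is not None else apply_standardizer(
            table, fit_standardizer(table)
        )

    if selector_config is None:
        features = list(table.feature_names)
    elif select_scope == "per-fold":
        ranking = rank_features(table_std.subset_rows(train), selector_config)
        features = select_top_n(ranking, selector_config.top_n)
    else:
        features = _global_features
        if features is None:
            ranking = rank_features(table_std, selector_config)
            features = select_top_n(ranking, selector_config.top_n)

    sub = table_std.select_features(features)
    X_tr, y_tr = sub.values[train], sub.labels[train]
    if adasyn_config is not None:
        cfg = replace(adasyn_config, seed=_child_seed(adasyn_config.seed, seed, fold))
        X_tr, y_tr = adasyn_oversample(X_tr, y_tr, cfg)
    return FoldData(X_tr, y_tr, sub.values[test], sub.labels[test], features)


def fit_fold_model(
    fold_data: FoldData,
    model_kind: str,
    train_config: TrainConfig,
    seed: int,
    model_config: ModelConfig | None = None,
    mlp_config: MLPConfig | None = None,
):
    """Train the requested model kind on one fold; returns (model, score_fn)."""
    n = len(fold_data.features)
    if model_kind == "vocaltab":
        cfg = replace(model_config or ModelConfig(), n_features=n)
        model, _ = train_model(fold_data.X_train, fold_data.y_train, cfg, train_config, seed)
        return model, lambda X: model.forward(X)
    if model_kind == "mlp":
        cfg = replace(mlp_config or MLPConfig(), n_features=n)
        model, _ = train_model(fold_data.X_train, fold_data.y_train, cfg, train_config, seed)
        return model, lambda X: model.forward(X)
    clf = make_baseline(model_kind, seed=seed)
    clf.fit(fold_data.X_train, fold_data.y_train)
    return clf, lambda X: clf.predict_proba(X)[:, 1]


def run_kfold_experiment(
    table: DysphoniaTable,
    selector_config: SelectorConfig | None,
    model_kind: str,
    train_config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    mlp_config: MLPConfig | None = None,
    adasyn_config: AdasynConfig | None = AdasynConfig(),
    scaler_scope: str = "global",
    select_scope: str = "global",
    fold_seed: int = 0,
) -> EvalReport:
    """Full subject-grouped k-fold evaluation of one model kind.

    Per fold: standardize (per configured scope) -> select features (per
    configured scope) -> ADASYN-balance the training rows -> train -> score
    the held-out subjects. Repeated over ``train_config.seeds``; the fold plan
    itself is fixed by ``fold_seed`` so seeds only vary initialisation,
    shuffling and synthesis.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    train_config = train_config or TrainConfig()
    plan = make_grouped_stratified_folds(table, train_config.folds, fold_seed)

    global_table = None
    global_features = None
    if scaler_scope == "global":
        global_table = apply_standardizer(table, fit_standardizer(table))
    if selector_config is not None and select_scope == "global":
        base = global_table if global_table is not None else table
        ranking = rank_features(base, selector_config)
        global_features = select_top_n(ranking, selector_config.top_n)

    rows = []
    for seed in train_config.seeds:
        for fold in range(plan.k):
            fd = prepare_fold(
                table,
                fold,
                plan,
                selector_config,
                adasyn_config,
                scaler_scope,
                select_scope,
                seed=seed,
                _global_table=global_table,
                _global_features=global_features,
            )
            _, score = fit_fold_model(
                fd, model_kind, train_config, _child_seed(seed, fold, 2),
                model_config, mlp_config,
            )
            s = score(fd.X_test)
            prec, rec = precision_recall(s, fd.y_test, train_config.threshold)
            rows.append(
                {
                    "seed": seed,
                    "fold": fold,
                    "auc": roc_auc(s, fd.y_test),
                    "precision": prec,
                    "recall": rec,
                }
            )
    per_seed, summary = _aggregate(rows, train_config.seeds)
    report = EvalReport(
        rows=rows,
        per_seed=per_seed,
        summary=summary,
        provenance={
            "model_kind": model_kind,
            "selector": None if selector_config is None else asdict(selector_config),
            "features": global_features,
            "train": asdict(train_config),
            "adasyn": None if adasyn_config is None else asdict(adasyn_config),
            "scaler_scope": scaler_scope,
            "select_scope": select_scope,
            "fold_plan": {str(k): int(v) for k, v in plan.assignments.items()},
            "fold_seed": fold_seed,
        },
    )
    report.validate()
    return report


@dataclass
class SweepSpec:
    """One-axis hyperparameter sweep: everything else held fixed."""

    axis: str  # batch_size | n_heads | top_n | depth
    grid: tuple
    seeds: tuple = (0,)

    def __post_init__(self) -> None:
        if self.axis not in ("batch_size", "n_heads", "top_n", "depth"):
            raise ValueError(f"unknown sweep axis {self.axis!r}")
        if not self.grid:
            raise ValueError("grid must be non-empty")


def run_sweep(
    table: DysphoniaTable,
    spec: SweepSpec,
    selector_config: SelectorConfig | None = None,
    train_config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    mlp_width: int = 256,
    mlp_layers_per_unit: int = 3,
    **kfold_kwargs,
) -> dict:
    """Run one k-fold experiment per grid value.

    Returns {model_name: {value: {"mean": auc_mean, "sd": auc_sd}}}. For the
    ``depth`` axis the transformer varies its encoder-block count while the
    MLP baseline varies its number of stacked hidden units, each unit being a
    group of ``mlp_layers_per_unit`` fixed-width FC+relu+dropout layers
    (mirroring the base MLP's three-hidden-layer stack).
    """
    train_config = train_config or TrainConfig()
    train_config = replace(train_config, seeds=tuple(spec.seeds))
    model_config = model_config or ModelConfig()
    results: dict = {}

    def record(name: str, value, report: EvalReport) -> None:
        results.setdefault(name, {})[value] = dict(report.summary["auc"])

    for v in spec.grid:
        if spec.axis == "batch_size":
            tc = replace(train_config, batch_size=int(v))
            record("vocaltab", v, run_kfold_experiment(
                table, selector_config, "vocaltab", tc,
                model_config=model_config, **kfold_kwargs))
        elif spec.axis == "n_heads":
            mc = replace(model_config, n_heads=int(v))
            record("vocaltab", v, run_kfold_experiment(
                table, selector_config, "vocaltab", train_config,
                model_config=mc, **kfold_kwargs))
        elif spec.axis == "top_n":
            sc = replace(selector_config or SelectorConfig(), top_n=int(v))
            record("vocaltab", v, run_kfold_experiment(
                table, sc, "vocaltab", train_config,
                model_config=model_config, **kfold_kwargs))
        elif spec.axis == "depth":
            mc = replace(model_config, n_encoders=int(v))
            record("vocaltab", v, run_kfold_experiment(
                table, selector_config, "vocaltab", train_config,
                model_config=mc, **kfold_kwargs))
            mlp_cfg = MLPConfig.stacked(
                table.n_features, mlp_width, mlp_layers_per_unit * int(v)
            )
            record("mlp", v, run_kfold_experiment(
                table, selector_config, "mlp", train_config,
                mlp_config=mlp_cfg, **kfold_kwargs))
    return results


def plot_sweep(results: dict, axis_label: str, path) -> None:
    """Line chart of sweep AUCs (one line per model); requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, series in results.items():
        xs = sorted(series)
        means = [series[x]["mean"] for x in xs]
        sds = [series[x]["sd"] for x in xs]
        ax.errorbar(xs, means, yerr=sds, marker="o", label=name)
    ax.set_xlabel(axis_label)
    ax.set_ylabel("mean ROC-AUC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
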