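"""Dysphonia feature tables: ingestion, standardization, grouped k-fold plans.

A dysphonia table holds one row per voice recording: a subject identifier,
a binary Parkinson's-disease label (1 = PD, the majority and positive class;
0 = healthy), and a matrix of continuous vocal measurements (jitter/shimmer
variants, MFCCs, wavelet and TQWT coefficients, ...). Subjects contribute
several recordings, so evaluation splits must group rows by subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SYNTHETIC_SUBJECT = "__synthetic__"

FEATURE_CATEGORIES = ("baseline", "MFCC", "wavelet", "TQWT", "vocal-fold", "other")


class SchemaError(ValueError):
    """The CSV layout does not provide the declared id/label columns."""


class IntegrityError(ValueError):
    """The table violates a structural invariant (e.g. label flips within a subject)."""


@dataclass
class DysphoniaTable:
    """m recordings x n continuous vocal features, with subject grouping.

    Attributes
    ----------
    subject_ids : array of shape (m,), one identifier per recording row.
    feature_names : ordered feature-column names (length n).
    values : float matrix of shape (m, n).
    labels : int array of shape (m,), 1 = PD, 0 = healthy.
    gender : optional per-row categorical metadata.
    categories : optional mapping feature name -> measure category tag.
    """

    subject_ids: np.ndarray
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    gender: np.ndarray | None = None
    categories: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.feature_names = list(self.feature_names)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        m, n = self.values.shape
        if len(self.feature_names) != n:
            raise IntegrityError(
                f"{len(self.feature_names)} feature names for {n} columns"
            )
        if self.subject_ids.shape != (m,) or self.labels.shape != (m,):
            raise IntegrityError("subject_ids/labels length mismatch with values")
        if not np.isfinite(self.values).all():
            raise IntegrityError("non-finite feature values after ingestion")
        if not np.isin(self.labels, (0, 1)).all():
            raise IntegrityError("labels must be 0 (healthy) or 1 (PD)")
        for sid in np.unique(self.subject_ids):
            labs = np.unique(self.labels[self.subject_ids == sid])
            if labs.size > 1:
                raise IntegrityError(f"subject {sid!r} carries both labels")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subjects(self) -> np.ndarray:
        """Unique subject ids in first-appearance order."""
        _, idx = np.unique(self.subject_ids, return_index=True)
        return self.subject_ids[np.sort(idx)]

    def subject_labels(self) -> dict:
        out = {}
        for sid in self.subjects():
            out[sid] = int(self.labels[self.subject_ids == sid][0])
        return out

    def subset_rows(self, rows: np.ndarray) -> "DysphoniaTable":
        rows = np.asarray(rows)
        return DysphoniaTable(
            subject_ids=self.subject_ids[rows],
            feature_names=self.feature_names,
            values=self.values[rows],
            labels=self.labels[rows],
            gender=None if self.gender is None else self.gender[rows],
            categories=self.categories,
        )

    def select_features(self, names: list[str]) -> "DysphoniaTable":
        index = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in index]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        cols = [index[f] for f in names]
        return DysphoniaTable(
            subject_ids=self.subject_ids,
            feature_names=list(names),
            values=self.values[:, cols],
            labels=self.labels,
            gender=self.gender,
            categories=self.categories,
        )

    def to_dataframe(self, schema: "ColumnSchema | None" = None) -> pd.DataFrame:
        schema = schema or ColumnSchema()
        data = {schema.id: self.subject_ids}
        if self.gender is not None and schema.gender:
            data[schema.gender] = self.gender
        for j, f in enumerate(self.feature_names):
            data[f] = self.values[:, j]
        data[schema.label] = self.labels
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ColumnSchema:
    """Column-role mapping for dysphonia CSV files (UCI-style layout)."""

    id: str = "id"
    label: str = "class"
    gender: str | None = "gender"


def read_dysphonia_csv(
    path, schema: ColumnSchema | None = None, on_missing: str = "reject"
) -> DysphoniaTable:
    """Read a dysphonia CSV into a validated :class:`DysphoniaTable`.

    Every column other than the id/label/gender roles is treated as a feature,
    in file order. Rows with missing or non-numeric feature entries are handled
    per ``on_missing``: ``"reject"`` (drop the row, with a warning), ``"error"``,
    or ``"impute"`` (per-feature mean of the valid rows).
    """
    schema = schema or ColumnSchema()
    df = pd.read_csv(path)
    for col in (schema.id, schema.label):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found in {list(df.columns)[:6]}")
    gender = None
    gender_col = schema.gender if schema.gender in df.columns else None
    roles = {schema.id, schema.label} | ({gender_col} if gender_col else set())
    feature_names = [c for c in df.columns if c not in roles]
    feats = df[feature_names].apply(pd.to_numeric, errors="coerce")
    bad = feats.isna().any(axis=1).to_numpy()
    if bad.any():
        if on_missing == "error":
            raise IntegrityError(f"{int(bad.sum())} rows with missing/non-numeric entries")
        if on_missing == "reject":
            warnings.warn(f"dropping {int(bad.sum())} rows with missing entries")
            df = df.loc[~bad].reset_index(drop=True)
            feats = feats.loc[~bad].reset_index(drop=True)
        elif on_missing == "impute":
            feats = feats.fillna(feats.mean())
        else:
            raise ValueError(f"unknown on_missing policy {on_missing!r}")
    labels = pd.to_numeric(df[schema.label], errors="coerce")
    if labels.isna().any() or not labels.isin([0, 1]).all():
        raise IntegrityError("label column must be binary 0/1")
    if gender_col:
        gender = df[gender_col].to_numpy()
    return DysphoniaTable(
        subject_ids=df[schema.id].astype(str).to_numpy(),
        feature_names=feature_names,
        values=feats.to_numpy(dtype=float),
        labels=labels.to_numpy(dtype=int),
        gender=gender,
    )


def write_dysphonia_csv(table: DysphoniaTable, path, schema: ColumnSchema | None = None) -> None:
    table.to_dataframe(schema).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Standardization: chi_ij = (x_ij - mu_j) / sigma_j
# ---------------------------------------------------------------------------


@dataclass
class StandardizationParams:
    """Per-feature location/scale, with provenance of the fitting rows.

    ``sigma`` uses the population convention (ddof=0) by default; ``fit_rows``
    records whether statistics came from the full table or a training fold.
    """

    mu: np.ndarray
    sigma: np.ndarray
    fit_rows: str = "all"

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu/sigma length mismatch")
        if (self.sigma < 0).any():
            raise ValueError("sigma must be non-negative")


def fit_standardizer(
    table: DysphoniaTable,
    rows: np.ndarray | None = None,
    ddof: int = 0,
    fit_rows: str | None = None,
) -> StandardizationParams:
    """Per-feature mean and standard deviation over ``rows`` (default: all)."""
    if rows is None:
        x = table.values
        desc = "all"
    else:
        rows = np.asarray(rows)
        if rows.size == 0 or (rows.dtype == bool and not rows.any()):
            raise ValueError("empty row subset")
        x = table.values[rows]
        desc = "training-fold"
    if x.shape[0] == 0:
        raise ValueError("empty row subset")
    return StandardizationParams(
        mu=x.mean(axis=0),
        sigma=x.std(axis=0, ddof=ddof),
        fit_rows=fit_rows or desc,
    )


def apply_standardizer(table: DysphoniaTable, params: StandardizationParams) -> DysphoniaTable:
    """Return a new table with chi = (x - mu) / sigma per feature.

    Zero-variance columns are mapped to 0 (guarded division) with a warning.
    """
    if params.mu.shape[0] != table.n_features:
        raise ValueError(
            f"standardizer fitted for {params.mu.shape[0]} features, table has {table.n_features}"
        )
    zero = params.sigma == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance feature(s) standardized to 0")
    sigma = np.where(zero, 1.0, params.sigma)
    chi = (table.values - params.mu) / sigma
    chi[:, zero] = 0.0
    return replace(table, values=chi)


# ---------------------------------------------------------------------------
# Subject-grouped stratified k-fold plans
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """Subject-level partition into k folds.

    All recordings of a subject fall in a single fold; per-class subject counts
    differ by at most one across folds (stratification at subject level).
    """

    k: int
    assignments: dict = field(default_factory=dict)
    seed: int = 0

    def test_subjects(self, fold: int) -> list:
        return [s for s, f in self.assignments.items() if f == fold]

    def test_rows(self, table: DysphoniaTable, fold: int) -> np.ndarray:
        subj = set(self.test_subjects(fold))
        return np.array([sid in subj for sid in table.subject_ids])

    def train_rows(self, table: DysphoniaTable, fold: int) -> np.ndarray:
        return ~self.test_rows(table, fold)


def make_grouped_stratified_folds(table: DysphoniaTable, k: int, seed: int) -> FoldPlan:
    """Stratified subject-grouped fold plan.

    Within each class, subjects are shuffled with ``seed`` and dealt round-robin
    to the k folds, so no subject's recordings ever straddle a train/test split
    and per-fold class proportions (counted in subjects) are within one subject
    of the global proportion.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    subject_labels = table.subject_labels()
    assignments: dict = {}
    for cls in (1, 0):
        members = [s for s, lab in subject_labels.items() if lab == cls]
        if len(members) < k:
            raise ValueError(
                f"class {cls} has {len(members)} subjects, fewer than k={k} folds"
            )
        order = rng.permutation(len(members))
        for pos, idx in enumerate(order):
            assignments[members[idx]] = pos % k
    return FoldPlan(k=k, assignments=assignments, seed=seed)
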