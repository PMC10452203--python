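"""Adaptive synthetic (ADASYN) oversampling of the minority class.

ADASYN targets the class imbalance of PD voice cohorts (healthy controls are
the minority) by synthesising minority points with a per-seed budget
proportional to local majority density: minority points surrounded by majority
neighbours receive more synthetic offspring. Each synthetic point is a uniform
interpolation between a minority seed and one of its minority nearest
neighbours, so synthesis never leaves the minority point cloud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .data import SYNTHETIC_SUBJECT, DysphoniaTable, FoldPlan


@dataclass
class AdasynConfig:
    """K nearest neighbours and the target minority/majority ratio beta.

    ``balance_ratio`` is the desired minority:majority count ratio after
    augmentation (1.0 = fully balanced), so the synthesis budget is
    G = round(beta * m_majority) - m_minority.
    """

    k_neighbors: int = 5
    balance_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.balance_ratio <= 1:
            raise ValueError("balance_ratio must be in (0, 1]")


def adasyn_oversample(
    X: np.ndarray, y: np.ndarray, config: AdasynConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Append ADASYN synthetic minority rows to (X, y).

    Original rows are returned unchanged and in order, followed by the
    synthetic rows (all carrying the minority label). Deterministic given
    ``config.seed``.
    """
    config = config or AdasynConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("ADASYN requires both classes present")
    if classes.size > 2:
        raise ValueError("binary labels expected")
    minority = classes[np.argmin(counts)]
    m_min = int(counts.min())
    m_maj = int(counts.max())
    K = config.k_neighbors
    if m_min < max(K, 2):
        raise ValueError(
            f"minority class has {m_min} rows < K={K}; lower k_neighbors"
        )

    G = int(round(config.balance_ratio * m_maj)) - m_min
    if G <= 0 or m_min == m_maj:
        return X.copy(), y.copy()

    min_idx = np.flatnonzero(y == minority)
    Xmin = X[min_idx]

    # density weights r_i: fraction of majority points among the K nearest
    # neighbours (any class, Euclidean), self excluded
    nn_all = NearestNeighbors(n_neighbors=K + 1).fit(X)
    _, nbr = nn_all.kneighbors(Xmin)
    nbr = nbr[:, 1:]  # drop self
    delta = (y[nbr] != minority).sum(axis=1)
    r = delta / K
    total = r.sum()
    if total == 0:
        warnings.warn("minority class fully isolated; distributing budget uniformly")
        r_hat = np.full(m_min, 1.0 / m_min)
    else:
        r_hat = r / total
    g = np.rint(r_hat * G).astype(int)

    # interpolation pool: K nearest *minority* neighbours of each seed
    k_pool = min(K, m_min - 1)
    nn_min = NearestNeighbors(n_neighbors=k_pool + 1).fit(Xmin)
    _, pool = nn_min.kneighbors(Xmin)
    pool = pool[:, 1:]

    rng = np.random.default_rng(config.seed)
    synth = []
    for i in range(m_min):
        if g[i] == 0:
            continue
        picks = rng.integers(0, k_pool, size=g[i])
        lam = rng.random(size=(g[i], 1))
        xi = Xmin[i]
        xz = Xmin[pool[i, picks]]
        synth.append(xi + lam * (xz - xi))
    if synth:
        Xs = np.vstack(synth)
        X_out = np.vstack([X, Xs])
        y_out = np.concatenate([y, np.full(len(Xs), minority, dtype=y.dtype)])
    else:
        X_out, y_out = X.copy(), y.copy()
    return X_out, y_out


def balance_training_fold(
    table: DysphoniaTable,
    fold: int,
    plan: FoldPlan,
    config: AdasynConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ADASYN-balance one fold's training rows only.

    Returns (X, y, subject_ids); synthetic rows carry the sentinel subject id
    so downstream bookkeeping can never mistake them for real recordings.
    Test-fold rows are untouched and unseen.
    """
    train = plan.train_rows(table, fold)
    X, y = table.values[train], table.labels[train]
    sids = table.subject_ids[train]
    X_out, y_out = adasyn_oversample(X, y, config)
    n_new = len(X_out) - len(X)
    sids_out = np.concatenate([sids, np.full(n_new, SYNTHETIC_SUBJECT, dtype=object)])
    return X_out, y_out, sids_out
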