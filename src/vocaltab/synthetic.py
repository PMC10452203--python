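"""Synthetic dysphonia cohorts with the structure the pipeline assumes.

The generator emulates the statistical shape of multi-recording PD voice
studies: a few hundred subjects with repeated sustained-phonation recordings,
~3:1 case:control imbalance, features organised in correlated category blocks
(baseline, MFCC, wavelet, TQWT, vocal-fold, other), a small subset of
class-informative features shifted for cases, and within-subject correlation
from a per-subject random effect. It makes no attempt to match the marginal
distributions of real jitter/shimmer/MFCC measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DysphoniaTable

#: block sizes per measure category; implementation-chosen values summing to 753
DEFAULT_BLOCKS: tuple = (
    ("baseline", 21),
    ("MFCC", 84),
    ("wavelet", 182),
    ("TQWT", 432),
    ("vocal-fold", 22),
    ("other", 12),
)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the main study population: 188 PD subjects and 64 healthy
    controls, three sustained-phonation recordings each, 753 features in
    category blocks. ``effect_size`` is the case-minus-control mean shift on
    informative features, in units of the marginal feature SD.
    """

    n_case_subjects: int = 188
    n_control_subjects: int = 64
    reps_per_subject: int = 3
    block_sizes: tuple = DEFAULT_BLOCKS
    informative_count: int = 20
    effect_size: float = 1.0
    within_block_corr: float = 0.3
    subject_sd: float = 0.5
    noise_sd: float = 1.0
    gender_as_feature: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case_subjects, self.n_control_subjects, self.reps_per_subject) < 1:
            raise ValueError("subject and repetition counts must be positive")
        if not 0 <= self.within_block_corr < 1:
            raise ValueError("within_block_corr must be in [0, 1)")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("sds must be non-negative")
        if not 0 <= self.informative_count <= self.n_features:
            raise ValueError("informative_count out of range")

    @property
    def n_features(self) -> int:
        return sum(size for _, size in self.block_sizes)

    @property
    def n_samples(self) -> int:
        return (self.n_case_subjects + self.n_control_subjects) * self.reps_per_subject

    @property
    def marginal_sd(self) -> float:
        # block gaussian (unit var) + subject effect + residual noise
        return float(np.sqrt(1.0 + self.subject_sd**2 + self.noise_sd**2))


def feature_names_for(spec: CohortSpec) -> list[str]:
    names = []
    for cat, size in spec.block_sizes:
        names.extend(f"{cat}_{i + 1:03d}" for i in range(size))
    return names


def oracle_informative_features(spec: CohortSpec) -> list[str]:
    """Ground-truth informative feature names (the first ``informative_count``)."""
    return feature_names_for(spec)[: spec.informative_count]


def generate_cohort(spec: CohortSpec) -> DysphoniaTable:
    """Draw a cohort table; byte-identical for identical specs.

    Per recording row, each feature block is an equicorrelated Gaussian
    (correlation ``within_block_corr``, unit variance), to which a per-subject
    N(0, subject_sd^2) scalar effect and N(0, noise_sd^2) residual noise are
    added. Cases (label 1) receive ``effect_size * marginal_sd`` extra mean on
    the informative features.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_features
    n_subj = spec.n_case_subjects + spec.n_control_subjects
    m = spec.n_samples
    reps = spec.reps_per_subject

    subject_ids = np.array(
        [f"case_{i + 1:03d}" for i in range(spec.n_case_subjects)]
        + [f"ctrl_{i + 1:03d}" for i in range(spec.n_control_subjects)]
    )
    subject_label = np.array([1] * spec.n_case_subjects + [0] * spec.n_control_subjects)

    row_subject = np.repeat(np.arange(n_subj), reps)
    labels = subject_label[row_subject]

    c = spec.within_block_corr
    n_blocks = len(spec.block_sizes)
    shared = rng.standard_normal((m, n_blocks))
    eps = rng.standard_normal((m, n))
    u = rng.normal(0.0, spec.subject_sd, size=n_subj)
    noise = rng.normal(0.0, spec.noise_sd, size=(m, n))

    x = np.empty((m, n))
    j = 0
    for b, (_, size) in enumerate(spec.block_sizes):
        x[:, j : j + size] = (
            np.sqrt(c) * shared[:, [b]] + np.sqrt(1.0 - c) * eps[:, j : j + size]
        )
        j += size
    x += u[row_subject, None] + noise

    if spec.informative_count:
        shift = spec.effect_size * spec.marginal_sd
        x[labels == 1, : spec.informative_count] += shift

    names = feature_names_for(spec)
    categories = {}
    j = 0
    for cat, size in spec.block_sizes:
        for i in range(size):
            categories[names[j + i]] = cat
        j += size

    gender_subj = rng.integers(0, 2, size=n_subj)
    gender = gender_subj[row_subject]
    if spec.gender_as_feature:
        x = np.hstack([x, gender[:, None].astype(float)])
        names = names + ["gender"]
        categories["gender"] = "other"

    return DysphoniaTable(
        subject_ids=subject_ids[row_subject],
        feature_names=names,
        values=x,
        labels=labels,
        gender=gender,
        categories=categories,
    )


#: a compact study-shaped cohort for fast end-to-end runs: same 3:1 imbalance
#: and repetition structure, scaled down in subjects and feature blocks
SMALL_BLOCKS: tuple = (("baseline", 30), ("MFCC", 30), ("wavelet", 40))


def small_cohort_spec(**overrides) -> CohortSpec:
    """A reduced cohort (60 subjects x 3 reps, 100 features) for quick pipelines."""
    defaults = dict(
        n_case_subjects=45,
        n_control_subjects=15,
        reps_per_subject=3,
        block_sizes=SMALL_BLOCKS,
        informative_count=20,
        effect_size=2.0,
        seed=0,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)
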