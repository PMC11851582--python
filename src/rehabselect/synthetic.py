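"""Synthetic shoulder-rehabilitation cohorts with controllable class structure.

The generator emulates the shape of the study cohort this package targets:
120 post-arthroplasty patients described by age and fifteen passive
range-of-motion (ROM) angles (five movements at three time points), with a
total rehabilitation time of 4-6 months binarized at 4.5 months into a fast
(class 0) and slow (class 1) prognosis group.

Features are truncated Gaussians around clinically plausible baselines, with
post-operative values improving over pre-operative on average.  Class
structure is injected by shifting the class-1 mean vector along a fixed unit
direction in feature space by ``separation`` within-class standard
deviations of *total Euclidean distance* — so separation 3.0 means the two
class centroids are 3 noise-SDs apart regardless of dimensionality, giving
strong but imperfect separability.  Rehabilitation times are drawn uniformly
from per-class ranges that straddle the threshold, so the binarization rule
recovers the generating class exactly (unless label noise is requested).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    DEFAULT_THRESHOLD,
    CaseTable,
    LabeledTable,
    binarize_outcome,
)

# (baseline mean, clip low, clip high) per feature, degrees except age in years
_FEATURE_SPEC = [
    ("age", 72.0, 40.0, 95.0),
    ("ff_pre", 80.0, 0.0, 180.0),
    ("hypre_pre", 20.0, 0.0, 60.0),
    ("ab_pre", 60.0, 0.0, 180.0),
    ("exr_pre", 20.0, 0.0, 90.0),
    ("inr_pre", 30.0, 0.0, 90.0),
    ("ff_post3", 110.0, 0.0, 180.0),
    ("hypre_post3", 30.0, 0.0, 60.0),
    ("ab_post3", 90.0, 0.0, 180.0),
    ("exr_post3", 30.0, 0.0, 90.0),
    ("inr_post3", 45.0, 0.0, 90.0),
    ("ff_post6", 140.0, 0.0, 180.0),
    ("hypre_post6", 40.0, 0.0, 60.0),
    ("ab_post6", 120.0, 0.0, 180.0),
    ("exr_post6", 45.0, 0.0, 90.0),
    ("inr_post6", 60.0, 0.0, 90.0),
]

FEATURE_BASELINES = np.array([m for _, m, _, _ in _FEATURE_SPEC])
CLIP_LOW = np.array([lo for _, _, lo, _ in _FEATURE_SPEC])
CLIP_HIGH = np.array([hi for _, _, _, hi in _FEATURE_SPEC])


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generator settings.

    ``separation`` is the Euclidean distance between class mean vectors in
    units of the (isotropic) within-class standard deviation; 0 means no
    class signal in the features at all.
    """

    n_cases: int = 120
    class1_fraction: float = 0.5
    separation: float = 3.0
    noise_sd: float = 10.0
    rehab_time_range_0: tuple[float, float] = (4.0, 4.4)
    rehab_time_range_1: tuple[float, float] = (4.5, 6.0)
    label_noise: float = 0.0
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        if not 0 < self.class1_fraction < 1:
            raise ValueError("class1_fraction must be in (0, 1)")
        if self.separation < 0 or self.noise_sd <= 0:
            raise ValueError("separation must be >= 0 and noise_sd > 0")
        for lo, hi in (self.rehab_time_range_0, self.rehab_time_range_1):
            if not (0 < lo <= hi <= 12):
                raise ValueError(f"rehab-time range ({lo}, {hi}) outside (0, 12]")
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must be in [0, 1]")
        if self.rehab_time_range_0[1] >= self.threshold:
            raise ValueError("class-0 rehab-time range must lie below the threshold")
        if self.rehab_time_range_1[0] < self.threshold:
            raise ValueError("class-1 rehab-time range must start at or above the threshold")


def _class_shift(separation: float, noise_sd: float, n_features: int) -> np.ndarray:
    """Shift vector of Euclidean length separation * noise_sd."""
    direction = np.ones(n_features) / np.sqrt(n_features)
    return separation * noise_sd * direction


def generate_table(config: SynthConfig = SynthConfig()
                   ) -> tuple[LabeledTable, np.ndarray]:
    """Generate a labeled cohort; returns (table, ground-truth class vector).

    With ``label_noise`` 0 the binarized labels equal the ground-truth
    classes for every case; a positive rate flips that many rehab times (in
    expectation) into the other class's range, decoupling features from
    labels.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    n1 = int(round(config.class1_fraction * n))
    truth = np.zeros(n, dtype=np.int64)
    truth[rng.choice(n, size=n1, replace=False)] = 1

    shift = _class_shift(config.separation, config.noise_sd, len(FEATURE_BASELINES))
    means = FEATURE_BASELINES[None, :] + truth[:, None] * shift[None, :]
    features = rng.normal(means, config.noise_sd)
    features = np.clip(features, CLIP_LOW[None, :], CLIP_HIGH[None, :])

    label_class = truth.copy()
    if config.label_noise > 0:
        flip = rng.random(n) < config.label_noise
        label_class = np.where(flip, 1 - label_class, label_class)
    lo0, hi0 = config.rehab_time_range_0
    lo1, hi1 = config.rehab_time_range_1
    rehab = np.where(
        label_class == 1,
        rng.uniform(lo1, hi1, size=n),
        rng.uniform(lo0, hi0, size=n),
    )
    table = CaseTable(
        features=features,
        rehab_time=rehab,
        case_ids=np.arange(1, n + 1, dtype=np.int64),
    )
    return binarize_outcome(table, config.threshold), truth


def generate_separable_toy(n_per_class: int, dims: int = 2, gap: float = 10.0,
                           seed: int = 0) -> LabeledTable:
    """Two unit-variance Gaussian blobs with centers ``gap`` apart per axis.

    With a large gap the blobs have a guaranteed margin, so 1-NN and 2-means
    classify them perfectly — the oracle input for exactness tests.  Labels
    are balanced (exactly n_per_class each); rehab times encode the class
    (4.0 below threshold, 5.0 above).
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    if dims < 1 or dims > 16:
        raise ValueError("dims must be in 1..16")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = np.array([0] * n_per_class + [1] * n_per_class, dtype=np.int64)
    pts = rng.normal(size=(n, dims))
    pts[labels == 1] += gap
    features = np.zeros((n, 16))
    features[:, :dims] = pts
    rehab = np.where(labels == 1, 5.0, 4.0)
    table = CaseTable(
        features=features, rehab_time=rehab,
        case_ids=np.arange(1, n + 1, dtype=np.int64),
    )
    return binarize_outcome(table, DEFAULT_THRESHOLD)
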