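"""Case-table data model, CSV I/O, outcome binarization and partitions.

A *case table* holds one row per patient: 16 numeric predictors (age plus
five passive range-of-motion angles measured pre-operatively and at 3 and 6
months post-operatively) and the total rehabilitation time in months.  The
rehabilitation time is binarized at a threshold (4.5 months by default) into
the two prognosis classes: class 0 for patients who recovered faster than the
threshold, class 1 for the rest.

All user-visible case indexing is 1-based and stable, matching the published
training-set listings shipped as fixtures.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical CSV column order: id column, 16 predictors, rehabilitation time.
CSV_COLUMNS = [
    "case_id",
    "age",
    "ff_pre", "hypre_pre", "ab_pre", "exr_pre", "inr_pre",
    "ff_post3", "hypre_post3", "ab_post3", "exr_post3", "inr_post3",
    "ff_post6", "hypre_post6", "ab_post6", "exr_post6", "inr_post6",
    "trt",
]

FEATURE_COLUMNS = CSV_COLUMNS[1:-1]
N_FEATURES = 16

#: Default binarization threshold for total rehabilitation time, in months.
DEFAULT_THRESHOLD = 4.5


class DataError(ValueError):
    """Raised for malformed case tables or illegal partitions."""


class DegeneratePartitionError(DataError):
    """Raised when a partition would leave the training or test side empty."""


@dataclass(frozen=True)
class CaseTable:
    """An N x 16 feature matrix plus rehabilitation times and 1-based ids."""

    features: np.ndarray          # (N, 16) float64
    rehab_time: np.ndarray        # (N,) float64, months
    case_ids: np.ndarray          # (N,) int64, 1-based

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        t = np.asarray(self.rehab_time, dtype=float)
        ids = np.asarray(self.case_ids, dtype=np.int64)
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "rehab_time", t)
        object.__setattr__(self, "case_ids", ids)
        if f.ndim != 2 or f.shape[1] != N_FEATURES:
            raise DataError(
                f"feature matrix must be N x {N_FEATURES}, got shape {f.shape}"
            )
        n = f.shape[0]
        if n < 2:
            raise DataError(f"a case table needs at least 2 cases, got {n}")
        if t.shape != (n,) or ids.shape != (n,):
            raise DataError("features, rehab_time and case_ids disagree on N")
        if not np.all(np.isfinite(f)):
            raise DataError("non-finite feature value in case table")
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise DataError("rehabilitation times must be finite and positive")
        if len(np.unique(ids)) != n:
            raise DataError("case_ids must be unique")

    @property
    def n_cases(self) -> int:
        return self.features.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=FEATURE_COLUMNS)
        df.insert(0, "case_id", self.case_ids)
        df["trt"] = self.rehab_time
        return df


@dataclass(frozen=True)
class LabeledTable:
    """A case table with its binary prognosis labels.

    ``labels[i] == 1`` exactly when ``rehab_time[i] >= threshold``.
    """

    table: CaseTable
    labels: np.ndarray            # (N,) int64 in {0, 1}
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", lab)
        if lab.shape != (self.table.n_cases,):
            raise DataError("labels must have one entry per case")
        if not np.all((lab == 0) | (lab == 1)):
            raise DataError("labels must be 0 or 1")

    @property
    def n_cases(self) -> int:
        return self.table.n_cases

    @property
    def features(self) -> np.ndarray:
        return self.table.features


@dataclass(frozen=True)
class Partition:
    """Disjoint train/test split of a table, by 1-based case id."""

    train_ids: tuple[int, ...]
    test_ids: tuple[int, ...]

    @property
    def S(self) -> int:
        """Training-set size."""
        return len(self.train_ids)

    def validate_against(self, table: LabeledTable | CaseTable) -> None:
        n = table.n_cases
        ids = table.table.case_ids if isinstance(table, LabeledTable) else table.case_ids
        universe = set(int(i) for i in ids)
        tr, te = set(self.train_ids), set(self.test_ids)
        if tr & te:
            raise DataError("train and test ids overlap")
        if tr | te != universe:
            raise DataError("partition does not cover all case ids")
        if not tr or not te:
            raise DegeneratePartitionError(
                f"degenerate partition: |train|={len(tr)}, |test|={len(te)}"
            )


@dataclass(frozen=True)
class FixtureTables:
    """The published optimal training-set case listings, one per algorithm."""

    gaclust_ids: tuple[int, ...]
    gaknn_ids: tuple[int, ...]
    gakmeans_ids: tuple[int, ...]
    ga2clust_ids: tuple[int, ...]

    def as_dict(self) -> dict[str, tuple[int, ...]]:
        return {
            "gaclust": self.gaclust_ids,
            "gaknn": self.gaknn_ids,
            "gakmeans": self.gakmeans_ids,
            "ga2clust": self.ga2clust_ids,
        }


def load_case_table(path) -> CaseTable:
    """Read a case table from CSV in the canonical schema.

    The header must name the 17 attribute columns in canonical order; a
    leading ``case_id`` column is optional (ids are assigned 1..N by row
    order when absent).  Every cell must parse as a finite real.
    """
    df = pd.read_csv(path)
    expected_no_id = CSV_COLUMNS[1:]
    cols = list(df.columns)
    if cols == CSV_COLUMNS:
        has_id = True
    elif cols == expected_no_id:
        has_id = False
    else:
        missing = [c for c in CSV_COLUMNS if c not in cols and c != "case_id"]
        raise DataError(
            f"unexpected CSV header {cols}; missing columns: {missing or 'none'}"
            f" (expected {CSV_COLUMNS} or the same without case_id)"
        )
    for col in expected_no_id:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | ~np.isfinite(numeric)
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 1
            raise DataError(f"non-numeric or missing value at row {row}, column '{col}'")
        df[col] = numeric.astype(float)
    if len(df) < 2:
        raise DataError(f"case table needs at least 2 rows, got {len(df)}")
    ids = (
        df["case_id"].astype(np.int64).to_numpy()
        if has_id
        else np.arange(1, len(df) + 1, dtype=np.int64)
    )
    return CaseTable(
        features=df[FEATURE_COLUMNS].to_numpy(dtype=float),
        rehab_time=df["trt"].to_numpy(dtype=float),
        case_ids=ids,
    )


def write_case_table(table: CaseTable, path) -> None:
    """Write a case table to CSV in the canonical schema (lossless round-trip)."""
    table.to_frame().to_csv(path, index=False, float_format="%.10g")


def binarize_outcome(table: CaseTable, threshold: float = DEFAULT_THRESHOLD) -> LabeledTable:
    """Binarize rehabilitation time: label 0 below *threshold*, 1 at or above."""
    if threshold <= 0:
        raise DataError(f"threshold must be positive, got {threshold}")
    labels = (table.rehab_time >= threshold).astype(np.int64)
    return LabeledTable(table=table, labels=labels, threshold=float(threshold))


def partition_from_genome(genome, table: LabeledTable) -> Partition:
    """Interpret a membership bit vector as a train/test split.

    Gene value 1 at position i puts case ``case_ids[i]`` in the training set;
    gene value 0 puts it in the test set.  All-ones and all-zeros genomes are
    rejected because evaluation needs both sides nonempty.
    """
    bits = np.asarray(genome, dtype=np.int64)
    n = table.n_cases
    if bits.shape != (n,):
        raise DataError(f"genome length {bits.shape} does not match N={n}")
    if not np.all((bits == 0) | (bits == 1)):
        raise DataError("genome must be binary")
    s = int(bits.sum())
    if s == 0 or s == n:
        raise DegeneratePartitionError(
            f"genome selects {s} of {n} cases; train and test must both be nonempty"
        )
    ids = table.table.case_ids
    return Partition(
        train_ids=tuple(int(i) for i in ids[bits == 1]),
        test_ids=tuple(int(i) for i in ids[bits == 0]),
    )


def train_fraction_size(n: int, fraction: float) -> int:
    """Training-set size for a fraction, rounded half-up (0.8 of 120 -> 96)."""
    return int(np.floor(fraction * n + 0.5))


def random_partition(table: LabeledTable, fraction: float, seed) -> Partition:
    """Sample a uniform random train/test split with S = round(fraction * N).

    ``seed`` may be an int or a numpy Generator; identical seeds give
    identical partitions.
    """
    n = table.n_cases
    s = train_fraction_size(n, fraction)
    if s < 1 or s > n - 1:
        raise DataError(
            f"fraction {fraction} gives training size {s}, outside 1..{n - 1}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = table.table.case_ids
    chosen = rng.choice(n, size=s, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    return Partition(
        train_ids=tuple(int(i) for i in ids[mask]),
        test_ids=tuple(int(i) for i in ids[~mask]),
    )


def split_arrays(table: LabeledTable, partition: Partition):
    """Materialize (X_train, y_train, X_test, y_test) for a partition."""
    partition.validate_against(table)
    id_to_row = {int(cid): i for i, cid in enumerate(table.table.case_ids)}
    tr = np.array([id_to_row[i] for i in partition.train_ids], dtype=np.int64)
    te = np.array([id_to_row[i] for i in partition.test_ids], dtype=np.int64)
    X = table.features
    y = table.labels
    return X[tr], y[tr], X[te], y[te]


def _read_fixture(name: str) -> tuple[int, ...]:
    text = (
        importlib.resources.files("rehabselect.fixtures")
        .joinpath(name)
        .read_text(encoding="utf-8")
    )
    values = tuple(int(tok) for tok in text.split())
    if any(b <= a for a, b in zip(values, values[1:])):
        raise DataError(f"fixture {name} is not strictly increasing")
    if values and (values[0] < 1 or values[-1] > 120):
        raise DataError(f"fixture {name} has indices outside 1..120")
    return values


def load_fixture_tables() -> FixtureTables:
    """Load the published optimal training-set case listings.

    These are the four case-index lists reported for GAClust, GAKNN,
    GAKmeans and GA2Clust on the original 120-patient cohort, transcribed
    verbatim; sizes are 64, 42, 50 and 43.
    """
    return FixtureTables(
        gaclust_ids=_read_fixture("gaclust_training_cases.txt"),
        gaknn_ids=_read_fixture("gaknn_training_cases.txt"),
        gakmeans_ids=_read_fixture("gakmeans_training_cases.txt"),
        ga2clust_ids=_read_fixture("ga2clust_training_cases.txt"),
    )
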