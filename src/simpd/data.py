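"""Dataset model, activity labeling and baseline train/test splitters.

The central object is :class:`AssayDataset`: an ordered collection of assayed
compounds (id, SMILES, activity in log units, optional registration date,
optional active/inactive label) together with the activity threshold used to
derive class labels. Three baseline splitters are provided:

* temporal — earliest compounds train, latest test (prospective validation);
* stratified random — class-stratified random partition;
* neighbor — compounds with few similar neighbors (Tanimoto >= 0.55 on
  radius-2 Morgan fingerprints) form the test set.

All splits are 80/20 by default; the test size is ``round(f * n)`` with
round-half-to-even.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .fingerprints import morgan_fingerprints, tanimoto_matrix

__all__ = [
    "ACTIVE",
    "INACTIVE",
    "DEFAULT_THRESHOLD",
    "NEIGHBOR_SIM_THRESHOLD",
    "CompoundRecord",
    "AssayDataset",
    "Split",
    "label_activity",
    "temporal_split",
    "random_stratified_split",
    "neighbor_count",
    "neighbor_split",
    "read_dataset_csv",
    "write_dataset_csv",
    "read_smiles_file",
    "write_split",
    "read_split",
]

ACTIVE = "active"
INACTIVE = "inactive"

#: Default activity cut-off in log units (pAC50 6.3 ~ 500 nM).
DEFAULT_THRESHOLD = 6.3

#: Tanimoto similarity at or above which two compounds count as neighbors.
NEIGHBOR_SIM_THRESHOLD = 0.55


def label_activity(activity: float, threshold: float) -> str:
    """Classify an activity value: active iff ``activity >= threshold``.

    The boundary is inclusive on the active side.
    """
    if not np.isfinite(activity):
        raise ValueError(f"activity must be finite, got {activity!r}")
    return ACTIVE if activity >= threshold else INACTIVE


@dataclass(frozen=True)
class CompoundRecord:
    """One assayed molecule."""

    id: str
    smiles: str
    activity: float | None = None
    date: object | None = None  # orderable: int ordinal or ISO-8601 timestamp
    label: str | None = None

    def resolved_label(self, threshold: float) -> str:
        """The explicit label if set, else derived from activity and threshold."""
        if self.label is not None:
            return self.label
        if self.activity is None:
            raise ValueError(f"record {self.id!r} has neither label nor activity")
        return label_activity(self.activity, threshold)


@dataclass
class AssayDataset:
    """An ordered set of compound records sharing one activity threshold."""

    records: list[CompoundRecord]
    threshold: float = DEFAULT_THRESHOLD
    assay_id: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate record id: {dup!r}")
        self._index = {r.id: i for i, r in enumerate(self.records)}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        return np.array([self._index[i] for i in ids], dtype=np.intp)

    def labels(self) -> np.ndarray:
        """Boolean array, True = active (explicit label or threshold-derived)."""
        return np.array(
            [r.resolved_label(self.threshold) == ACTIVE for r in self.records]
        )

    def activities(self) -> np.ndarray:
        return np.array(
            [np.nan if r.activity is None else r.activity for r in self.records]
        )

    def subset(self, ids: Iterable[str]) -> "AssayDataset":
        idx = self.index_of(ids)
        return AssayDataset(
            [self.records[i] for i in idx], self.threshold, self.assay_id
        )


@dataclass(frozen=True)
class Split:
    """A disjoint, covering train/test partition of a dataset's ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    strategy: str
    test_fraction: float
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def validate(self, dataset: AssayDataset) -> None:
        train, test = set(self.train_ids), set(self.test_ids)
        if train & test:
            raise ValueError("train and test sets overlap")
        if train | test != set(dataset.ids):
            raise ValueError("split does not cover the dataset")
        want = required_test_size(len(dataset), self.test_fraction)
        if len(test) != want:
            raise ValueError(f"|test| = {len(test)}, expected {want}")

    def train_index(self, dataset: AssayDataset) -> np.ndarray:
        return dataset.index_of(self.train_ids)

    def test_index(self, dataset: AssayDataset) -> np.ndarray:
        return dataset.index_of(self.test_ids)

    def test_mask(self, dataset: AssayDataset) -> np.ndarray:
        mask = np.zeros(len(dataset), dtype=bool)
        mask[self.test_index(dataset)] = True
        return mask


def required_test_size(n: int, test_fraction: float) -> int:
    """Number of test compounds: round-half-to-even of ``test_fraction * n``."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    k = int(round(test_fraction * n))  # Python round = banker's rounding
    if k == 0 or k == n:
        raise ValueError(f"degenerate split: n={n}, test_fraction={test_fraction}")
    return k


def _date_key(record: CompoundRecord):
    if record.date is None:
        raise ValueError(f"record {record.id!r} has no registration date")
    return (record.date, record.id)


def temporal_split(dataset: AssayDataset, test_fraction: float = 0.2) -> Split:
    """Earliest (1-f) of the records train, latest f test.

    Records are ordered by (date, id); the id tie-break makes equal-date
    datasets deterministic.
    """
    order = sorted(dataset.records, key=_date_key)
    k = required_test_size(len(dataset), test_fraction)
    train = tuple(r.id for r in order[: len(order) - k])
    test = tuple(r.id for r in order[len(order) - k :])
    return Split(train, test, "temporal", test_fraction)


def random_stratified_split(
    dataset: AssayDataset, test_fraction: float = 0.2, seed: int = 0
) -> Split:
    """Random split stratified on the activity class.

    Per-class test counts are ``round(f * class_size)`` adjusted by +-1
    (starting with the larger class) so they sum to the global test size.
    """
    rng = np.random.default_rng(seed)
    labels = dataset.labels()
    n = len(dataset)
    k = required_test_size(n, test_fraction)

    classes = [np.flatnonzero(labels), np.flatnonzero(~labels)]
    classes = [c for c in classes if len(c)]
    classes.sort(key=len, reverse=True)  # larger class absorbs the remainder
    counts = [int(round(test_fraction * len(c))) for c in classes]
    i = 0
    while sum(counts) != k:
        j = i % len(classes)
        step = 1 if sum(counts) < k else -1
        if 0 <= counts[j] + step <= len(classes[j]):
            counts[j] += step
        i += 1

    test_idx: list[int] = []
    for cls, c in zip(classes, counts):
        test_idx.extend(rng.choice(cls, size=c, replace=False))
    test_set = set(int(i) for i in test_idx)
    train = tuple(r.id for i, r in enumerate(dataset.records) if i not in test_set)
    test = tuple(dataset.records[i].id for i in sorted(test_set))
    return Split(train, test, "random", test_fraction, seed)


def neighbor_count(
    dataset: AssayDataset, similarity_threshold: float = NEIGHBOR_SIM_THRESHOLD
) -> np.ndarray:
    """Per-compound number of neighbors at Tanimoto >= threshold (self excluded).

    Radius-2 Morgan fingerprints, 2048 bits.
    """
    fps = morgan_fingerprints(dataset.smiles, radius=2)
    sim = tanimoto_matrix(fps)
    np.fill_diagonal(sim, 0.0)
    return (sim >= similarity_threshold).sum(axis=1)


def neighbor_split(
    dataset: AssayDataset,
    test_fraction: float = 0.2,
    seed: int = 0,
    similarity_threshold: float = NEIGHBOR_SIM_THRESHOLD,
) -> Split:
    """Sort by decreasing neighbor count; many-neighbor compounds train.

    Records with equal counts are permuted by the seed before cutting, so
    boundary ties are resolved randomly but reproducibly.
    """
    counts = neighbor_count(dataset, similarity_threshold)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    order = sorted(range(len(dataset)), key=lambda i: (-counts[i], perm[i]))
    k = required_test_size(len(dataset), test_fraction)
    train = tuple(dataset.records[i].id for i in order[: len(order) - k])
    test = tuple(dataset.records[i].id for i in order[len(order) - k :])
    return Split(train, test, "neighbor", test_fraction, seed,
                 {"similarity_threshold": similarity_threshold})


# ---------------------------------------------------------------------------
# File I/O


def _parse_date(value):
    if pd.isna(value):
        return None
    if isinstance(value, (int, np.integer)):
        return int(value)
    s = str(value)
    if s.lstrip("-").isdigit():
        return int(s)
    return pd.Timestamp(s)


def read_dataset_csv(
    path: str | Path,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    id_col: str = "id",
    smiles_col: str = "smiles",
    activity_col: str = "activity",
    date_col: str = "date",
    label_col: str = "label",
    assay_id: str = "",
) -> AssayDataset:
    """Load a dataset from CSV (UTF-8, header required, columns configurable)."""
    df = pd.read_csv(path)
    for col in (id_col, smiles_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    records = []
    for _, row in df.iterrows():
        activity = row.get(activity_col)
        activity = None if activity is None or pd.isna(activity) else float(activity)
        label = row.get(label_col)
        label = None if label is None or pd.isna(label) else str(label)
        date = _parse_date(row.get(date_col)) if date_col in df.columns else None
        records.append(
            CompoundRecord(str(row[id_col]), str(row[smiles_col]), activity, date, label)
        )
    return AssayDataset(records, threshold, assay_id or str(Path(path).stem))


def write_dataset_csv(dataset: AssayDataset, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": dataset.ids,
            "smiles": dataset.smiles,
            "activity": [r.activity for r in dataset.records],
            "date": [r.date for r in dataset.records],
            "label": [r.label for r in dataset.records],
        }
    )
    df.to_csv(path, index=False)


def read_smiles_file(path: str | Path, threshold: float = DEFAULT_THRESHOLD) -> AssayDataset:
    """Raw SMILES file: one ``smiles id`` (whitespace-separated) pair per line."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        smi = parts[0]
        cid = parts[1] if len(parts) > 1 else f"mol{lineno}"
        records.append(CompoundRecord(cid, smi))
    return AssayDataset(records, threshold, str(Path(path).stem))


def write_split(split: Split, prefix: str | Path) -> None:
    """Serialize as ``<prefix>.csv`` (id, partition) + ``<prefix>.json`` provenance."""
    prefix = Path(prefix)
    rows = [(i, "train") for i in split.train_ids] + [(i, "test") for i in split.test_ids]
    pd.DataFrame(rows, columns=["id", "partition"]).to_csv(
        prefix.with_suffix(".csv"), index=False
    )
    meta = {
        "strategy": split.strategy,
        "seed": split.seed,
        "test_fraction": split.test_fraction,
        "params": split.params,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_split(prefix: str | Path) -> Split:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    train = tuple(str(i) for i, p in zip(df["id"], df["partition"]) if p == "train")
    test = tuple(str(i) for i, p in zip(df["id"], df["partition"]) if p == "test")
    return Split(
        train, test, meta["strategy"], meta["test_fraction"], meta["seed"],
        meta.get("params", {}),
    )
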