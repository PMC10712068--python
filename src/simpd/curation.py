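"""Dataset-curation rules for project-style and public bioactivity data.

Pure predicates and transforms over in-memory records, mirroring the curation
pipeline used to assemble lead-optimization benchmark datasets:

* replicate aggregation with a variability cut,
* molecule-level property filters (MW window, N+O heteroatom fraction,
  optional external substructure filter),
* main-registration-period trimming,
* assay-level filters (activity range, class-balance, size window),
* overlap-based assay deduplication (Jaccard >= 0.5, keep the largest),
* the automatic 60/40 inactive/active threshold picker for public data.

Every drop carries one primary reason and the :class:`FilterReport` counts
reconcile exactly with the input/output sizes.
"""

from __future__ import annotations


import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from rdkit.Chem import Descriptors

from .data import (
    ACTIVE,
    DEFAULT_THRESHOLD,
    AssayDataset,
    CompoundRecord,
    label_activity,
    required_test_size,
)
from .fingerprints import mol_from_smiles

__all__ = [
    "RawMeasurement",
    "FilterReport",
    "aggregate_replicates",
    "property_filters",
    "main_period_filter",
    "assay_level_filters",
    "assay_dedup",
    "pick_60_40_threshold",
    "chembl_set_criteria",
    "curate_records",
]


@dataclass(frozen=True)
class RawMeasurement:
    """Repeated activity measurements of one compound in one assay."""

    id: str
    smiles: str
    pac50: tuple[float, ...]
    date: object | None = None
    project_code: str | None = None


@dataclass
class FilterReport:
    """Per-rule removal counts, in application order."""

    n_input: int = 0
    n_output: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    def record(self, reason: str) -> None:
        self.removed[reason] = self.removed.get(reason, 0) + 1

    def reconciles(self) -> bool:
        return self.n_input - self.n_output == sum(self.removed.values())


def aggregate_replicates(
    raw: RawMeasurement, *, max_rel_sd: float = 0.1
) -> tuple[CompoundRecord | None, str | None]:
    """Mean-combine replicates; reject noisy compounds.

    A compound is rejected when it has >= 2 replicates whose sample standard
    deviation exceeds ``max_rel_sd`` times the mean pAC50. Single measurements
    are kept (the sd is undefined).
    """
    values = np.asarray(raw.pac50, dtype=float)
    if values.size == 0 or not np.all(np.isfinite(values)):
        raise ValueError(f"record {raw.id!r}: empty or non-finite replicates")
    mean = float(values.mean())
    if values.size >= 2:
        sd = float(values.std(ddof=1))
        if sd > max_rel_sd * mean:
            return None, "replicate_variability"
    return CompoundRecord(raw.id, raw.smiles, mean, raw.date), None


def property_filters(
    record: CompoundRecord,
    *,
    mw_range: tuple[float, float] = (250.0, 700.0),
    no_frac_range: tuple[float, float] = (0.0, 0.6),
    substructure_filter: Callable[[CompoundRecord], bool] | None = None,
) -> tuple[bool, str | None]:
    """Molecule-level keep/drop decision with the primary drop reason.

    Drops: unparsable SMILES; molecular weight outside [250, 700] g/mol;
    (N+O)/heavy-atoms fraction outside the open interval (0, 0.6); and, if
    configured, a positive external substructure-filter match (the hook takes
    the record and returns True to drop).
    """
    try:
        mol = mol_from_smiles(record.smiles)
    except ValueError:
        return False, "unparsable_smiles"
    mw = Descriptors.MolWt(mol)
    if not mw_range[0] <= mw <= mw_range[1]:
        return False, "molecular_weight"
    n_heavy = mol.GetNumHeavyAtoms()
    n_no = sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))
    frac = n_no / n_heavy
    if not no_frac_range[0] < frac < no_frac_range[1]:
        return False, "heteroatom_fraction"
    if substructure_filter is not None and substructure_filter(record):
        return False, "substructure_filter"
    return True, None


def _year_of(date) -> int:
    if hasattr(date, "year"):
        return int(date.year)
    return int(date)  # integer ordinals are treated as years


def main_period_filter(
    records: Sequence[CompoundRecord], *, min_per_year: int = 50
) -> tuple[list[CompoundRecord], FilterReport]:
    """Keep records registered during the assay's main activity period.

    All years with more than ``min_per_year`` registrations are found; the
    window spans the first to the last such year (inclusive), so quiet years
    inside the window survive. Without any qualifying year the records are
    returned unchanged with a warning.
    """
    report = FilterReport(n_input=len(records))
    years = [_year_of(r.date) for r in records]
    counts = Counter(years)
    qualifying = sorted(y for y, c in counts.items() if c > min_per_year)
    if not qualifying:
        warnings.warn("no year exceeds the registration floor; keeping all records",
                      stacklevel=2)
        report.n_output = len(records)
        return list(records), report
    lo, hi = qualifying[0], qualifying[-1]
    kept = []
    for r, y in zip(records, years):
        if lo <= y <= hi:
            kept.append(r)
        else:
            report.record("outside_main_period")
    report.n_output = len(kept)
    return kept, report


def assay_level_filters(
    dataset: AssayDataset,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    min_range: float = 3.0,
    min_class_ratio: float = 0.05,
    size_range: tuple[int, int] = (200, 10_000),
) -> tuple[bool, str | None]:
    """Whole-assay keep/drop decision.

    Drops when: the pAC50 range is below ``min_range`` log units; the active
    or inactive ratio is below ``min_class_ratio`` in the whole set, the
    earliest 80 % or the latest 20 % (by registration date); or the assay size
    falls outside ``size_range``.
    """
    n = len(dataset)
    if not size_range[0] <= n <= size_range[1]:
        return False, "size"
    acts = dataset.activities()
    if np.ptp(acts[np.isfinite(acts)]) < min_range:
        return False, "activity_range"

    order = sorted(dataset.records, key=lambda r: (r.date, r.id))
    k = required_test_size(n, 0.2)
    slices = {
        "whole": order,
        "early80": order[: n - k],
        "late20": order[n - k :],
    }
    for name, chunk in slices.items():
        frac_active = np.mean(
            [label_activity(r.activity, threshold) == ACTIVE for r in chunk]
        )
        if frac_active < min_class_ratio or (1 - frac_active) < min_class_ratio:
            return False, f"class_ratio_{name}"
    return True, None


def assay_dedup(
    assays: Mapping[str, set],
    *,
    project_codes: Mapping[str, str] | None = None,
    jaccard_threshold: float = 0.5,
) -> list[str]:
    """Collapse near-duplicate assays; keep the largest of each group.

    ``assays`` maps assay id to its set of (compound id, label) pairs. Within
    each project code, assays are grouped by single linkage at Jaccard
    similarity >= ``jaccard_threshold``; the assay with the most measurements
    survives (ties to the lexically smallest id).
    """
    ids = sorted(assays)
    codes = project_codes or {}
    survivors = []
    by_project: dict[str, list[str]] = {}
    for a in ids:
        by_project.setdefault(codes.get(a, ""), []).append(a)

    for members in by_project.values():
        # single-linkage connected components over the Jaccard graph
        parent = {a: a for a in members}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                sa, sb = assays[a], assays[b]
                union = len(sa | sb)
                jac = len(sa & sb) / union if union else 1.0
                if jac >= jaccard_threshold:
                    parent[find(a)] = find(b)
        groups: dict[str, list[str]] = {}
        for a in members:
            groups.setdefault(find(a), []).append(a)
        for group in groups.values():
            survivors.append(max(group, key=lambda a: (len(assays[a]), a)))
    return sorted(survivors)


def pick_60_40_threshold(
    values: Sequence[float], *, inactive_frac: float = 0.6
) -> tuple[float, float]:
    """Pick the activity threshold giving an (approximately) 60/40
    inactive/active split.

    Actives are ``value >= threshold``. Candidate thresholds are the observed
    values; the one whose inactive fraction is closest to ``inactive_frac``
    wins (ties to the lower threshold). Returns ``(threshold,
    achieved_inactive_fraction)``; with heavy ties the achieved fraction can
    deviate from the target and is reported as observed.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    if n < 10:
        raise ValueError("need at least 10 values to pick a threshold")
    candidates = np.unique(values)
    frac_inactive = np.searchsorted(values, candidates, side="left") / n
    best = int(np.argmin(np.abs(frac_inactive - inactive_frac)))
    return float(candidates[best]), float(frac_inactive[best])


def chembl_set_criteria(
    *,
    n_unique_compounds: int,
    measurement_type: str | None,
    has_pchembl: bool | None,
    target_ids: Iterable | None,
    organisms: Iterable | None,
    categories: Iterable | None,
    bao_formats: Iterable | None,
    size_range: tuple[int, int] = (300, 1000),
) -> tuple[bool, str | None]:
    """Public-dataset selection rule.

    Keep iff the set is Ki-type with assigned pChEMBL values, has
    300-1000 unique compounds, and all combined assays agree on target id,
    organism, assay category and BAO format. Missing metadata drops the set.
    """
    meta = {
        "measurement_type": measurement_type,
        "has_pchembl": has_pchembl,
        "target_ids": target_ids,
        "organisms": organisms,
        "categories": categories,
        "bao_formats": bao_formats,
    }
    for key, value in meta.items():
        if value is None:
            return False, f"missing_{key}"
    if str(measurement_type).lower() != "ki":
        return False, "measurement_type"
    if not has_pchembl:
        return False, "no_pchembl"
    if not size_range[0] <= n_unique_compounds <= size_range[1]:
        return False, "size"
    for key in ("target_ids", "organisms", "categories", "bao_formats"):
        if len(set(meta[key])) > 1:
            return False, f"inconsistent_{key}"
    return True, None


def curate_records(
    raw: Sequence[RawMeasurement],
    *,
    max_rel_sd: float = 0.1,
    mw_range: tuple[float, float] = (250.0, 700.0),
    no_frac_range: tuple[float, float] = (0.0, 0.6),
    substructure_filter: Callable[[CompoundRecord], bool] | None = None,
    apply_main_period: bool = True,
    min_per_year: int = 50,
) -> tuple[list[CompoundRecord], FilterReport]:
    """Compound-level curation pipeline: aggregation, property filters,
    main-period trimming — in that order, with a reconciled report."""
    report = FilterReport(n_input=len(raw))
    records: list[CompoundRecord] = []
    for m in raw:
        rec, reason = aggregate_replicates(m, max_rel_sd=max_rel_sd)
        if rec is None:
            report.record(reason)
            continue
        keep, reason = property_filters(
            rec,
            mw_range=mw_range,
            no_frac_range=no_frac_range,
            substructure_filter=substructure_filter,
        )
        if not keep:
            report.record(reason)
            continue
        records.append(rec)
    if apply_main_period and records and all(r.date is not None for r in records):
        records, period_report = main_period_filter(records, min_per_year=min_per_year)
        for reason, count in period_report.removed.items():
            report.removed[reason] = report.removed.get(reason, 0) + count
    report.n_output = len(records)
    return records, report
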