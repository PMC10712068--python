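"""Curation predicates and transforms."""

import numpy as np
import pytest

from simpd.curation import (
    RawMeasurement,
    aggregate_replicates,
    assay_dedup,
    assay_level_filters,
    chembl_set_criteria,
    curate_records,
    main_period_filter,
    pick_60_40_threshold,
    property_filters,
)
from simpd.data import AssayDataset, CompoundRecord


class TestAggregateReplicates:
    def test_consistent_replicates_kept(self):
        rec, reason = aggregate_replicates(RawMeasurement("a", "CCO", (6.0, 6.0, 6.0)))
        assert reason is None and rec.activity == 6.0

    def test_noisy_replicates_rejected(self):
        # mean 6.0, sample sd ~1.414 > 0.6
        rec, reason = aggregate_replicates(RawMeasurement("a", "CCO", (5.0, 7.0)))
        assert rec is None and reason == "replicate_variability"

    def test_single_measurement_kept(self):
        rec, reason = aggregate_replicates(RawMeasurement("a", "CCO", (7.2,)))
        assert reason is None and rec.activity == 7.2


class TestPropertyFilters:
    def test_low_mw_dropped(self):
        keep, reason = property_filters(CompoundRecord("b", "c1ccccc1", 6.0))
        assert not keep and reason == "molecular_weight"

    def test_zero_heteroatom_fraction_dropped(self):
        # pure hydrocarbon in the MW window: strict > 0.0 rule
        smiles = "C" * 25  # C25H52, MW ~353
        keep, reason = property_filters(CompoundRecord("c", smiles, 6.0))
        assert not keep and reason == "heteroatom_fraction"

    def test_druglike_molecule_kept(self):
        # ~350 Da with a moderate N+O fraction
        smiles = "CC(=O)Nc1ccc(OCCN2CCOCC2)cc1C(=O)NC"
        keep, reason = property_filters(CompoundRecord("d", smiles, 6.0))
        assert keep and reason is None

    def test_unparsable_dropped(self):
        keep, reason = property_filters(CompoundRecord("e", "not_smiles", 6.0))
        assert not keep and reason == "unparsable_smiles"

    def test_substructure_hook(self):
        smiles = "CC(=O)Nc1ccc(OCCN2CCOCC2)cc1C(=O)NC"
        keep, reason = property_filters(
            CompoundRecord("f", smiles, 6.0), substructure_filter=lambda r: True
        )
        assert not keep and reason == "substructure_filter"


class TestMainPeriod:
    def _records(self, year_counts):
        records = []
        i = 0
        for year, count in year_counts.items():
            for _ in range(count):
                records.append(CompoundRecord(f"r{i}", "CCO", 6.0, year))
                i += 1
        return records

    def test_window_spans_first_to_last_qualifying_year(self):
        records = self._records({2001: 60, 2002: 10, 2003: 70, 2005: 5})
        kept, report = main_period_filter(records)
        years = {r.date for r in kept}
        assert years == {2001, 2002, 2003}  # quiet 2002 inside the window survives
        assert report.removed == {"outside_main_period": 5}
        assert report.reconciles()

    def test_single_qualifying_year(self):
        records = self._records({2001: 10, 2002: 60, 2003: 10})
        kept, _ = main_period_filter(records)
        assert {r.date for r in kept} == {2002}

    def test_no_qualifying_year_keeps_all(self):
        records = self._records({2001: 10, 2002: 20})
        with pytest.warns(UserWarning):
            kept, _ = main_period_filter(records)
        assert len(kept) == 30


class TestAssayLevelFilters:
    def _assay(self, activities, dates=None):
        dates = dates if dates is not None else range(len(activities))
        return AssayDataset(
            [
                CompoundRecord(f"a{i}", "CCO", act, d)
                for i, (act, d) in enumerate(zip(activities, dates))
            ]
        )

    def test_narrow_range_dropped(self):
        acts = list(np.linspace(5.0, 7.9, 250))  # range 2.9 < 3 log units
        keep, reason = assay_level_filters(self._assay(acts))
        assert not keep and reason == "activity_range"

    def test_all_active_tail_dropped(self):
        acts = [5.0 + 2.0 * (i % 7 == 0) for i in range(200)] + [9.0] * 50
        keep, reason = assay_level_filters(self._assay(acts))
        assert not keep and reason.startswith("class_ratio")

    def test_balanced_wide_assay_kept(self):
        rng = np.random.default_rng(0)
        acts = list(rng.uniform(4.5, 8.5, 300))
        keep, reason = assay_level_filters(self._assay(acts))
        assert keep and reason is None

    def test_size_bounds(self):
        acts = list(np.linspace(4, 9, 150))
        keep, reason = assay_level_filters(self._assay(acts))
        assert not keep and reason == "size"


class TestAssayDedup:
    def test_identical_assays_one_survivor(self):
        s = {("c1", "active"), ("c2", "inactive")}
        assert assay_dedup({"A": set(s), "B": set(s)}) in (["A"], ["B"])

    def test_disjoint_assays_both_survive(self):
        assays = {"A": {("c1", "active")}, "B": {("c2", "active")}}
        assert assay_dedup(assays) == ["A", "B"]

    def test_single_linkage_chain(self):
        # pairwise Jaccard: (A,B) and (B,C) >= 0.5, (A,C) < 0.5 -> one group
        base = [(f"c{i}", "active") for i in range(10)]
        a = set(base[:6])
        b = set(base[2:8])  # J(a,b) = 4/8 = 0.5
        c = set(base[4:10])  # J(b,c) = 4/8 = 0.5, J(a,c) = 2/10 = 0.2
        survivors = assay_dedup({"A": a, "B": b, "C": c})
        assert len(survivors) == 1

    def test_largest_assay_kept(self):
        big = {(f"c{i}", "active") for i in range(10)}
        small = {(f"c{i}", "active") for i in range(6)}  # J = 6/10 = 0.6
        assert assay_dedup({"small": small, "big": big}) == ["big"]


class TestThresholdPicker:
    def test_100_distinct_values(self):
        values = 4.0 + 0.05 * np.arange(100)
        threshold, frac = pick_60_40_threshold(values)
        assert frac == pytest.approx(0.6)
        assert np.mean(values < threshold) == pytest.approx(0.6)
        assert np.mean(values >= threshold) == pytest.approx(0.4)

    def test_ten_distinct_values(self):
        values = np.arange(10.0)
        threshold, frac = pick_60_40_threshold(values)
        assert np.sum(values < threshold) == 6
        assert np.sum(values >= threshold) == 4

    def test_all_identical_reports_deviation(self):
        threshold, frac = pick_60_40_threshold(np.full(20, 6.0))
        assert frac == 0.0  # everything active: deviation reported as achieved

    def test_threshold_reapplication_consistent(self):
        rng = np.random.default_rng(3)
        values = rng.normal(6, 1, 157)
        threshold, frac = pick_60_40_threshold(values)
        assert np.mean(values < threshold) == pytest.approx(frac)


class TestChemblCriteria:
    BASE = dict(
        n_unique_compounds=500,
        measurement_type="Ki",
        has_pchembl=True,
        target_ids=["T1"],
        organisms=["Homo sapiens"],
        categories=["confirmatory"],
        bao_formats=["BAO_0000357"],
    )

    def test_consistent_set_kept(self):
        keep, reason = chembl_set_criteria(**self.BASE)
        assert keep

    @pytest.mark.parametrize(
        "override, reason_part",
        [
            ({"n_unique_compounds": 299}, "size"),
            ({"n_unique_compounds": 1001}, "size"),
            ({"measurement_type": "IC50"}, "measurement_type"),
            ({"has_pchembl": False}, "no_pchembl"),
            ({"bao_formats": ["A", "B"]}, "inconsistent_bao_formats"),
            ({"target_ids": None}, "missing_target_ids"),
        ],
    )
    def test_drop_reasons(self, override, reason_part):
        keep, reason = chembl_set_criteria(**{**self.BASE, **override})
        assert not keep and reason == reason_part

    def test_boundary_sizes_inclusive(self):
        for n in (300, 1000):
            keep, _ = chembl_set_criteria(**{**self.BASE, "n_unique_compounds": n})
            assert keep


def test_pipeline_report_reconciles():
    raw = [
        RawMeasurement("ok", "CC(=O)Nc1ccc(OCCN2CCOCC2)cc1C(=O)NC", (6.5, 6.6), 2001),
        RawMeasurement("noisy", "CC(=O)Nc1ccc(OCCN2CCOCC2)cc1C(=O)NC", (4.0, 8.0), 2001),
        RawMeasurement("small", "c1ccccc1", (6.0,), 2001),
        RawMeasurement("bad", "xx", (6.0,), 2001),
    ]
    records, report = curate_records(raw, apply_main_period=False)
    assert [r.id for r in records] == ["ok"]
    assert report.n_input == 4 and report.n_output == 1
    assert report.reconciles()
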