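import numpy as np
import pytest

from chromforge.discovery import (
    AssignmentTable,
    Cell,
    CellFlag,
    ComponentCatalog,
    UnresolvedAlertError,
    assign,
    background_filter,
    build_catalog,
    diagnostics,
    ms_cosine,
    resolve,
    spectral_r,
)
from chromforge.mcr import ExtractedComponent
from conftest import spectrum_with_correlation

LAM = np.linspace(210, 400, 60)


def _spec(center, width=12.0, second=None):
    s = np.exp(-0.5 * ((LAM - center) / width) ** 2)
    if second:
        s = s + 0.5 * np.exp(-0.5 * ((LAM - second) / width) ** 2)
    return s / np.linalg.norm(s)


def _comp(run, spectrum, apex, pure=True, purity=1.0, ms=None):
    return ExtractedComponent(
        run_id=run,
        cluster_id=0,
        profile=np.ones(5),
        spectrum=spectrum / np.linalg.norm(spectrum),
        apex_time=apex,
        purity=purity,
        pure=pure,
        ms_spectrum=ms,
    )


class TestBuildCatalog:
    def test_same_component_in_all_runs_merges_to_one_entry(self):
        s = _spec(260)
        comps = [_comp(f"run{i}", s, 2.0 + 0.1 * i) for i in range(8)]
        cat = build_catalog(comps)
        assert len(cat.pure_set) == 1
        assert len(cat.pure_set[0].provenance_runs) == 8

    def test_identical_uv_different_ms_base_peaks_stay_separate(self):
        s = _spec(260)
        a = _comp("run1", s, 2.0, ms={154.0: 100.0, 120.0: 10.0})
        b = _comp("run2", s, 2.1, ms={182.0: 100.0, 140.0: 8.0})
        cat = build_catalog([a, b], ms_mode=True)
        assert len(cat.pure_set) == 2
        cat_uv = build_catalog([a, b], ms_mode=False)
        assert len(cat_uv.pure_set) == 1

    def test_component_pure_in_one_run_only_still_enters_pure_set(self):
        s1, s2 = _spec(240), _spec(320)
        comps = [
            _comp("run1", s1, 2.0, pure=True),
            _comp("run2", s1, 2.5, pure=False),
            _comp("run2", s2, 2.6, pure=False),
        ]
        cat = build_catalog(comps)
        assert len(cat.pure_set) == 1
        assert len(cat.mixed_set) == 2

    def test_empty_input_empty_catalog(self):
        cat = build_catalog([])
        assert cat.pure_set == [] and cat.mixed_set == []


class TestAssignmentThresholds:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.96, CellFlag.assigned), (0.85, CellFlag.alert), (0.5, CellFlag.unassigned)],
    )
    def test_threshold_bands(self, r, expected):
        base = _spec(260, second=330)
        entry_comp = _comp("run1", base, 2.0)
        cat = build_catalog([entry_comp])
        probe = spectrum_with_correlation(base, r, seed=3)
        table = assign(cat, {"run1": [_comp("run1", probe, 2.0)]})
        cell = table.cell(cat.pure_set[0].entry_id, "run1")
        assert cell.flag is expected
        if expected is CellFlag.assigned:
            assert cell.tR == 2.0
        else:
            assert cell.tR is None
        assert cell.best_r == pytest.approx(r, abs=1e-6)

    def test_competing_entries_higher_r_wins(self):
        base = _spec(260, second=330)
        near = spectrum_with_correlation(base, 0.93, seed=1)  # below merge limit
        cat = build_catalog([_comp("run1", base, 2.0), _comp("run1", near, 3.0)])
        assert len(cat.pure_set) == 2
        # one extracted component correlating with both entries
        probe = spectrum_with_correlation(base, 0.99, seed=2)
        table = assign(cat, {"run2": [_comp("run2", probe, 5.0)]})
        flags = [table.cell(e.entry_id, "run2").flag for e in cat.pure_set]
        assert flags.count(CellFlag.assigned) == 1
        # the base-spectrum entry correlates higher and must win
        winner = max(
            cat.pure_set, key=lambda e: spectral_r(e.spectrum, probe)
        )
        assert table.cell(winner.entry_id, "run2").flag is CellFlag.assigned

    def test_no_component_consumed_twice_per_run(self, discovered):
        catalog, table, extracted = discovered
        for rid in table.run_ids:
            taken = [
                table.cell(e, rid).tR
                for e in table.entries
                if table.cell(e, rid).flag is CellFlag.assigned
            ]
            assert len(taken) == len(set(taken))


class TestBackgroundFilter:
    def test_drift_like_entry_flagged_not_deleted(self, campaign):
        spec, runs, _ = campaign
        lam = spec.uv_axis.values
        # inject a known sloped drift spectrum and give one catalog entry
        # that exact spectral shape
        drift_spec = np.linspace(1.0, 0.3, len(lam))
        seed_spec = np.exp(-0.5 * ((lam - 260) / 12.0) ** 2)
        cat = build_catalog([_comp("run1", seed_spec, 2.0)])
        cat.pure_set[0].spectrum = drift_spec / np.linalg.norm(drift_spec)
        from chromforge.synthgen import BaselineModel, simulate_run
        import dataclasses

        spec2 = dataclasses.replace(
            spec,
            baseline=BaselineModel(drift_coeffs=(0.02,), drift_spectrum=drift_spec),
        )
        drifted = [simulate_run(spec2, 0)]
        out = background_filter(cat, drifted)
        assert out.pure_set[0].artifact  # flagged
        assert len(out.pure_set) == 1  # never deleted
        assert out.active_entries == []

    def test_orthogonal_entry_untouched(self, campaign):
        spec, runs, _ = campaign
        lam = spec.uv_axis.values
        narrow = np.exp(-0.5 * ((lam - 260) / 6.0) ** 2)
        cat = build_catalog([_comp("run1", narrow, 2.0)])
        out = background_filter(cat, runs[:2])
        assert not out.pure_set[0].artifact


class TestDiagnostics:
    def _table_for(self, cat, assignments):
        cells = {}
        run_ids = sorted({rid for _, rid in assignments})
        for e in cat.pure_set:
            for rid in run_ids:
                tR = assignments.get((e.entry_id, rid))
                cells[(e.entry_id, rid)] = (
                    Cell(tR, CellFlag.assigned, 0.99)
                    if tR is not None
                    else Cell(None, CellFlag.unassigned, 0.0)
                )
        return AssignmentTable([e.entry_id for e in cat.pure_set], run_ids, cells)

    def test_duplicate_entry_reported_as_redundancy(self):
        s = _spec(260)
        cat = build_catalog([_comp("run1", s, 2.0)])
        # force a duplicate entry past the merge by inserting directly
        import copy

        dup = copy.deepcopy(cat.pure_set[0])
        dup.entry_id = 99
        cat.pure_set.append(dup)
        table = self._table_for(
            cat, {(cat.pure_set[0].entry_id, "run1"): 2.0, (99, "run1"): 2.001}
        )
        rep = diagnostics(table, cat, dtr_tol=0.01)
        assert rep["redundancy"]
        pair = rep["redundancy"][0]["entries"]
        assert set(pair) == {cat.pure_set[0].entry_id, 99}

    def test_sum_spectrum_candidate_detected(self):
        s1, s2 = _spec(235), _spec(350)
        ssum = s1 + s2
        cat = build_catalog(
            [
                _comp("run1", s1, 2.0),
                _comp("run1", s2, 3.0),
                _comp("run1", ssum, 2.5),
            ]
        )
        assert len(cat.pure_set) == 3
        ids = [e.entry_id for e in cat.pure_set]
        table = self._table_for(
            cat,
            {
                (ids[0], "run1"): 2.00,
                (ids[1], "run1"): 2.001,  # co-eluting pair
                (ids[2], "run1"): 2.0005,
            },
        )
        rep = diagnostics(table, cat, dtr_tol=0.01)
        assert any(
            set(c["summands"]) == {ids[0], ids[1]} for c in rep["sum_spectrum"]
        )

    def test_column_inconsistency_detected(self):
        s = _spec(260)
        cat = build_catalog([_comp("run1", s, 2.0)])
        eid = cat.pure_set[0].entry_id
        table = self._table_for(cat, {(eid, "run1"): 2.0})
        # run2 exists but is unassigned; it belongs to the other column
        table.run_ids.append("run2")
        table.cells[(eid, "run2")] = Cell(None, CellFlag.unassigned, 0.3)
        rep = diagnostics(
            table, cat, column_of_run={"run1": "colA", "run2": "colB"}
        )
        assert rep["column_inconsistency"][0]["unassigned_columns"] == ["colB"]

    def test_clean_campaign_empty_report(self, campaign, discovered):
        _, runs, _ = campaign
        catalog, table, _ = discovered
        rep = diagnostics(
            table, catalog, sampling_interval=runs[0].sampling_interval
        )
        assert rep["redundancy"] == []
        assert rep["sum_spectrum"] == []


class TestResolve:
    def _small(self):
        s1, s2 = _spec(240), _spec(320)
        cat = build_catalog([_comp("run1", s1, 2.0), _comp("run1", s2, 3.0)])
        cells = {}
        for e in cat.pure_set:
            cells[(e.entry_id, "run1")] = Cell(2.0, CellFlag.assigned, 0.99)
            cells[(e.entry_id, "run2")] = Cell(None, CellFlag.alert, 0.9)
        table = AssignmentTable([e.entry_id for e in cat.pure_set], ["run1", "run2"], cells)
        return cat, table

    def test_delete_removes_entry_keeps_others(self):
        cat, table = self._small()
        doomed = cat.pure_set[1].entry_id
        survivor = cat.pure_set[0].entry_id
        t2, c2 = resolve(table, cat, [{"action": "delete", "entry": doomed}])
        assert len(c2.pure_set) == 1
        assert t2.cell(survivor, "run1").tR == 2.0

    def test_set_tR_converts_alert_to_manual(self):
        cat, table = self._small()
        eid = cat.pure_set[0].entry_id
        t2, _ = resolve(
            table, cat, [{"action": "set_tR", "entry": eid, "run_id": "run2", "tR": 4.2}]
        )
        cell = t2.cell(eid, "run2")
        assert cell.flag is CellFlag.manual and cell.tR == 4.2

    def test_edit_on_missing_entry_rejected(self):
        cat, table = self._small()
        with pytest.raises(KeyError):
            resolve(table, cat, [{"action": "delete", "entry": 12345}])

    def test_fitting_refused_with_outstanding_alerts(self):
        from chromforge.design import DesignMatrix, FactorDef, FactorRole
        from chromforge.retention import fit_all

        cat, table = self._small()
        f = [FactorDef("t_G", FactorRole.gradient_time, 5.0, 15.0)]
        dm = DesignMatrix(f, np.array([[-1.0], [1.0]]), ["calibration", "calibration"])
        with pytest.raises(UnresolvedAlertError):
            fit_all(table, dm, {}, mode="lss")


class TestSpectralMetrics:
    def test_ms_cosine_identical_and_disjoint(self):
        a = {137.0: 100.0, 93.0: 30.0}
        assert ms_cosine(a, a) == pytest.approx(1.0)
        assert ms_cosine(a, {500.0: 100.0}) == 0.0

    def test_run_order_invariance(self):
        """Catalog membership does not depend on the order runs arrive."""
        s1, s2 = _spec(240), _spec(320)
        comps = [
            _comp("run1", s1, 2.0),
            _comp("run2", s1, 2.5),
            _comp("run1", s2, 3.0),
            _comp("run2", s2, 3.5),
        ]
        cat_fwd = build_catalog(comps)
        cat_rev = build_catalog(comps[::-1])
        specs_fwd = sorted(np.argmax(e.spectrum) for e in cat_fwd.pure_set)
        specs_rev = sorted(np.argmax(e.spectrum) for e in cat_rev.pure_set)
        assert specs_fwd == specs_rev


def test_catalog_matches_truth_on_clean_campaign(campaign, discovered, entry_truth_map):
    """Every component elutes pure somewhere and spectra are distinct, so the
    catalog recovers exactly the true component set and assigned retention
    times agree with ground truth to within one sampling interval."""
    spec, runs, truth = campaign
    catalog, table, _ = discovered
    assert len(catalog.active_entries) == len(spec.components)
    names = [entry_truth_map[e.entry_id][0] for e in catalog.active_entries]
    assert sorted(names) == sorted(c.name for c in spec.components)
    assert min(entry_truth_map[e.entry_id][1] for e in catalog.active_entries) > 0.99
    dt = runs[0].sampling_interval
    for e in catalog.active_entries:
        name = entry_truth_map[e.entry_id][0]
        for rid, tR in table.tR_row(e.entry_id).items():
            assert abs(tR - truth.tR(name, rid)) <= dt
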