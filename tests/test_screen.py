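"""Cross-target matrix semantics and screening rules."""

from __future__ import annotations

import numpy as np
import pytest

from polyscreen.admet import ADMETProfile, default_ranges
from polyscreen.chem import CuratedDataset
from polyscreen.screen import (
    ScreenCandidate,
    ScreeningConfigError,
    ScreeningThresholds,
    build_cross_matrix,
    classify_side_effects,
    cross_grid_cells,
    find_repurposing,
    grid_partition,
    potent_inhibitors,
    prediction_correlation,
    screen_leads,
)

from conftest import StubModel


def stub_dataset(target_id, table):
    """table: compound_id -> (smiles, experimental ba)"""
    cids = list(table)
    return CuratedDataset(
        target_id,
        cids,
        [table[c][0] for c in cids],
        np.array([table[c][1] for c in cids]),
    )


SMILES = {"a": "CCO", "b": "CCN", "c": "CCS"}


def three_by_three():
    datasets = [
        stub_dataset("T1", {"a": (SMILES["a"], -8.0), "b": (SMILES["b"], -10.2), "c": (SMILES["c"], -9.6)}),
        stub_dataset("T2", {"d": ("CCCO", -9.0)}),
        stub_dataset("T3", {"e": ("CCCN", -7.0)}),
    ]
    models = [
        StubModel("T1", {SMILES["a"]: -8.0, SMILES["b"]: -10.2, SMILES["c"]: -9.6, "CCCO": -9.0, "CCCN": -7.5}),
        StubModel("T2", {SMILES["a"]: -8.0, SMILES["b"]: -10.2, SMILES["c"]: -9.6, "CCCO": -9.2, "CCCN": -6.0}),
        StubModel("T3", {SMILES["a"]: -9.55, SMILES["b"]: -9.54, SMILES["c"]: -9.0, "CCCO": -8.8, "CCCN": -7.0}),
    ]
    return datasets, models


class TestCrossMatrix:
    def test_grid_shape_and_diagonal(self):
        datasets, models = three_by_three()
        matrix = build_cross_matrix(models, datasets)
        assert matrix.grid_size == 9
        for tid in ("T1", "T2", "T3"):
            assert matrix.entry(tid, tid) == pytest.approx(0.9)  # stub CV R

    def test_offdiagonal_takes_max_absolute_ba(self):
        datasets, models = three_by_three()
        matrix = build_cross_matrix(models, datasets)
        # predictions of model T2 on dataset T1: {-8.0, -10.2, -9.6} -> -10.2
        assert matrix.entry("T1", "T2") == pytest.approx(-10.2)
        assert matrix.argmax_compound[("T1", "T2")] == "b"

    def test_grid_cell_arithmetic(self):
        assert cross_grid_cells(136, 136) == 18_496
        assert cross_grid_cells(3, 3) == 9

    def test_partition_remainder(self):
        total, remainder = grid_partition(136, 136, 15_318)
        assert (total, remainder) == (18_496, 3_178)

    def test_unfit_model_is_an_error(self):
        datasets, models = three_by_three()
        models[0].members = {}
        with pytest.raises(ScreeningConfigError, match="T1"):
            build_cross_matrix(models, datasets)


class TestSideEffectClassification:
    @pytest.mark.parametrize(
        "entry, flagged",
        [(-10.0, True), (-9.0, False), (-9.54, False)],  # strict "less than"
    )
    def test_threshold_strictness(self, entry, flagged):
        datasets = [
            stub_dataset("T1", {"a": (SMILES["a"], -8.0)}),
            stub_dataset("T2", {"d": ("CCCO", -9.0)}),
        ]
        models = [
            StubModel("T1", {SMILES["a"]: -8.0, "CCCO": -7.0}),
            StubModel("T2", {SMILES["a"]: entry, "CCCO": -8.0}),
        ]
        summary = classify_side_effects(build_cross_matrix(models, datasets))
        assert bool(summary.flags.loc["T1", "T2"]) is flagged

    def test_counts_partition_full_grid(self):
        datasets, models = three_by_three()
        summary = classify_side_effects(build_cross_matrix(models, datasets))
        assert summary.n_flagged + summary.n_unflagged == summary.grid_size == 9

    def test_diagonal_never_flagged(self):
        datasets, models = three_by_three()
        summary = classify_side_effects(build_cross_matrix(models, datasets))
        for tid in ("T1", "T2", "T3"):
            assert not summary.flags.loc[tid, tid]


def repurposing_fixture(herg_pred=-6.30):
    """One weak-on-origin compound with printed-value-style predictions."""
    datasets = [
        stub_dataset("ORIG", {"cand": ("CCO", -8.5), "potent": ("CCN", -10.0)}),
        stub_dataset("THER", {"t0": ("CCS", -10.0)}),
        stub_dataset("hERG", {"h0": ("CCCS", -8.0)}),
    ]
    models = [
        StubModel("ORIG", {"CCO": -8.5, "CCN": -10.0, "CCS": -8.0, "CCCS": -8.0}),
        StubModel("THER", {"CCO": -10.81, "CCN": -10.81, "CCS": -10.0, "CCCS": -7.0}),
        StubModel("hERG", {"CCO": herg_pred, "CCN": herg_pred, "CCS": -6.0, "CCCS": -8.0}),
    ]
    return datasets, models


class TestRepurposing:
    def test_candidate_found(self):
        datasets, models = repurposing_fixture()
        cands = find_repurposing(datasets, models, "THER")
        assert [c.compound_id for c in cands if c.origin_dataset == "ORIG"] == ["cand"]
        (cand,) = [c for c in cands if c.compound_id == "cand"]
        assert cand.therapeutic_ba == pytest.approx(-10.81)

    def test_herg_liability_rejected(self):
        datasets, models = repurposing_fixture(herg_pred=-8.35)
        cands = find_repurposing(datasets, models, "THER")
        assert all(c.compound_id != "cand" for c in cands)

    def test_potent_on_origin_excluded(self):
        datasets, models = repurposing_fixture()
        cands = find_repurposing(datasets, models, "THER")
        assert all(c.compound_id != "potent" for c in cands)

    def test_missing_herg_model_is_config_error(self):
        datasets, models = repurposing_fixture()
        with pytest.raises(ScreeningConfigError):
            find_repurposing(datasets, models[:2], "THER")

    def test_anti_monotone_in_side_effect_threshold(self):
        datasets, models = repurposing_fixture()
        loose = ScreeningThresholds(side_effect_ba=-9.54)
        strict = ScreeningThresholds(side_effect_ba=-10.5)
        found_loose = {c.compound_id for c in find_repurposing(datasets, models, "THER", loose)}
        found_strict = {c.compound_id for c in find_repurposing(datasets, models, "THER", strict)}
        # a more negative (more permissive) off-target bound never removes a candidate
        assert found_loose <= found_strict

    def test_potent_inhibitors_selects_experimental_binders(self):
        datasets, models = repurposing_fixture()
        cands = potent_inhibitors(datasets[1], models, ScreeningThresholds())
        assert [c.compound_id for c in cands] == ["t0"]


def make_candidate(cid="L1", ther=-10.0, herg=-6.0, off=-8.0):
    return ScreenCandidate(
        compound_id=cid,
        smiles="CCO",
        origin_dataset="THER",
        therapeutic_ba=ther,
        predictions={"THER": ther, "hERG": herg, "OFF": off},
    )


def profile(cid="L1", logp=1.5, logd=2.0, sas=3.0):
    return ADMETProfile(cid, {"logP": logp, "logD": logd, "SAS": sas})


class TestScreenLeads:
    def test_all_rules_pass(self):
        (report,) = screen_leads(
            [make_candidate()], "THER", {"L1": profile()}, default_ranges()
        )
        assert report.verdict
        assert report.failed_rules == []

    def test_single_rule_failure_flips_verdict(self):
        (report,) = screen_leads(
            [make_candidate()], "THER", {"L1": profile(logp=3.57)}, default_ranges()
        )
        assert not report.verdict
        assert report.flags["admet_pass"] is False
        assert all(v for k, v in report.flags.items() if k != "admet_pass")

    def test_missing_profile(self):
        (report,) = screen_leads([make_candidate()], "THER", {}, default_ranges())
        assert not report.flags["admet_pass"]
        assert "admet:missing" in report.failed_rules

    def test_empty_candidates(self):
        assert screen_leads([], "THER", {}, default_ranges()) == []

    def test_verdict_is_conjunction_exhaustively(self):
        rng = np.random.default_rng(1)
        ranges = default_ranges()
        for _ in range(200):
            cand = make_candidate(
                ther=rng.uniform(-12, -8),
                herg=rng.uniform(-10, -6),
                off=rng.uniform(-11, -7),
            )
            prof = profile(logp=rng.uniform(-1, 5), logd=rng.uniform(0, 4), sas=rng.uniform(1, 9))
            (report,) = screen_leads([cand], "THER", {"L1": prof}, ranges)
            assert report.verdict == all(report.flags.values())
            assert set(report.flags) == {
                "potent_on_therapeutic",
                "herg_safe",
                "off_target_clean",
                "admet_pass",
                "sas_pass",
            }


class TestPredictionCorrelation:
    def test_self_correlation_is_one(self):
        datasets, models = three_by_three()
        assert prediction_correlation(datasets[0], models[0], models[0]) == pytest.approx(1.0)

    def test_same_family_targets_correlate(self, small_world, small_datasets, small_models):
        by_id = {m.target_id: m for m in small_models}
        fam = {t.target_id: t.family for t in small_world.targets}
        same = [t for t in fam if fam[t] == 2]  # the one multi-target family
        a, b = by_id[same[0]], by_id[same[1]]
        ds = next(d for d in small_datasets if d.target_id == same[0])
        r_same = prediction_correlation(ds, a, b)
        assert r_same >= 0.7
        # cross-family correlation on the same compounds is weaker
        other = by_id["hERG"]
        assert prediction_correlation(ds, a, other) < r_same
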