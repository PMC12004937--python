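"""Activity parsing, unit conversion and curation rules."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyscreen.chem import (
    ActivityRecord,
    ActivityType,
    ConfigurationError,
    CurationCriteria,
    CuratedDataset,
    CurationRejection,
    DomainError,
    UsageError,
    ba_to_ki,
    curate_dataset,
    ic50_to_ki,
    ki_to_ba,
    parse_activity_table,
    standardize_records,
)


def record(
    cid="C1",
    smiles="CCO",
    atype=ActivityType.KI,
    value=1e-7,
    organism="Homo sapiens",
    target="T1",
    single=True,
):
    return ActivityRecord(cid, smiles, atype, value, organism, target, single)


class TestConversions:
    @pytest.mark.parametrize(
        "ki, expected",
        [
            (1.0e-7, -9.5431),  # Ki = 0.1 uM, the side-effect/potency threshold
            (1.0e-6, -8.1798),  # Ki = 1 uM, the hERG threshold
            (1.0, 0.0),
        ],
    )
    def test_ki_to_ba(self, ki, expected):
        assert ki_to_ba(ki) == pytest.approx(expected, abs=5e-5)

    def test_threshold_values_at_two_decimals(self):
        assert round(ki_to_ba(1.0e-7), 2) == -9.54
        assert round(ki_to_ba(1.0e-6), 2) == -8.18

    @pytest.mark.parametrize("ic50, ki", [(2.0e-7, 1.0e-7), (2.0e-6, 1.0e-6)])
    def test_ic50_halved(self, ic50, ki):
        assert ic50_to_ki(ic50) == pytest.approx(ki)

    @pytest.mark.parametrize("bad", [0.0, -1e-9])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(DomainError):
            ic50_to_ki(bad)
        with pytest.raises(DomainError):
            ki_to_ba(bad)

    @given(st.floats(min_value=1e-12, max_value=1.0))
    @settings(deadline=None, max_examples=50)
    def test_ba_ki_round_trip(self, ki):
        assert ba_to_ki(ki_to_ba(ki)) == pytest.approx(ki, rel=1e-12)

    @given(st.floats(min_value=1e-12, max_value=1e-2), st.floats(min_value=1e-12, max_value=1e-2))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_ki(self, a, b):
        lo, hi = sorted((a, b))
        if lo < hi:
            assert ki_to_ba(lo) < ki_to_ba(hi)

    def test_composition_matches_closed_form(self):
        for x in (1e-9, 3e-7, 5e-5):
            assert ki_to_ba(ic50_to_ki(x)) == pytest.approx(1.3633 * math.log10(x / 2.0))


class TestParsing:
    HEADER = "compound_id,smiles,activity_type,activity_value,units,organism,target_id,single_protein\n"

    def write(self, tmp_path, rows):
        path = tmp_path / "table.csv"
        path.write_text(self.HEADER + "".join(rows))
        return path

    def test_unit_normalization(self, tmp_path):
        path = self.write(tmp_path, ["C1,CCO,IC50,200,nM,Homo sapiens,T1,true\n"])
        result = parse_activity_table(path)
        (rec,) = result.records
        assert rec.activity_value == pytest.approx(2.0e-7)
        assert rec.activity_type is ActivityType.IC50

    def test_negative_value_dropped_and_counted(self, tmp_path):
        path = self.write(tmp_path, ["C1,CCO,IC50,-5,nM,Homo sapiens,T1,true\n"])
        result = parse_activity_table(path)
        assert result.records == []
        assert result.dropped["nonpositive_value"] == 1

    def test_three_row_fixture_with_one_bad_cell(self, tmp_path):
        path = self.write(
            tmp_path,
            [
                "C1,CCO,Ki,100,nM,Homo sapiens,T1,true\n",
                "C2,,Ki,100,nM,Homo sapiens,T1,true\n",  # missing SMILES
                "C3,CCN,IC50,2,uM,Homo sapiens,T1,true\n",
            ],
        )
        result = parse_activity_table(path)
        assert len(result.records) == 2
        assert result.dropped["missing_smiles"] == 1

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("compound_id,smiles\nC1,CCO\n")
        with pytest.raises(ConfigurationError):
            parse_activity_table(path)

    def test_micro_sign_variants(self, tmp_path):
        path = self.write(
            tmp_path,
            ["C1,CCO,Ki,1,uM,Homo sapiens,T1,true\n", "C2,CCN,Ki,1,μM,Homo sapiens,T1,true\n"],
        )
        result = parse_activity_table(path)
        assert [r.activity_value for r in result.records] == pytest.approx([1e-6, 1e-6])


class TestStandardize:
    def test_geometric_mean_of_replicates(self):
        recs = [record(value=1e-7), record(cid="C2", value=1e-5)]
        (merged,) = standardize_records(recs)
        assert merged.activity_value == pytest.approx(1e-6)
        assert merged.activity_type is ActivityType.KI

    def test_single_record_unchanged_and_idempotent(self):
        recs = standardize_records([record()])
        assert len(recs) == 1
        assert standardize_records(recs) == recs

    def test_invalid_smiles_dropped(self):
        recs = standardize_records([record(smiles="C1CC")])  # unclosed ring
        assert recs == []

    def test_ic50_converted_before_aggregation(self):
        # IC50 2e-7 is Ki 1e-7; merged with a Ki 1e-7 replicate -> Ki 1e-7
        recs = [record(atype=ActivityType.IC50, value=2e-7), record(cid="C2", value=1e-7)]
        (merged,) = standardize_records(recs)
        assert merged.activity_value == pytest.approx(1e-7)

    def test_deterministic_order(self):
        recs = [record(cid="B", smiles="CCN"), record(cid="A", smiles="CCO")]
        out = standardize_records(recs)
        assert [r.smiles for r in out] == sorted(r.smiles for r in out)


class TestCuration:
    def many(self, n, **kw):
        # distinct linear alkanes: one unique molecule per record
        return [record(cid=f"C{i:04d}", smiles="C" * (i + 1), **kw) for i in range(n)]

    def test_accept_at_exact_minimum(self):
        out = curate_dataset(standardize_records(self.many(250)), CurationCriteria(min_size=250))
        assert isinstance(out, CuratedDataset)
        assert out.n == 250

    def test_reject_one_below_minimum(self):
        out = curate_dataset(standardize_records(self.many(249)), CurationCriteria(min_size=250))
        assert isinstance(out, CurationRejection)
        assert out.rule == "min_size"

    def test_organism_filter_then_size_rule(self):
        recs = self.many(20) + self.many(10, organism="Rattus norvegicus")
        # filters drop the 10 rat records, leaving 20 < 25
        out = curate_dataset(recs, CurationCriteria(min_size=25))
        assert isinstance(out, CurationRejection)
        assert out.rule == "min_size"

    def test_single_protein_flag_filter(self):
        recs = self.many(5) + self.many(5, single=False)
        out = curate_dataset(recs, CurationCriteria(min_size=1))
        assert out.n == 5

    def test_mixed_targets_rejected(self):
        with pytest.raises(UsageError):
            curate_dataset([record(target="T1"), record(cid="C2", target="T2")], CurationCriteria(min_size=1))

    def test_monotone_in_min_size(self):
        recs = standardize_records(self.many(40))
        accepted = curate_dataset(recs, CurationCriteria(min_size=len(recs)))
        assert isinstance(accepted, CuratedDataset)
        smaller = curate_dataset(recs, CurationCriteria(min_size=1))
        assert isinstance(smaller, CuratedDataset)
        assert smaller.n == accepted.n

    def test_ba_labels_match_formula(self):
        recs = [record(value=1e-7), record(cid="C2", smiles="CCN", value=1e-6)]
        out = curate_dataset(recs, CurationCriteria(min_size=1))
        assert sorted(out.ba.tolist()) == pytest.approx(sorted([ki_to_ba(1e-7), ki_to_ba(1e-6)]))

    def test_csv_round_trip(self, tmp_path):
        out = curate_dataset([record()], CurationCriteria(min_size=1))
        path = tmp_path / "curated.csv"
        out.to_csv(path)
        back = CuratedDataset.from_csv(path, "T1")
        assert back.compound_ids == out.compound_ids
        assert back.ba.tolist() == pytest.approx(out.ba.tolist())
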