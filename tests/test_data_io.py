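"""Dataset loading, duplicate resolution, alignment validation, numbering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nanotherm import data_io
from nanotherm.exceptions import (AlignmentError, ConfigError, DatasetError,
                                  FormatError)
from nanotherm.scales import AHO_LENGTH, GAP
from nanotherm.templates import GERMLINE_TEMPLATES

T1 = GERMLINE_TEMPLATES["t1"]
T2 = GERMLINE_TEMPLATES["t2"]


def _table(rows, path, dialect="csv"):
    df = pd.DataFrame(rows)
    if dialect == "xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, sep="\t" if dialect == "tsv" else ",", index=False)
    return path


def _rows(n=3):
    seqs = [T1.replace(GAP, ""), T2.replace(GAP, ""),
            GERMLINE_TEMPLATES["t3"].replace(GAP, "")]
    return [{"id": f"nb{i}", "sequence": seqs[i], "tm": 60.0 + i,
             "method": m, "source": "unit"}
            for i, m in enumerate(["nanoDSF", "CD ", "dsf"][:n])]


class TestReadThermoTable:
    @pytest.mark.parametrize("dialect", ["csv", "tsv", "xlsx"])
    def test_reads_and_normalizes_methods(self, tmp_path, dialect):
        path = _table(_rows(), tmp_path / f"t.{dialect}", dialect)
        ds = data_io.read_thermo_table(path)
        assert len(ds) == 3
        assert ds.methods == ["nanoDSF", "CD", "DSF"]
        assert ds.n_unknown_methods == 0

    def test_unknown_method_maps_to_other_with_count(self, tmp_path):
        rows = _rows()
        rows[0]["method"] = "thermofluor??"
        path = _table(rows, tmp_path / "t.csv")
        with pytest.warns(UserWarning, match="unrecognized"):
            ds = data_io.read_thermo_table(path)
        assert ds.methods[0] == "other"
        assert ds.n_unknown_methods == 1

    def test_missing_column_names_it(self, tmp_path):
        rows = [{k: v for k, v in r.items() if k != "tm"} for r in _rows()]
        path = _table(rows, tmp_path / "t.csv")
        with pytest.raises(FormatError, match="tm"):
            data_io.read_thermo_table(path)

    def test_empty_table_is_dataset_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("id,sequence,tm,method\n")
        with pytest.raises(DatasetError, match="empty"):
            data_io.read_thermo_table(path)

    def test_non_numeric_tm_reports_row(self, tmp_path):
        rows = _rows()
        rows[1]["tm"] = "hot"
        path = _table(rows, tmp_path / "t.csv")
        with pytest.raises(DatasetError, match="row 1"):
            data_io.read_thermo_table(path)

    def test_tm_outside_plausibility_band_rejected(self, tmp_path):
        rows = _rows()
        rows[0]["tm"] = 140.0
        path = _table(rows, tmp_path / "t.csv")
        with pytest.raises(DatasetError, match="plausibility"):
            data_io.read_thermo_table(path)

    def test_roundtrip_preserves_fields(self, tmp_path):
        path = _table(_rows(), tmp_path / "t.csv")
        ds = data_io.read_thermo_table(path)
        out = tmp_path / "out.tsv"
        data_io.write_thermo_table(ds, out)
        ds2 = data_io.read_thermo_table(out)
        assert ds2.ids == ds.ids
        assert ds2.sequences == ds.sequences
        assert ds2.methods == ds.methods
        assert np.allclose(ds2.tms, ds.tms, atol=0.01)


def _rec(i, seq, tm, method, source="s"):
    return data_io.ThermoRecord(id=f"r{i}", sequence=seq, tm=tm,
                                method=method, source=source)


class TestResolveDuplicates:
    def test_method_preference_retains_nanodsf(self):
        seq = T1.replace(GAP, "")
        ds = data_io.Dataset([_rec(0, seq, 65.0, "nanoDSF"),
                              _rec(1, seq, 63.0, "CD")])
        out, report = data_io.resolve_duplicates(ds)
        assert len(out) == 1
        assert out.records[0].tm == 65.0
        assert report.groups[0].pairwise_abs_diffs == [2.0]

    def test_no_duplicates_is_identity(self):
        ds = data_io.Dataset([_rec(0, T1.replace(GAP, ""), 60.0, "CD"),
                              _rec(1, T2.replace(GAP, ""), 70.0, "CD")])
        out, report = data_io.resolve_duplicates(ds)
        assert out.ids == ds.ids
        assert report.groups == []
        assert np.isnan(report.mean_pairwise_abs_diff)

    def test_mean_pairwise_diff_matches_bruteforce(self):
        seqs = [GERMLINE_TEMPLATES[t].replace(GAP, "")
                for t in ("t1", "t2", "t3", "t4", "t5")]
        tms = [60.0, 61.5, 70.0, 72.0, 68.0, 66.0, 80.0]
        # t1 appears twice, t2 three times
        ds = data_io.Dataset([
            _rec(0, seqs[0], tms[0], "CD"), _rec(1, seqs[0], tms[1], "DSF"),
            _rec(2, seqs[1], tms[2], "CD"), _rec(3, seqs[1], tms[3], "DSC"),
            _rec(4, seqs[1], tms[4], "CD"), _rec(5, seqs[2], tms[5], "CD"),
            _rec(6, seqs[3], tms[6], "CD"),
        ])
        _, report = data_io.resolve_duplicates(ds)
        # brute-force enumeration of within-group pairs
        expected = np.mean([abs(60.0 - 61.5),
                            abs(70.0 - 72.0), abs(70.0 - 68.0),
                            abs(72.0 - 68.0)])
        assert report.mean_pairwise_abs_diff == pytest.approx(expected)

    def test_empty_preference_is_config_error(self):
        ds = data_io.Dataset([_rec(0, T1.replace(GAP, ""), 60.0, "CD")])
        with pytest.raises(ConfigError):
            data_io.resolve_duplicates(ds, preference=[])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.sampled_from(data_io.METHODS),
                              st.floats(20, 100)),
                    min_size=1, max_size=6))
    def test_retained_tm_is_group_member_and_idempotent(self, group):
        seq = T1.replace(GAP, "")
        ds = data_io.Dataset([_rec(i, seq, round(tm, 2), m)
                              for i, (m, tm) in enumerate(group)])
        once, _ = data_io.resolve_duplicates(ds)
        assert len(once) == 1
        assert once.records[0].tm in [round(tm, 2) for _, tm in group]
        twice, rep2 = data_io.resolve_duplicates(once)
        assert twice.ids == once.ids and rep2.groups == []


class TestValidateAligned:
    def test_all_gaps_valid_with_149_gap_positions(self):
        gaps = data_io.validate_aligned(GAP * AHO_LENGTH)
        assert gaps == list(range(AHO_LENGTH))

    def test_wrong_length_reports_observed(self):
        with pytest.raises(AlignmentError, match="148"):
            data_io.validate_aligned(GAP * 148)

    def test_invalid_character_named_with_position(self):
        bad = T1[:10] + "X" + T1[11:]
        with pytest.raises(AlignmentError, match="'X' at position 10"):
            data_io.validate_aligned(bad)

    def test_template_gap_positions_match_annotation(self):
        gaps = data_io.validate_aligned(T1)
        assert gaps == [i for i, ch in enumerate(T1) if ch == GAP]


class TestNumberSequence:
    def test_already_aligned_passthrough(self):
        assert data_io.number_sequence(T1) == T1

    @pytest.mark.parametrize("name", list(GERMLINE_TEMPLATES))
    def test_degap_then_renumber_recovers_template(self, name):
        tmpl = GERMLINE_TEMPLATES[name]
        assert data_io.number_sequence(tmpl.replace(GAP, "")) == tmpl

    def test_random_non_antibody_sequence_fails(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=160))
        with pytest.raises(AlignmentError):
            data_io.number_sequence(seq)

    def test_low_identity_same_length_fails(self, rng):
        n = len(T1.replace(GAP, ""))
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
        with pytest.raises(AlignmentError):
            data_io.number_sequence(seq)

    def test_align_dataset_drops_unalignable_with_warning(self, rng):
        seq_ok = T1.replace(GAP, "")
        seq_bad = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=160))
        ds = data_io.Dataset([_rec(0, seq_ok, 60.0, "CD"),
                              _rec(1, seq_bad, 61.0, "CD")])
        with pytest.warns(UserWarning, match="unalignable"):
            out = data_io.align_dataset(ds)
        assert out.ids == ["r0"]
        assert out.records[0].aligned == T1
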