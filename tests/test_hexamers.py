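"""Hexamer taxonomy, oligo construction, ratios and the log-log correlation."""


import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pasbind.hexamers import (
    HexamerRecord,
    build_oligo,
    classify_variant,
    display_ratio,
    group_kd_ranges,
    hamming,
    load_reference_table,
    loglog_correlation,
    ratio_table,
    reference_records,
)
from pasbind.report import assemble_report

hexamer_st = st.text(alphabet="ACGU", min_size=6, max_size=6)


class TestHamming:
    @pytest.mark.parametrize("h1,h2,d", [
        ("AAUAAA", "AAUAAA", 0),
        ("AAUAAA", "AUUAAA", 1),
        ("AAUAAA", "AACAAG", 2),
    ])
    def test_examples(self, h1, h2, d):
        assert hamming(h1, h2) == d

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming("AAUAAA", "AAUAA")

    def test_rejects_dna_alphabet(self):
        with pytest.raises(ValueError):
            hamming("AATAAA", "AAUAAA")

    @given(a=hexamer_st, b=hexamer_st, c=hexamer_st)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_metric_axioms(self, a, b, c):
        assert hamming(a, b) == hamming(b, a)
        assert (hamming(a, b) == 0) == (a == b)
        assert hamming(a, c) <= hamming(a, b) + hamming(b, c)


class TestClassifyVariant:
    @pytest.mark.parametrize("hexamer,group", [
        ("AAUAAA", "canonical"),
        ("AUUAAA", "A1A2"),
        ("AGUAAA", "A1A2"),
        ("UAUAAA", "A1A2"),
        ("AACAAA", "U3A6"),
        ("AAUAAU", "U3A6"),
        ("AAUGAA", "A4A5"),
        ("AAUAUA", "A4A5"),
        ("AUUAUA", "AUUAAA_derived"),
        ("AUUACA", "AUUAAA_derived"),
        ("AACAAG", "other"),
        ("GGGGGG", "other"),
    ])
    def test_examples(self, hexamer, group):
        assert classify_variant(hexamer) == group

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            classify_variant("AATAAA")

    def test_reference_panel_partition(self):
        """The 18 panel hexamers: 1 canonical, 14 one-step variants of AAUAAA
        (6 A1A2 + 4 U3A6 + 4 A4A5), 2 AUUAAA-derived, 1 other."""
        recs = reference_records()
        groups = [r.group for r in recs]
        assert len(recs) == 18
        assert groups.count("canonical") == 1
        assert sum(r.dist_canonical == 1 for r in recs) == 14
        assert groups.count("A1A2") == 6
        assert groups.count("U3A6") == 4
        assert groups.count("A4A5") == 4
        assert groups.count("AUUAAA_derived") == 2
        assert groups.count("other") == 1
        assert [r.hexamer for r in recs if r.group == "other"] == ["AACAAG"]
        assert all(r.dist_secondary == 1 for r in recs if r.group == "AUUAAA_derived")


class TestBuildOligo:
    @pytest.mark.parametrize("hexamer,oligo", [
        ("AAUAAA", "UGCAAUAAACAA"),
        ("AACAAA", "UGCAACAAACAA"),
        ("AACAAG", "UGCAACAAGCAA"),
    ])
    def test_examples(self, hexamer, oligo):
        assert build_oligo(hexamer) == oligo

    def test_reference_sequences_follow_the_rule(self):
        df = load_reference_table()
        assert all(build_oligo(h) == s for h, s in zip(df["hexamer"], df["sequence"]))


class TestRatioTable:
    def test_reference_panel_reproduced_exactly(self):
        """Every published fold-change, including the FAM probe's 0.5, follows
        from the Kd column under half-to-even display rounding."""
        df = load_reference_table().dropna(subset=["kd_nM"])
        unlabeled = df[df["label"] != "FAM"]
        kd_map = dict(zip(unlabeled["hexamer"], unlabeled["kd_nM"]))
        ratios = ratio_table(kd_map, "AAUAAA")
        for _, row in unlabeled.iterrows():
            assert ratios[row["hexamer"]]["display"] == row["ratio_printed"], row["hexamer"]
        fam_kd = float(df[df["label"] == "FAM"]["kd_nM"].iloc[0])
        assert display_ratio(fam_kd / kd_map["AAUAAA"]) == 0.5

    def test_reference_is_unity(self):
        assert ratio_table({"AAUAAA": 40.0})["AAUAAA"]["display"] == 1

    def test_raw_kept_alongside_display(self):
        out = ratio_table({"AAUAAA": 40.0, "GAUAAA": 580.0})
        assert out["GAUAAA"]["raw"] == pytest.approx(14.5)
        assert out["GAUAAA"]["display"] == 14

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            ratio_table({"AUUAAA": 79.0})


class TestLogLogCorrelation:
    def test_exact_inverse_power_law(self):
        kd = np.geomspace(10, 1e4, 8)
        recs = [HexamerRecord("AAUAAA", frequency=float(100 / k), kd=float(k))
                for k in kd]
        res = loglog_correlation(recs)
        assert res.pearson_r_loglog == pytest.approx(-1.0)
        assert res.slope_loglog == pytest.approx(-1.0)
        assert res.outliers == ()

    def test_reference_panel_inverse_correlation(self):
        recs = [r for r in reference_records() if r.kd]
        res = loglog_correlation(recs)
        assert res.n == 16
        assert res.spearman_rho < 0
        assert res.pearson_r_loglog < 0

    def test_permutation_invariance(self):
        recs = [r for r in reference_records() if r.kd]
        res = loglog_correlation(recs)
        shuffled = list(recs)
        random.Random(1).shuffle(shuffled)
        assert loglog_correlation(shuffled) == res

    def test_too_few_records_rejected(self):
        recs = [HexamerRecord("AAUAAA", frequency=60.0, kd=40.0)] * 2
        with pytest.raises(ValueError):
            loglog_correlation(recs)

    def test_outlier_flagging(self):
        kd = np.geomspace(10, 1e4, 12)
        freq = 100 / kd
        freq[5] *= 40  # one point far off the power law
        recs = [HexamerRecord("AAUAAA", frequency=float(f), kd=float(k))
                for f, k in zip(freq, kd)]
        res = loglog_correlation(recs)
        assert len(res.outliers) >= 1


def test_group_kd_ranges_match_panel():
    """Per-group Kd extremes: A1A2 79-2700 nM, U3A6 1170-13000 nM,
    A4A5 1180-2500 nM."""
    ranges = group_kd_ranges(reference_records())
    assert ranges["A1A2"] == (79, 2700)
    assert ranges["U3A6"] == (1170, 13000)
    assert ranges["A4A5"] == (1180, 2500)


class TestAssembleReport:
    def test_rows_without_kd_kept_but_not_correlated(self):
        freq = {"AAUAAA": 60.0, "AUUAAA": 16.0, "AACAAA": 1.0, "AACAAG": 0.3}
        kds = {"AAUAAA": 40.0, "AUUAAA": 79.0, "AACAAA": 13000.0}
        frame, corr = assemble_report(freq, kds)
        assert len(frame) == 4
        assert np.isnan(frame.loc[frame.hexamer == "AACAAG", "kd_nM"].iloc[0])
        assert corr.n == 3

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            assemble_report({"AUUAAA": 16.0}, {"AUUAAA": 79.0})

    def test_ratio_column_matches_rule(self):
        freq = {"AAUAAA": 60.0, "GAUAAA": 1.23, "ACUAAA": 0.56}
        kds = {"AAUAAA": 40.0, "GAUAAA": 580.0, "ACUAAA": 2700.0}
        frame, _ = assemble_report(freq, kds)
        by_hex = frame.set_index("hexamer")
        assert by_hex.loc["GAUAAA", "ratio_display"] == 14
        assert by_hex.loc["ACUAAA", "ratio_display"] == 68
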