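"""Chromosome classification, asymmetry indices and karyotype formulas."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import karyohybrid as kh
from karyohybrid.errors import (
    FormulaError,
    InputError,
    InvalidMeasurementError,
    PairingError,
)
from karyohybrid.karyotype import TYPE_ORDER, arm_ratio

from conftest import make_records


class TestClassification:
    @pytest.mark.parametrize(
        "short,long,expected",
        [
            (0.0, 6.2, "T"),       # no short arm: telocentric point
            (3.0, 3.0, "M"),       # equal arms: median point
            (1.0, 5.0, "st"),      # ratio 5.00 inside 3.01-7.00
            (1.0, 7.0, "st"),      # upper st bound inclusive
            (1.0, 7.01, "t"),      # t strictly above 7.00
            (1.0, 1.70, "m"),      # upper m bound inclusive
            (1.0, 1.71, "sm"),     # open interval band
            (1.0, 3.0, "sm"),
            (5.0, 1.0, "st"),      # arms auto-swapped
            (2.0, 2.005, "M"),     # rounding tolerance at ratio 1
        ],
    )
    def test_arm_ratio_bands(self, short, long, expected):
        assert kh.classify_chromosome(short, long) == expected

    def test_both_arms_zero_is_invalid(self):
        with pytest.raises(InvalidMeasurementError):
            kh.classify_chromosome(0.0, 0.0)

    @given(
        s=st.floats(min_value=0.0, max_value=50.0),
        l=st.floats(min_value=0.01, max_value=50.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_classifier_is_total(self, s, l):
        assert kh.classify_chromosome(s, l) in TYPE_ORDER


class TestFormula:
    @pytest.mark.parametrize(
        "text,two_n,counts",
        [
            ("2n = 2x = 22 = 10t + 12st", 22, {"t": 10, "st": 12}),
            ("2n = 14 = 8 m + 6 T", 14, {"m": 8, "T": 6}),
            ("2n = 18 = 4 m + 6st + 5t + 3 T", 18, {"m": 4, "st": 6, "t": 5, "T": 3}),
            ("2n=18=3T+5t+6st+4m", 18, {"m": 4, "st": 6, "t": 5, "T": 3}),
        ],
    )
    def test_parse(self, text, two_n, counts):
        assert kh.parse_formula(text) == (two_n, counts)

    def test_format_canonical_order(self):
        assert kh.format_formula({"T": 6, "m": 8}, 14) == "2n = 14 = 8m + 6T"

    def test_sum_mismatch_rejected(self):
        with pytest.raises(FormulaError):
            kh.parse_formula("2n = 10 = 4m + 4t")
        with pytest.raises(FormulaError):
            kh.format_formula({"m": 4}, 10)

    @given(
        counts=st.dictionaries(
            st.sampled_from(TYPE_ORDER), st.integers(min_value=1, max_value=30),
            min_size=1, max_size=6,
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip(self, counts):
        two_n = sum(counts.values())
        text = kh.format_formula(counts, two_n)
        assert kh.parse_formula(text) == (two_n, counts)


class TestPairing:
    def test_forced_pairing(self):
        recs = make_records([(1.0, 1.2), (1.0, 1.2), (0.2, 2.0), (0.2, 2.0)])
        pairs = kh.pair_homologs(recs)
        assert [p.type_class for p in pairs] == ["m", "t"]

    def test_study_complement_pairs(self):
        arms = [(0.5, 4.5)] * 10 + [(1.0, 4.0)] * 12  # 10t + 12st
        pairs = kh.pair_homologs(make_records(arms))
        assert len(pairs) == 11
        assert sum(p.type_class == "t" for p in pairs) == 5
        assert sum(p.type_class == "st" for p in pairs) == 6

    def test_odd_count_raises_and_names_type(self):
        recs = make_records([(1.0, 1.2)] * 3)
        with pytest.raises(PairingError, match="'m'"):
            kh.pair_homologs(recs, strict=True)

    def test_lenient_mode_keeps_singleton(self):
        recs = make_records([(1.0, 1.2)] * 3)
        pairs = kh.pair_homologs(recs, strict=False)
        assert len(pairs) == 2
        assert {len(p.members) for p in pairs} == {1, 2}


class TestAsymmetry:
    def test_hand_computed_a1(self):
        # pairs (b,B) = (1,1) and (0,2): A1 = 1 - (1 + 0)/2
        recs = make_records([(1, 1), (1, 1), (0, 2), (0, 2)])
        a1, _ = kh.asymmetry_indices(kh.pair_homologs(recs))
        assert a1 == pytest.approx(0.5)

    def test_symmetric_complement_is_zero(self):
        recs = make_records([(2, 2)] * 4)
        a1, a2 = kh.asymmetry_indices(kh.pair_homologs(recs))
        assert a1 == 0.0 and a2 == 0.0

    def test_all_telocentric_reaches_one(self):
        recs = make_records([(0, 3), (0, 3), (0, 5), (0, 5)])
        a1, _ = kh.asymmetry_indices(kh.pair_homologs(recs))
        assert a1 == 1.0

    @given(
        arms=st.lists(
            st.tuples(
                st.floats(min_value=0.0, max_value=10.0),
                st.floats(min_value=0.5, max_value=10.0),
            ),
            min_size=2, max_size=12,
        ).filter(lambda a: len(a) % 2 == 0),
        scale=st.floats(min_value=0.1, max_value=20.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounds_and_scale_invariance(self, arms, scale):
        arms = [(min(s, l), max(s, l)) for s, l in arms]
        pairs = kh.pair_homologs(make_records(arms), strict=False)
        a1, a2 = kh.asymmetry_indices(pairs)
        assert 0.0 <= a1 <= 1.0
        assert a2 >= 0.0
        scaled = [(s * scale, l * scale) for s, l in arms]
        b1, b2 = kh.asymmetry_indices(kh.pair_homologs(make_records(scaled), strict=False))
        assert b1 == pytest.approx(a1, abs=1e-9)
        assert b2 == pytest.approx(a2, abs=1e-9)


class TestComplementStats:
    def _df(self, cells):
        rows = []
        for ci, arms in enumerate(cells):
            for i, (s, l) in enumerate(arms):
                rows.append({"taxon": "x", "cell": f"c{ci}", "chrom": i + 1,
                             "short_um": s, "long_um": l})
        return pd.DataFrame(rows)

    def test_single_cell(self):
        df = self._df([[(2, 2), (2, 2), (3, 3), (3, 3)]])
        tcl, ls, rel = kh.complement_stats(df)
        assert tcl == pytest.approx(10.0)
        assert ls == pytest.approx(1.5)
        assert sum(rel) == pytest.approx(200.0, abs=1e-6)  # diploid = 2 haploid sets

    def test_identical_chromosomes_give_ls_one(self):
        df = self._df([[(1, 2)] * 4])
        _, ls, _ = kh.complement_stats(df)
        assert ls == 1.0

    def test_tcl_mean_over_cells(self):
        df = self._df([[(2, 3), (2, 3), (2, 3), (2, 3)],
                       [(2.4, 3.6), (2.4, 3.6), (2.4, 3.6), (2.4, 3.6)]])
        tcl, _, _ = kh.complement_stats(df)
        assert tcl == pytest.approx(11.0)

    def test_inconsistent_two_n_rejected(self):
        df = self._df([[(1, 2)] * 4, [(1, 2)] * 6])
        with pytest.raises(InputError):
            kh.complement_stats(df)


class TestStebbins:
    def test_digit_boundaries(self):
        assert kh.stebbins_from_counts({"m": 4}, 1.5) == "1A"
        assert kh.stebbins_from_counts({"m": 2, "t": 2}, 1.5) == "2A"
        assert kh.stebbins_from_counts({"m": 1, "t": 3}, 1.5) == "3A"
        assert kh.stebbins_from_counts({"t": 4}, 1.5) == "4A"

    def test_letter_boundaries(self):
        assert kh.stebbins_from_counts({"t": 4}, 1.99) == "4A"
        assert kh.stebbins_from_counts({"t": 4}, 2.0) == "4B"
        assert kh.stebbins_from_counts({"t": 4}, 4.0) == "4B"
        assert kh.stebbins_from_counts({"t": 4}, 4.01) == "4C"

    def test_records_based_classification(self):
        recs = make_records([(1, 1), (1, 1), (0.5, 4.5), (0.5, 4.5)])
        assert kh.stebbins_class(recs, 2.5) == "2B"


class TestIO:
    def test_auto_swap_on_read(self, tmp_path, caplog):
        p = tmp_path / "m.tsv"
        p.write_text(
            "taxon\tcell\tchrom\tshort_um\tlong_um\n"
            "x\tc1\t1\t5.0\t1.0\n"
            "x\tc1\t2\t1.0\t5.0\n"
        )
        df = kh.read_measurements(p)
        assert (df["short_um"] <= df["long_um"]).all()

    def test_both_zero_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "taxon\tcell\tchrom\tshort_um\tlong_um\nx\tc1\t1\t0\t0\n"
        )
        with pytest.raises(InvalidMeasurementError):
            kh.read_measurements(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError):
            kh.read_measurements(tmp_path / "absent.tsv")


def test_summary_relative_lengths_and_formula():
    from karyohybrid.simulate import radiata_like, simulate_karyotype_measurements

    df = simulate_karyotype_measurements(radiata_like(0, noise_cv=0.0))
    s = kh.summarize_karyotype(df)
    assert s.formula == "2n = 22 = 12st + 10t"
    assert s.two_n == 22
    assert sum(r.relative_length for r in s.records) == pytest.approx(200.0, abs=1e-6)
    assert s.stebbins == "4A"
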