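"""Per-peak rank testing, fold changes, incidences and overlaps."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as hst

from peptidiff import count_significant, mann_whitney, overlap_significant, peak_statistics
from peptidiff.errors import ConfigurationError
from peptidiff.stats import ComparisonResult

from conftest import make_matrix


def enumeration_pvalue(a, b):
    """Independent oracle: exact two-sided p by enumerating all label assignments.

    Counts the fraction of the C(n, |a|) partitions of the pooled data
    whose U statistic is at least as far from its null centre as observed.
    """
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)
    centre = na * len(b) / 2.0

    def ustat(group_a, group_b):
        return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in group_a for y in group_b)

    observed = abs(ustat(a, b) - centre)
    idx = range(len(pooled))
    count = total = 0
    for comb in itertools.combinations(idx, na):
        in_a = set(comb)
        ga = [pooled[i] for i in idx if i in in_a]
        gb = [pooled[i] for i in idx if i not in in_a]
        total += 1
        if abs(ustat(ga, gb) - centre) >= observed - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_groups_give_most_extreme_exact_p(self):
        # only 2 of the C(6,3)=20 assignments are this extreme
        assert mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert mann_whitney(a, list(a)) == pytest.approx(1.0)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(size=5)
        assert mann_whitney(a, b) == pytest.approx(mann_whitney(b, a), abs=1e-14)

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigurationError):
            mann_whitney([], [1.0])

    def test_no_variation_at_all_gives_p_one(self):
        assert mann_whitney([2.0] * 6, [2.0] * 7) == 1.0

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            na = int(rng.integers(1, 11))
            nb = int(rng.integers(1, 12 - na + 1)) if na < 11 else 1
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            assert mann_whitney(a, b) == pytest.approx(
                enumeration_pvalue(a, b), abs=1e-10
            )

    @pytest.mark.parametrize(
        "n_detected_a, n_a, n_detected_b, n_b, expected_p",
        [
            # Detection patterns of three published CSF peptide peaks whose
            # p-values are fully determined by presence/absence alone
            # (absences rank as zeros, detected values all higher).
            (0, 10, 6, 11, 0.0092),   # vitamin D-binding protein peptide
            (7, 10, 0, 11, 0.0014),   # beta-2-microglobulin peptide
            (6, 10, 0, 11, 0.0041),   # serine/threonine kinase NLK peptide
        ],
    )
    def test_detection_pattern_pvalues_match_published_values(
        self, n_detected_a, n_a, n_detected_b, n_b, expected_p
    ):
        a = [0.0] * (n_a - n_detected_a) + [10.0 + i for i in range(n_detected_a)]
        b = [0.0] * (n_b - n_detected_b) + [20.0 + i for i in range(n_detected_b)]
        assert round(mann_whitney(a, b), 4) == expected_p

    @given(
        a=hst.lists(hst.floats(-1e3, 1e3), min_size=2, max_size=10),
        b=hst.lists(hst.floats(-1e3, 1e3), min_size=2, max_size=10),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_p_in_unit_interval_and_monotone_invariant(self, a, b):
        p = mann_whitney(a, b)
        assert 0.0 <= p <= 1.0
        # strictly monotone transform preserves ranks, hence p
        f = lambda x: math.atan(x / 10.0) * 7.0 + 2.0
        # guard against float collisions that would change the tie structure
        assume(len({f(x) for x in a + b}) == len(set(a + b)))
        assert mann_whitney([f(x) for x in a], [f(x) for x in b]) == pytest.approx(
            p, abs=1e-12
        )


class TestPeakStatistics:
    def _pattern_matrix(self):
        # peak 0: detected 3/10 PP and 7/11 RR; peak 1: 0/10 PP, 6/11 RR
        cols = {}
        groups = {}
        for i in range(10):
            sid = f"PP_{i:02d}"
            groups[sid] = "PP"
            cols[sid] = [100.0 + i if i < 3 else np.nan, np.nan]
        for i in range(11):
            sid = f"RR_{i:02d}"
            groups[sid] = "RR"
            cols[sid] = [
                50.0 + i if i < 7 else np.nan,
                30.0 + i if i < 6 else np.nan,
            ]
        return make_matrix(cols, groups)

    def test_incidences_integer_percent_rounded(self):
        res = peak_statistics(self._pattern_matrix(), "PP", "RR")
        row0 = res.table.iloc[0]
        assert (row0["incidence_a"], row0["incidence_b"]) == (30, 64)  # 3/10, 7/11
        row1 = res.table.iloc[1]
        assert (row1["incidence_a"], row1["incidence_b"]) == (0, 55)  # 0/10, 6/11

    def test_incidence_truncation_option(self):
        res = peak_statistics(
            self._pattern_matrix(), "PP", "RR", incidence_rounding="truncate"
        )
        assert res.table.iloc[0]["incidence_b"] == 63  # 7/11 = 63.6 -> 63
        assert res.table.iloc[1]["incidence_b"] == 54

    def test_group_with_no_detections_gives_defined_p_undefined_fold(self):
        res = peak_statistics(self._pattern_matrix(), "PP", "RR")
        row1 = res.table.iloc[1]
        assert np.isnan(row1["fold_change"])
        assert row1["direction"] == "down-in-A"
        assert round(row1["p_value"], 4) == 0.0092

    def test_identical_vectors_give_p_one_fold_one_undefined_direction(self):
        cols = {f"A_{i}": [5.0 + i] for i in range(4)}
        cols.update({f"B_{i}": [5.0 + i] for i in range(4)})
        groups = {s: s[0] for s in cols}
        res = peak_statistics(make_matrix(cols, groups), "A", "B")
        row = res.table.iloc[0]
        assert row["p_value"] == pytest.approx(1.0)
        assert row["fold_change"] == pytest.approx(1.0)
        assert row["direction"] == "undefined"

    @pytest.mark.parametrize("scale", [0.01, 1.0, 3e4])
    def test_scale_equivariance_of_p_and_fold(self, scale):
        rng = np.random.default_rng(5)
        cols = {f"A_{i}": rng.lognormal(3, 1, 6).tolist() for i in range(5)}
        cols.update({f"B_{i}": rng.lognormal(3.5, 1, 6).tolist() for i in range(6)})
        groups = {s: s[0] for s in cols}
        base = peak_statistics(make_matrix(cols, groups), "A", "B")
        scaled_cols = {s: [v * scale for v in vals] for s, vals in cols.items()}
        scaled = peak_statistics(make_matrix(scaled_cols, groups), "A", "B")
        np.testing.assert_allclose(scaled.p_values, base.p_values, rtol=1e-12)
        np.testing.assert_allclose(
            scaled.table["fold_change"], base.table["fold_change"], rtol=1e-9
        )

    def test_detected_only_policy_undefined_p_when_one_side_empty(self):
        res = peak_statistics(
            self._pattern_matrix(), "PP", "RR", missing_policy="detected-only"
        )
        assert np.isnan(res.table.iloc[1]["p_value"])

    def test_unknown_group_rejected(self):
        with pytest.raises(ConfigurationError):
            peak_statistics(self._pattern_matrix(), "PP", "XX")


def _result(pvals, mzs=None, alpha=0.01):
    n = len(pvals)
    table = pd.DataFrame(
        {
            "mz": mzs if mzs is not None else 1000.0 + 10.0 * np.arange(n),
            "p_value": pvals,
            "fold_change": np.ones(n),
            "direction": ["undefined"] * n,
            "incidence_a": [100] * n,
            "incidence_b": [100] * n,
        }
    )
    return ComparisonResult("t", "A", "B", alpha, table)


class TestCountsAndOverlap:
    def test_count_uses_strict_inequality_at_alpha(self):
        assert count_significant(_result([0.009, 0.01, 0.011])) == 1

    def test_all_null_pvalues_count_zero(self):
        assert count_significant(_result([0.5] * 5)) == 0

    def test_overlap_identity_and_disjoint(self):
        r1 = _result([0.001, 0.5, 0.002, 0.9])
        assert overlap_significant(r1, r1) == 2
        r2 = _result([0.5, 0.001, 0.9, 0.002])
        assert overlap_significant(r1, r2) == 0

    def test_overlap_by_mz_when_matrices_differ(self):
        r1 = _result([0.001, 0.5], mzs=[1000.0, 1100.0])
        r2 = _result([0.002, 0.5, 0.003], mzs=[1000.000004, 1200.0, 1300.0])
        assert overlap_significant(r1, r2, mz_tol_ppm=5.0) == 1
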