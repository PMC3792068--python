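"""Differential screening, AUROC, ratio-marker selection, and bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycoserum.cohort import CohortConfig, null_cohort
from glycoserum.stats import (
    NoMarkerError,
    auroc,
    bootstrap_group_means,
    per_glycan_differential,
    select_ratio_marker,
    strata_compare,
    student_t_test,
)


def brute_force_auroc(cases, controls):
    """Independent oracle: direct pairwise counting, ties worth one half."""
    wins = sum((c > k) + 0.5 * (c == k) for c in cases for k in controls)
    return wins / (len(cases) * len(controls))


class TestStudentT:
    def test_identical_samples(self):
        t, p = student_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1

    def test_closed_form_example(self):
        t, p = student_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_swap_negates_t_keeps_p(self, rng):
        x, y = rng.normal(size=8), rng.normal(1, 1, size=6)
        t1, p1 = student_t_test(x, y)
        t2, p2 = student_t_test(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            student_t_test([1.0, 1.0], [1.0, 1.0])

    def test_group_of_one_raises(self):
        with pytest.raises(ValueError):
            student_t_test([1.0], [1.0, 2.0])


class TestAuroc:
    def test_pairwise_example(self):
        vals = [2, 3, 4, 1, 1.5, 2.5]
        labels = ["case"] * 3 + ["ctrl"] * 3
        assert auroc(vals, labels, "case") == pytest.approx(8 / 9)

    def test_all_identical_is_half(self):
        assert auroc([5.0] * 6, ["a"] * 3 + ["b"] * 3, "a") == 0.5

    def test_perfect_separation_is_one(self):
        assert auroc([10, 11, 1, 2], ["a", "a", "b", "b"], "a") == 1.0

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            auroc([1, 2], ["a", "a"], "a")

    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=50),
        st.lists(st.integers(0, 20), min_size=1, max_size=50),
    )
    def test_matches_brute_force_oracle(self, cases, controls):
        vals = list(cases) + list(controls)
        labels = ["case"] * len(cases) + ["ctrl"] * len(controls)
        assert auroc(vals, labels, "case") == pytest.approx(
            brute_force_auroc(cases, controls), abs=1e-12
        )

    def test_complement_under_negation(self, rng):
        vals = rng.normal(size=30)  # continuous, tie-free
        labels = np.array(["a"] * 12 + ["b"] * 18)
        assert auroc(vals, labels, "a") + auroc(-vals, labels, "a") == pytest.approx(1.0)


def toy_screen(n=10, shift_up=50.0, shift_down=50.0):
    """Tiny cohort with one perfectly separated up and one down glycan."""
    rng = np.random.default_rng(3)
    idx = [f"u{i}" for i in range(n)] + [f"h{i}" for i in range(n)]
    groups = pd.Series(["UC"] * n + ["HLT"] * n, index=idx)
    m = pd.DataFrame(
        {
            "up": np.r_[rng.normal(10 + shift_up, 1, n), rng.normal(10, 1, n)],
            "down": np.r_[rng.normal(10, 1, n), rng.normal(10 + shift_down, 1, n)],
            "flat": rng.normal(10, 1, 2 * n),
        },
        index=idx,
    )
    return m, groups


class TestPerGlycanDifferential:
    def test_bonferroni_threshold_is_alpha_over_g(self, panel, default_cohort):
        abundance, metadata = default_cohort
        res = per_glycan_differential(abundance, metadata["group"].astype(str), panel=panel)
        assert res.attrs["threshold"] == pytest.approx(0.05 / 61)
        assert len(res) == 61

    def test_planted_shift_detected_with_direction(self):
        m, groups = toy_screen()
        res = per_glycan_differential(m, groups)
        assert res.loc["up", "significant"] and res.loc["up", "direction"] == "up"
        assert res.loc["down", "significant"] and res.loc["down", "direction"] == "down"
        assert not res.loc["flat", "significant"]

    def test_missing_group_labels_raise(self):
        m, groups = toy_screen()
        with pytest.raises(ValueError, match="without group labels"):
            per_glycan_differential(m, groups.drop("u0"))


class TestSelectRatioMarker:
    def test_perfectly_separated_pair(self):
        m, groups = toy_screen()
        res = per_glycan_differential(m, groups)
        marker = select_ratio_marker(res, m, groups)
        assert (marker.numerator, marker.denominator) == ("up", "down")
        assert marker.auroc == 1.0

    def test_invariant_to_scaling_a_column(self):
        m, groups = toy_screen()
        res = per_glycan_differential(m, groups)
        m2 = m.assign(down=m["down"] * 2.0)
        res2 = per_glycan_differential(m2, groups)
        a = select_ratio_marker(res, m, groups)
        b = select_ratio_marker(res2, m2, groups)
        assert (a.numerator, a.denominator) == (b.numerator, b.denominator)
        assert a.auroc == pytest.approx(b.auroc, abs=1e-12)

    def test_default_cohort_selects_planted_pair(self, panel, default_cohort):
        abundance, metadata = default_cohort
        groups = metadata["group"].astype(str)
        res = per_glycan_differential(abundance, groups, panel=panel)
        marker = select_ratio_marker(res, abundance, groups, panel)
        assert (marker.numerator, marker.denominator) == ("5402", "5410")
        assert (marker.numerator_label, marker.denominator_label) == (2378, 1914)

    def test_null_cohort_raises_no_marker(self, panel):
        abundance, metadata = null_cohort(CohortConfig(seed=5))
        groups = metadata["group"].astype(str)
        res = per_glycan_differential(abundance, groups, panel=panel)
        with pytest.raises(NoMarkerError):
            select_ratio_marker(res, abundance, groups, panel)

    def test_nonpositive_denominator_samples_are_excluded(self):
        m, groups = toy_screen()
        m.loc["u0", "down"] = 0.0
        res = per_glycan_differential(m.drop(index="u0"), groups.drop("u0"))
        marker = select_ratio_marker(res, m, groups)
        assert "u0" not in marker.values.index


class TestBootstrap:
    def test_constant_groups_exact_estimate_and_p_one(self):
        vals = [3.0] * 5 + [3.0] * 4
        groups = ["a"] * 5 + ["b"] * 4
        out = bootstrap_group_means(vals, groups, B=200, seed=0)
        assert out["point_estimates"] == {"a": 3.0, "b": 3.0}
        assert out["p"] == 1.0

    def test_reproducible_bit_for_bit(self, rng):
        vals = rng.normal(size=30)
        groups = ["a"] * 15 + ["b"] * 15
        o1 = bootstrap_group_means(vals, groups, B=500, seed=11)
        o2 = bootstrap_group_means(vals, groups, B=500, seed=11)
        assert o1 == o2

    def test_point_estimate_close_to_plain_mean(self, rng):
        vals = rng.normal(5, 2, size=40)
        groups = ["a"] * 20 + ["b"] * 20
        out = bootstrap_group_means(vals, groups, B=2000, seed=2)
        for g in ("a", "b"):
            se = out["bootstrap_se"][g]
            assert abs(out["point_estimates"][g] - out["observed_means"][g]) < 2 * se

    def test_separated_groups_attain_minimal_p(self):
        vals = list(range(10)) + list(range(100, 110))
        groups = ["a"] * 10 + ["b"] * 10
        B = 999
        out = bootstrap_group_means(vals, groups, B=B, seed=1)
        assert out["p"] == pytest.approx(2 / (B + 1))

    def test_small_b_rejected(self):
        with pytest.raises(ValueError, match="B must be"):
            bootstrap_group_means([1, 2, 3, 4], ["a", "a", "b", "b"], B=10)


class TestStrataCompare:
    def test_identical_distributions_large_p(self, rng):
        vals = pd.Series(np.tile(rng.normal(size=30), 2))
        stratum = pd.Series([True] * 30 + [False] * 30)
        out = strata_compare(vals, stratum, B=500, seed=0)
        assert out["p"] > 0.9
        assert out["means"]["True"] == pytest.approx(out["means"]["False"])

    def test_missing_stratum_levels_are_excluded(self, rng):
        vals = pd.Series(rng.normal(size=10))
        stratum = pd.Series([True] * 4 + [False] * 4 + [pd.NA, pd.NA], dtype="boolean")
        out = strata_compare(vals, stratum, B=200, seed=0)
        assert out["n"] == {"False": 4, "True": 4}

    def test_empty_stratum_raises(self, rng):
        vals = pd.Series(rng.normal(size=6))
        stratum = pd.Series([True] * 6)
        with pytest.raises(ValueError, match="2 levels"):
            strata_compare(vals, stratum, B=200, seed=0)

    def test_default_cohort_marker_higher_in_severe_strata(self, panel, default_cohort):
        abundance, metadata = default_cohort
        uc = metadata[metadata["group"] == "UC"]
        ratio = abundance.loc[uc.index, "5402"] / abundance.loc[uc.index, "5410"]
        out = strata_compare(ratio, (uc["cai"] > 10).astype("boolean"), B=500, seed=3)
        assert out["means"]["True"] > out["means"]["False"]
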