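"""Normalization, fold-change and permutation-screen behaviour."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from reciprome.errors import ConfigurationError, NormalizationError
from reciprome.nanostring import (
    compare_groups,
    fold_change,
    normalize_counts,
    permutation_test,
    screen,
)

from conftest import make_count_matrix


class TestNormalize:
    def test_identical_positive_controls_give_identity_scaling(self):
        m = make_count_matrix(
            endo={"a": [10, 20], "b": [5, 7]},
            pos={"P1": [100, 100], "P2": [400, 400]},
        )
        norm = normalize_counts(m)
        assert np.allclose(norm.scale_factors, 1.0)
        assert np.allclose(norm.values.loc["a"], [10, 20])

    def test_hand_computed_two_sample_toy(self):
        # sample B's positive-control geometric mean is 4x sample A's:
        # scale factors are gm/sqrt(gmA*gmB) = (0.5, 2), so B is halved
        # relative to raw twice over and A doubled
        m = make_count_matrix(
            endo={"a": [10, 40], "b": [6, 6], "c": [0, 8]},
            pos={"P1": [100, 400], "P2": [400, 1600]},
        )
        norm = normalize_counts(m)
        assert np.allclose(norm.scale_factors, [0.5, 2.0])
        assert np.allclose(norm.values.loc["a"], [20.0, 20.0])
        assert np.allclose(norm.values.loc["b"], [12.0, 3.0])

    def test_scale_factors_have_unit_geometric_mean(self, rng):
        counts = rng.integers(1, 2000, size=(8, 6))
        m = make_count_matrix(
            endo={f"e{i}": list(counts[i]) for i in range(6)},
            pos={f"P{i}": list(counts[6 + i]) for i in range(2)},
        )
        norm = normalize_counts(m)
        assert math.isclose(np.exp(np.mean(np.log(norm.scale_factors))), 1.0)

    def test_all_zero_positive_controls_name_the_sample(self):
        m = make_count_matrix(endo={"a": [1, 1]}, pos={"P1": [10, 0], "P2": [10, 0]})
        with pytest.raises(NormalizationError, match="S2"):
            normalize_counts(m)

    def test_no_positive_controls_rejected(self):
        m = make_count_matrix(endo={"a": [1, 1]}, pos={})
        with pytest.raises(ConfigurationError):
            normalize_counts(m)

    def test_zero_negative_controls_detect_all_nonzero(self):
        m = make_count_matrix(
            endo={"a": [3, 3], "z": [0, 0]},
            pos={"P1": [10, 10]},
            neg={"N1": [0, 0], "N2": [0, 0]},
        )
        norm = normalize_counts(m)
        assert np.allclose(norm.background, 0.0)
        assert bool(norm.detected["a"]) and not bool(norm.detected["z"])

    def test_normalization_preserves_within_sample_rank_order(self, rng):
        counts = rng.integers(0, 5000, size=(30, 5))
        m = make_count_matrix(
            endo={f"e{i:02d}": list(counts[i]) for i in range(28)},
            pos={"P1": list(rng.integers(100, 900, 5)), "P2": list(rng.integers(100, 900, 5))},
        )
        norm = normalize_counts(m)
        for s in m.samples:
            raw_rank = m.counts.loc[norm.values.index, s].rank()
            assert (norm.values[s].rank() == raw_rank).all()


class TestFoldChange:
    def _norm(self, a_vals, b_vals):
        n = len(a_vals[0])
        m = make_count_matrix(
            endo={f"f{i}": av + bv for i, (av, bv) in enumerate(zip(a_vals, b_vals))},
            pos={"P1": [100] * 2 * n},
            groups={f"S{i + 1}": ("A" if i < n else "B") for i in range(2 * n)},
        )
        return normalize_counts(m)

    def test_equal_group_means_give_unit_fold(self):
        norm = self._norm([[5, 7]], [[7, 5]])
        fc = fold_change(norm, "A", "B", pseudocount=0.5)
        assert fc["f0"] == pytest.approx(1.0)

    def test_boundary_three_fold_is_not_more_than_three_fold(self):
        # means 12 vs 4 with pseudocount 0 -> ratio exactly 3, which the
        # strict "more than 3-fold" screen must exclude
        norm = self._norm([[12, 12]], [[4, 4]])
        fc = fold_change(norm, "A", "B", pseudocount=0.0)
        assert fc["f0"] == pytest.approx(3.0)
        df = pd.DataFrame(
            {"fold_change": fc, "log2_fc": np.log2(fc), "p_perm": 1.0}
        )
        assert screen(df, 3.0).empty
        assert not screen(df, 2.9).empty

    def test_unknown_group_rejected(self):
        norm = self._norm([[1, 1]], [[1, 1]])
        with pytest.raises(ConfigurationError):
            fold_change(norm, "A", "nope")


def _brute_force_perm_p(x: np.ndarray, n_a: int) -> float:
    """Independent exhaustive two-sided permutation p for one feature."""
    n = x.size
    obs = x[:n_a].mean() - x[n_a:].mean()
    count, total = 0, 0
    for idx in combinations(range(n), n_a):
        a = x[list(idx)]
        b = np.delete(x, list(idx))
        stat = a.mean() - b.mean()
        total += 1
        if abs(stat) >= abs(obs) - 1e-12:
            count += 1
    return count / total


class TestPermutation:
    def _norm_two_groups(self, data: np.ndarray, n_a: int):
        n = data.shape[1]
        m = make_count_matrix(
            endo={f"f{i}": list(data[i]) for i in range(data.shape[0])},
            pos={"P1": [100] * n},
            groups={f"S{j + 1}": ("A" if j < n_a else "B") for j in range(n)},
        )
        return normalize_counts(m)

    def test_constant_features_get_p_one(self):
        norm = self._norm_two_groups(np.full((3, 6), 7), 3)
        p = permutation_test(norm, "A", "B", n_perm=1000)
        assert (p == 1.0).all()

    def test_exact_path_matches_brute_force_enumeration(self, rng):
        data = rng.integers(1, 500, size=(6, 6))
        norm = self._norm_two_groups(data, 3)
        p = permutation_test(norm, "A", "B", n_perm=10_000, pseudocount=0.5)
        x = np.log2(norm.values.to_numpy() + 0.5)
        for i, probe in enumerate(norm.values.index):
            assert p[probe] == pytest.approx(_brute_force_perm_p(x[i], 3))

    def test_maximally_extreme_split_has_enumerated_tail_mass(self):
        # 3 vs 3 with all A values above all B values: only the observed
        # split and its mirror reach |obs|, so p = 2/20
        data = np.array([[800, 900, 1000, 10, 11, 12]])
        norm = self._norm_two_groups(data, 3)
        p = permutation_test(norm, "A", "B", n_perm=10_000)
        assert p.iloc[0] == pytest.approx(2 / 20)

    def test_monte_carlo_agrees_with_exact_on_small_design(self, rng):
        data = rng.integers(1, 500, size=(10, 8))
        norm = self._norm_two_groups(data, 4)
        exact = permutation_test(norm, "A", "B", n_perm=10_000)  # C(8,4)=70
        mc = permutation_test(norm, "A", "B", n_perm=60, seed=7)
        # MC estimate within 3 binomial SEs of the exact p (plus add-one shift)
        for probe in exact.index:
            se = math.sqrt(exact[probe] * (1 - exact[probe]) / 60) + 1 / 61
            assert abs(mc[probe] - exact[probe]) <= 3 * se + 1e-9

    def test_null_pvalues_super_uniform(self, rng):
        # 500 null features, 4 vs 4, exact enumeration (70 assignments)
        data = rng.poisson(200, size=(500, 8))
        norm = self._norm_two_groups(data, 4)
        p = permutation_test(norm, "A", "B", n_perm=10_000)
        for alpha in (0.05, 0.2):
            se = math.sqrt(alpha * (1 - alpha) / 500)
            assert (p < alpha).mean() <= alpha + 3 * se

    def test_p_floor_is_inverse_of_assignment_count(self):
        data = np.array([[1000, 900, 800, 1, 2, 3]])
        norm = self._norm_two_groups(data, 3)
        p = permutation_test(norm, "A", "B", n_perm=10_000)
        assert p.iloc[0] >= 1 / 20

    def test_bad_inputs_rejected(self):
        data = np.ones((2, 6), dtype=int)
        norm = self._norm_two_groups(data, 3)
        with pytest.raises(ConfigurationError):
            permutation_test(norm, "A", "B", n_perm=0)


class TestScreen:
    def _results(self, folds: dict[str, float]) -> pd.DataFrame:
        fc = pd.Series(folds)
        return pd.DataFrame(
            {"fold_change": fc, "log2_fc": np.log2(fc), "p_perm": 0.5}
        )

    def test_two_sided_and_sorted_by_magnitude(self):
        res = self._results({"up4": 4.0, "dn4": 0.25, "flat": 1.1, "up8": 8.0})
        hits = screen(res, 3.0)
        assert list(hits.index) == ["up8", "dn4", "up4"]

    def test_stricter_cutoff_is_subset(self, rng):
        folds = {f"f{i}": float(2.0 ** rng.normal(0, 1.5)) for i in range(100)}
        res = self._results(folds)
        assert set(screen(res, 3.0).index) <= set(screen(res, 1.5).index)

    def test_infinite_cutoff_empty(self):
        res = self._results({"a": 1000.0})
        assert screen(res, math.inf).empty

    def test_tie_break_lexicographic(self):
        res = self._results({"zz": 4.0, "aa": 4.0, "mm": 0.25})
        assert list(screen(res, 3.0).index) == ["aa", "mm", "zz"]

    def test_p_cutoff_filters(self):
        res = self._results({"a": 4.0, "b": 5.0})
        res.loc["a", "p_perm"] = 0.001
        assert list(screen(res, 3.0, p_cutoff=0.003).index) == ["a"]


def test_compare_groups_flags_consistent(rng):
    data = rng.integers(1, 2000, size=(20, 6))
    n = data.shape[1]
    m = make_count_matrix(
        endo={f"f{i}": list(data[i]) for i in range(20)},
        pos={"P1": [100] * n},
        groups={f"S{j + 1}": ("A" if j < 3 else "B") for j in range(n)},
    )
    df = compare_groups(normalize_counts(m), "A", "B", n_perm=100)
    assert (df.loc[df["passes_3x"], "passes_1_5x"]).all()
    assert (df["fold_change"] > 0).all()
    assert ((df["p_perm"] > 0) & (df["p_perm"] <= 1)).all()
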