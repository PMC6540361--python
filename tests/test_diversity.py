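"""Alpha indices, Bray-Curtis partition, Koleff incidence measures and
community-matrix standardizations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import braycurtis as scipy_bray

from cytodiv import (
    alpha_indices,
    bray_curtis,
    bray_partition,
    distance_matrix,
    koleff_index,
    transform_counts,
    KOLEFF_IDS,
)
from cytodiv.errors import ConfigError, NumericError


class TestAlpha:
    def test_uniform_four_bins_closed_form(self):
        a = alpha_indices(np.array([25.0, 25, 25, 25]))
        assert a["richness"] == 4
        assert a["shannon"] == pytest.approx(math.log(4), abs=1e-12)
        assert a["simpson"] == pytest.approx(0.75)
        assert a["inv_simpson"] == pytest.approx(4.0)
        assert a["pielou"] == pytest.approx(1.0)

    def test_single_bin_degenerate(self):
        a = alpha_indices(np.array([100.0]))
        assert a["richness"] == 1 and a["shannon"] == 0.0
        assert math.isnan(a["pielou"])

    def test_two_even_bins(self):
        a = alpha_indices(np.array([50.0, 50.0]))
        assert a["simpson"] == pytest.approx(0.5)
        assert a["inv_simpson"] == pytest.approx(2.0)

    def test_all_zero_names_sample(self):
        with pytest.raises(NumericError, match="lake3"):
            alpha_indices(np.zeros(5), sample_id="lake3")

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 2**32 - 1), st.floats(1e-3, 1e3))
    def test_scale_invariance(self, seed, c):
        x = np.random.default_rng(seed).integers(0, 20, 30).astype(float)
        if x.sum() == 0:
            x[0] = 1
        a, b = alpha_indices(x), alpha_indices(c * x)
        for k in a:
            assert a[k] == pytest.approx(b[k], nan_ok=True)

    def test_shannon_bounded_by_log_richness(self):
        x = np.random.default_rng(8).random(40)
        a = alpha_indices(x)
        assert a["shannon"] <= math.log(a["richness"]) + 1e-12


class TestBray:
    def test_identity_disjoint_arithmetic(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([1, 0], [0, 1]) == 1.0
        assert bray_curtis([2, 2], [1, 1]) == pytest.approx(1 / 3)

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x, y = rng.integers(0, 40, 15), rng.integers(0, 40, 15)
            if (x + y).sum() == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(scipy_bray(x, y))

    def test_length_mismatch(self):
        with pytest.raises(ConfigError):
            bray_curtis([1, 2], [1, 2, 3])

    def test_partition_nested_pair(self):
        p = bray_partition([2.0, 2.0], [1.0, 1.0])
        assert p.bray == pytest.approx(1 / 3)
        assert p.balanced == 0.0
        assert p.gradient == pytest.approx(1 / 3)

    def test_partition_pure_turnover(self):
        p = bray_partition([1.0, 0.0], [0.0, 1.0])
        assert (p.bray, p.balanced, p.gradient) == (1.0, 1.0, 0.0)

    def test_partition_identity_vector(self):
        p = bray_partition([3.0, 1.0], [3.0, 1.0])
        assert (p.bray, p.balanced, p.gradient) == (0.0, 0.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 40))
    def test_partition_sums_to_bray(self, seed, n):
        """Baselga's decomposition is exact: balanced + gradient = bray."""
        rng = np.random.default_rng(seed)
        x = rng.gamma(0.5, 10, n).round(3)
        y = rng.gamma(0.5, 10, n).round(3)
        if x.sum() == 0 and y.sum() == 0:
            x[0] = 1.0
        p = bray_partition(x, y)
        assert abs(p.balanced + p.gradient - p.bray) < 1e-12
        assert 0 <= p.balanced <= p.bray <= 1
        assert p.bray == pytest.approx(bray_curtis(x, y))


# Independent oracle: matching components from explicit set operations,
# formulas re-typed from the published pairwise table.
def _koleff_oracle(x, y, index_id):
    sx = {i for i, v in enumerate(x) if v > 0}
    sy = {i for i, v in enumerate(y) if v > 0}
    a, b, c = len(sx & sy), len(sx - sy), len(sy - sx)
    ln = math.log
    try:
        return {
            "w": (b + c) / (2 * a + b + c),
            "-1": (b + c) / (2 * a + b + c),
            "c": (b + c) / 2,
            "wb": b + c,
            "r": 2 * b * c / ((a + b + c) ** 2 - 2 * b * c),
            "I": ln(2 * a + b + c) - 2 * a * ln(2) / (2 * a + b + c)
                 - ((a + b) * ln(a + b) + (a + c) * ln(a + c)) / (2 * a + b + c),
            "e": math.exp(
                ln(2 * a + b + c) - 2 * a * ln(2) / (2 * a + b + c)
                - ((a + b) * ln(a + b) + (a + c) * ln(a + c)) / (2 * a + b + c)
            ) - 1,
            "t": (b + c) / (2 * a + b + c),
            "me": (b + c) / (2 * a + b + c),
            "j": a / (a + b + c),
            "sor": 2 * a / (2 * a + b + c),
            "m": (2 * a + b + c) * (b + c) / (a + b + c),
            "-2": min(b, c) / (max(b, c) + a),
            "co": (a * c + a * b + 2 * b * c) / (2 * (a + b) * (a + c)),
            "cc": (b + c) / (a + b + c),
            "g": (b + c) / (a + b + c),
            "-3": min(b, c) / (a + b + c),
            "l": (b + c) / 2,
            "19": 2 * (b * c + 1) / ((a + b + c) * (a + b + c - 1)),
            "hk": (b + c) / (2 * a + b + c),
            "rlb": a / (a + c),
            "sim": min(b, c) / (min(b, c) + a),
            "gl": 2 * abs(b - c) / (2 * a + b + c),
            "z": (ln(2) - ln(2 * a + b + c) + ln(a + b + c)) / ln(2),
        }[index_id]
    except (ZeroDivisionError, ValueError):
        return float("nan")


class TestKoleff:
    def test_sorensen_hand_example(self):
        # a=2 shared, b=1 only-x, c=1 only-y -> (b+c)/(2a+b+c) = 1/3
        x = np.array([1, 1, 1, 0.0])
        y = np.array([1, 1, 0, 1.0])
        assert koleff_index(x, y, "w") == pytest.approx(1 / 3)
        assert koleff_index(x, y, "sor") == pytest.approx(2 / 3)  # similarity form

    def test_whittaker_identity_is_minimum(self):
        x = np.array([3, 0, 2.0])
        assert koleff_index(x, x, "w") == 0.0

    def test_disjoint_complement_is_maximal(self):
        assert koleff_index([1, 0], [0, 1], "cc") == 1.0

    def test_unknown_id_lists_valid(self):
        with pytest.raises(ConfigError, match="sor"):
            koleff_index([1], [1], "nope")

    def test_all_24_against_set_oracle(self):
        rng = np.random.default_rng(10)
        checked = 0
        for _ in range(200):
            x = (rng.random(25) < 0.4).astype(float)
            y = (rng.random(25) < 0.4).astype(float)
            for idx in KOLEFF_IDS:
                got = koleff_index(x, y, idx)
                want = _koleff_oracle(x, y, idx)
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12), idx
            checked += 1
        assert checked == 200 and len(KOLEFF_IDS) == 24


class TestDistanceMatrix:
    def test_identical_columns_zero_matrix(self):
        F = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 3))
        mats = distance_matrix(F, ["a", "b", "c"])
        np.testing.assert_allclose(mats["bray"].values, 0)

    def test_pair_delegation(self):
        F = np.array([[2.0, 1.0], [2.0, 1.0]])
        mats = distance_matrix(F, ["a", "b"])
        assert mats["bray"].values[0, 1] == pytest.approx(1 / 3)
        assert mats["gradient"].values[0, 1] == pytest.approx(1 / 3)

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(11)
        F = rng.integers(0, 30, (10, 4)).astype(float)
        F[0] += 1  # no all-zero columns
        mats = distance_matrix(F, list("abcd"))
        for i in range(4):
            for j in range(4):
                want = 0.0 if i == j else bray_curtis(F[:, i], F[:, j])
                assert mats["bray"].values[i, j] == pytest.approx(want)
        np.testing.assert_allclose(
            mats["balanced"].values + mats["gradient"].values,
            mats["bray"].values, atol=1e-12,
        )

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(12)
        F = rng.integers(1, 30, (8, 5)).astype(float)
        perm = [3, 0, 4, 1, 2]
        base = distance_matrix(F, list("abcde"))["bray"].values
        permuted = distance_matrix(F[:, perm],
                                   [list("abcde")[p] for p in perm])["bray"].values
        np.testing.assert_allclose(permuted, base[np.ix_(perm, perm)])

    def test_koleff_matrix_route(self):
        F = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        m = distance_matrix(F, ["a", "b"], index="w")["w"]
        assert m.values[0, 1] == pytest.approx(0.5)


class TestTransforms:
    def test_total(self):
        out = transform_counts(np.array([[2.0], [2.0], [4.0]]), "total")
        np.testing.assert_allclose(out[:, 0], [0.25, 0.25, 0.5])

    def test_pa(self):
        out = transform_counts(np.array([[0.0], [3.0], [0.5]]), "pa")
        np.testing.assert_array_equal(out[:, 0], [0, 1, 1])

    def test_hellinger(self):
        out = transform_counts(np.array([[1.0], [4.0]]), "hellinger")
        np.testing.assert_allclose(out[:, 0], [np.sqrt(0.2), np.sqrt(0.8)])

    def test_unknown_method(self):
        with pytest.raises(ConfigError):
            transform_counts(np.ones((2, 2)), "bogus")
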