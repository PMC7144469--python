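"""Ranking strategies against an explicit brute-force reference, and
precision-at-top-k against a set-intersection oracle."""

import math
import warnings

import numpy as np
import pytest

from uqscreen.ranking import (
    STRATEGIES,
    RankingConfig,
    RankingInput,
    normalize,
    precision_at_top,
    rank,
    strategy_comparison,
)


# ---------------------------------------------------------------------------
# independent reference: plain-python formulas + stable sort
def brute_force_order(y, u, strategy, lam=None, mode="minmax_range"):
    def norm(v):
        lo, hi = min(v), max(v)
        if mode == "minmax_range":
            return [0.0] * len(v) if hi == lo else [(x - lo) / (hi - lo) for x in v]
        if hi == 0 or hi == lo:
            return [0.0] * len(v)
        return [(x - lo) / hi for x in v]

    if strategy == "baseline":
        R = list(y)
    elif strategy == "add":
        R = [a + b for a, b in zip(y, u)]
    elif strategy == "scale":
        R = [a * b for a, b in zip(norm(u), y)]
    elif strategy == "add_scaled":
        R = [a + b for a, b in zip(norm(u), y)]
    elif strategy == "sum_scaled":
        R = [a + b for a, b in zip(norm(u), norm(y))]
    elif strategy == "comb":
        R = [lam * a + (1 - lam) * b for a, b in zip(y, u)]
    else:
        raise ValueError(strategy)
    return sorted(range(len(R)), key=lambda i: (R[i], str(i), i)), R


def make_input(y, u, ids=None, y_true=None):
    ids = ids or [str(i) for i in range(len(y))]
    return RankingInput(ids, np.asarray(y, float), np.asarray(u, float), y_true)


class TestNormalize:
    def test_minmax_range(self):
        np.testing.assert_allclose(normalize([2, 4, 6], "minmax_range"), [0, 0.5, 1])

    def test_minmax_over_max_as_printed(self):
        np.testing.assert_allclose(
            normalize([2, 4, 6], "minmax_over_max"), [0, 1 / 3, 2 / 3]
        )

    def test_constant_vector_maps_to_zeros(self):
        for mode in ("minmax_range", "minmax_over_max"):
            np.testing.assert_array_equal(normalize([5, 5, 5], mode), [0, 0, 0])

    def test_over_max_with_zero_max_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="max == 0"):
            out = normalize([-2.0, -1.0, 0.0], "minmax_over_max")
        np.testing.assert_array_equal(out, [0, 0, 0])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            normalize([], "minmax_range")


class TestRankArithmetic:
    def test_add_strategy_values(self):
        res = rank(make_input([1, 2], [0.5, 0.1]), RankingConfig(strategy="add"))
        np.testing.assert_allclose(res.R, [1.5, 2.1])
        assert list(res.order) == [0, 1]

    def test_comb_half_lambda_values(self):
        res = rank(
            make_input([1, 2], [0.5, 0.1]), RankingConfig(strategy="comb", lam=0.5)
        )
        np.testing.assert_allclose(res.R, [0.75, 1.05])
        assert list(res.order) == [0, 1]

    def test_comb_lambda_one_reproduces_baseline(self, rng):
        y = rng.standard_normal(30)
        u = rng.uniform(0, 1, 30)
        base = rank(make_input(y, u), RankingConfig(strategy="baseline"))
        comb = rank(make_input(y, u), RankingConfig(strategy="comb", lam=1.0))
        np.testing.assert_array_equal(base.order, comb.order)

    def test_comb_lambda_zero_orders_by_uncertainty(self, rng):
        y = rng.standard_normal(30)
        u = rng.uniform(0, 1, 30)
        comb = rank(make_input(y, u), RankingConfig(strategy="comb", lam=0.0))
        assert list(comb.order) == list(np.argsort(u, kind="stable"))

    def test_zero_uncertainty_neutral_for_additive_strategies(self):
        y, u = [3.0, 1.0, 2.0], [0.0, 0.0, 0.0]
        base = rank(make_input(y, u), RankingConfig(strategy="baseline"))
        assert list(base.order) == [1, 2, 0]
        for s in ("add", "add_scaled"):
            res = rank(make_input(y, u), RankingConfig(strategy=s))
            np.testing.assert_array_equal(res.order, base.order)

    def test_scale_with_negative_predictions_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            rank(make_input([-1.0, 2.0], [0.1, 0.9]), RankingConfig(strategy="scale"))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RankingConfig(strategy="comb")  # missing lambda
        with pytest.raises(ValueError):
            RankingConfig(strategy="add", lam=0.5)
        with pytest.raises(ValueError):
            RankingConfig(strategy="nope")


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("strategy", STRATEGIES)
    @pytest.mark.parametrize("mode", ["minmax_range", "minmax_over_max"])
    def test_order_matches_reference(self, strategy, mode, rng):
        for trial in range(100):
            n = int(rng.integers(2, 51))
            y = np.round(rng.standard_normal(n) * 2 + 1.5, 6)
            u = np.round(rng.uniform(0, 1, n), 6)
            lam = float(rng.uniform(0, 1)) if strategy == "comb" else None
            ref_order, ref_R = brute_force_order(list(y), list(u), strategy, lam, mode)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = rank(
                    make_input(y, u),
                    RankingConfig(strategy=strategy, lam=lam, normalization=mode),
                )
            np.testing.assert_allclose(res.R, ref_R, rtol=1e-10, atol=1e-12)

    def test_shift_invariance_of_minmax_range_strategies(self, rng):
        """Adding a positive constant to all u leaves scaled-strategy orders
        unchanged under minmax_range normalization."""
        y = rng.standard_normal(40) + 2
        u = rng.uniform(0, 1, 40)
        for s in ("scale", "add_scaled", "sum_scaled"):
            cfg = RankingConfig(strategy=s, normalization="minmax_range")
            o1 = rank(make_input(y, u), cfg).order
            o2 = rank(make_input(y, u + 3.7), cfg).order
            np.testing.assert_array_equal(o1, o2)


class TestPrecisionAtTop:
    def test_perfect_prediction_gives_one(self, rng):
        y = rng.standard_normal(50)
        assert precision_at_top(y, y, 0.1) == 1.0

    def test_reversed_distinct_gives_zero(self):
        y = np.arange(20, dtype=float)
        assert precision_at_top(y, -y, 0.1) == 0.0

    def test_half_overlap(self):
        # n=20, m=2: true top-2 = {0,1}; predicted top-2 = {1,19}
        y = np.arange(20, dtype=float)
        R = y.copy()
        R[19] = -10.0  # pulls 19 into predicted top-2, displacing 0
        assert precision_at_top(y, R, 0.1) == 0.5

    def test_brute_force_set_intersection_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 60))
            frac = float(rng.choice([0.1, 0.2, 0.5]))
            y = rng.standard_normal(n)
            R = rng.standard_normal(n)
            m = math.ceil(frac * n)
            ids = [str(i) for i in range(n)]
            top_true = set(sorted(range(n), key=lambda i: (y[i], ids[i]))[:m])
            top_pred = set(sorted(range(n), key=lambda i: (R[i], ids[i]))[:m])
            expected = len(top_true & top_pred) / m
            assert precision_at_top(y, R, frac) == pytest.approx(expected)

    def test_invariant_to_monotone_transform_of_R(self, rng):
        y = rng.standard_normal(40)
        R = rng.standard_normal(40)
        p1 = precision_at_top(y, R, 0.1)
        p2 = precision_at_top(y, np.exp(R * 2) + 5, 0.1)
        assert p1 == p2

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            precision_at_top(np.array([]), np.array([]), 0.1)


class TestStrategyComparison:
    def test_all_strategies_and_lambda_grid_present(self, rng):
        y_true = rng.standard_normal(50)
        inp = make_input(
            y_true + rng.normal(0, 0.2, 50), rng.uniform(0, 0.5, 50), y_true=y_true
        )
        out = strategy_comparison(inp)
        assert {"baseline", "add", "scale", "add_scaled", "sum_scaled"} <= set(out)
        assert sum(k.startswith("comb_lam=") for k in out) == 11
        assert all(0.0 <= v <= 1.0 for v in out.values())

    def test_requires_truth(self, rng):
        inp = make_input(rng.standard_normal(10), rng.uniform(0, 1, 10))
        with pytest.raises(ValueError, match="true"):
            strategy_comparison(inp)
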