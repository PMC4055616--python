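import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from phytogrowth.errors import (
    BootstrapInstabilityError,
    DegenerateDataError,
    ValidationError,
)
from phytogrowth.stats import (
    bin_by_chl,
    bootstrap_rma_ci,
    mann_whitney,
    ols_fit,
    pearson_test,
    rma_fit,
)


class TestRMAFit:
    def test_exact_collinearity(self):
        fit = rma_fit([1, 2, 3], [2, 4, 6])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        fit = rma_fit([0, 1, 2], [0, 1, 3])
        assert fit.slope == pytest.approx(1.52753, abs=1e-4)
        assert fit.intercept == pytest.approx(-0.19425, abs=1e-4)
        assert fit.pearson_r == pytest.approx(0.98198, abs=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_geometric_mean_identity_and_duality(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        y = 0.7 * x + rng.normal(scale=0.5, size=40)
        fit = rma_fit(x, y)
        b_yx = ols_fit(x, y).slope
        b_xy = ols_fit(y, x).slope
        assert abs(fit.slope) == pytest.approx(math.sqrt(abs(b_yx / b_xy)), rel=1e-9)
        assert abs(fit.slope * rma_fit(y, x).slope) == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("a,c", [(2.0, 3.0), (0.5, 10.0)])
    def test_affine_equivariance(self, a, c):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.3, size=30)
        base = rma_fit(x, y).slope
        assert rma_fit(a * x + 1.0, c * y - 2.0).slope == pytest.approx(
            (c / a) * base, rel=1e-9
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            rma_fit([1, 1, 1], [1, 2, 3])


class TestBootstrapRMA:
    def test_collinear_data_degenerate_interval(self):
        fit = bootstrap_rma_ci([1, 2, 3, 4], [2, 4, 6, 8], n_boot=200, seed=0)
        assert fit.slope_ci == (2.0, 2.0)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.4, size=30)
        a = bootstrap_rma_ci(x, y, n_boot=500, seed=42)
        b = bootstrap_rma_ci(x, y, n_boot=500, seed=42)
        assert a == b

    def test_interval_brackets_estimate(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        y = 1.4 * x + rng.normal(scale=0.6, size=60)
        fit = bootstrap_rma_ci(x, y, n_boot=1000, seed=1)
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]
        assert fit.intercept_ci[0] <= fit.intercept <= fit.intercept_ci[1]

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=400)
        y = x + rng.normal(scale=0.5, size=400)
        w_small = np.diff(bootstrap_rma_ci(x[:50], y[:50], n_boot=800, seed=2).slope_ci)
        w_big = np.diff(bootstrap_rma_ci(x, y, n_boot=800, seed=2).slope_ci)
        # n grows 8x; sqrt-n scaling predicts ~2.8x narrower
        assert w_big < w_small / 1.8

    def test_overly_discrete_data_raise_instability(self):
        with pytest.raises(BootstrapInstabilityError):
            bootstrap_rma_ci([1.0, 1.0, 2.0], [1.0, 1.0, 2.0], n_boot=500, seed=0)

    def test_bca_variant_runs_and_brackets(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=40)
        y = 2.0 * x + rng.normal(scale=0.5, size=40)
        fit = bootstrap_rma_ci(x, y, n_boot=300, seed=3, method="bca")
        assert fit.slope_ci[0] < fit.slope < fit.slope_ci[1]


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p, n = pearson_test(x, x)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_hand_computed_example(self):
        r, p, n = pearson_test([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert p == pytest.approx(0.2, abs=0.005)

    def test_null_distribution_rarely_large(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            r, _, _ = pearson_test(rng.normal(size=72), rng.normal(size=72))
            hits += abs(r) < 0.25
        assert hits >= 38  # |r| < 0.25 in >= 95% of independent draws

    def test_degenerate_error(self):
        with pytest.raises(DegenerateDataError):
            pearson_test([1, 1, 1], [1, 2, 3])


class TestOLS:
    def test_hand_computed_example(self):
        fit = ols_fit([0, 1, 2], [0, 1, 3])
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(-1.0 / 6.0, abs=1e-12)

    def test_collinear_p_near_zero(self):
        fit = ols_fit([0, 1, 2, 3], [1, 3, 5, 7])
        assert fit.slope == pytest.approx(2.0)
        assert fit.p_slope < 1e-10

    def test_null_slope_p_roughly_uniform(self):
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            ps.append(ols_fit(rng.normal(size=30), rng.normal(size=30)).p_slope)
        ps = np.asarray(ps)
        assert 0.25 < ps.mean() < 0.75
        assert (ps < 0.05).mean() < 0.2


def exact_mann_whitney_oracle(a, b):
    """Full enumeration of rank arrangements (midranks for ties)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    ranks = rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = []
    for idx in itertools.combinations(range(n), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        us.append(u)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.method == "exact"

    def test_identical_groups(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.u_statistic == pytest.approx(4.5)  # n^2 / 2
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("na,nb", list(itertools.product([2, 3, 4, 5], repeat=2)))
    def test_matches_enumeration_oracle_without_ties(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(3):
            pooled = rng.permutation(np.arange(1.0, na + nb + 1.0))
            a, b = pooled[:na], pooled[na:]
            u_ref, p_ref = exact_mann_whitney_oracle(a, b)
            res = mann_whitney(a, b)
            assert res.u_statistic == pytest.approx(u_ref)
            assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_u_statistic_matches_oracle_with_ties(self):
        a, b = [1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 3.0]
        u_ref, _ = exact_mann_whitney_oracle(a, b)
        res = mann_whitney(a, b)
        assert res.u_statistic == pytest.approx(u_ref)
        assert res.method == "asymptotic"

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_p_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=6)
        b = rng.normal(loc=0.5, size=5)
        base = mann_whitney(a, b)
        trans = mann_whitney(np.exp(a), np.exp(b))
        assert trans.p_value == pytest.approx(base.p_value, rel=1e-12)
        assert trans.u_statistic == base.u_statistic

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([1.0], [2.0, 3.0])


class TestChlBinning:
    @staticmethod
    def _frame(chl):
        return pd.DataFrame(
            {
                "station_id": [f"s{i}" for i in range(len(chl))],
                "chl_mg_m3": chl,
                "p_c": np.linspace(0.1, 2.0, len(chl)),
            }
        )

    def test_boundary_is_right_open(self):
        out = bin_by_chl(self._frame([0.2]))
        row = out[out["n"] > 0].iloc[0]
        assert row["bin"] == "0.2-0.5"

    def test_one_station_per_bin(self):
        out = bin_by_chl(self._frame([0.1, 0.3, 1.0, 3.0, 7.0]))
        assert list(out["n"]) == [1, 1, 1, 1, 1]

    def test_mean_and_sd(self):
        df = self._frame([0.6, 0.7, 1.9])
        out = bin_by_chl(df)
        row = out[out["bin"] == "0.5-2"].iloc[0]
        assert row["n"] == 3
        assert row["mean_p_c"] == pytest.approx(df["p_c"].mean())
        assert row["sd_p_c"] == pytest.approx(df["p_c"].std(ddof=1))

    def test_nonpositive_chl_rejected(self):
        with pytest.raises(ValidationError):
            bin_by_chl(self._frame([0.0, 1.0]))
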