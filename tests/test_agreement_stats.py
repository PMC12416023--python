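import numpy as np
import pytest
from scipy import stats as sstats

from armkin.agreement_stats import (
    AnovaResult,
    DifferenceSet,
    anova_oneway,
    bland_altman,
    compare_methods,
    compare_planes,
    simulate_difference_set,
    variance_partition,
)
from armkin.errors import ParameterError


def brute_force_partition(groups: dict, nbar_mode="mean"):
    """Independent sums-of-squares oracle: direct double loops, no vectorised
    shortcuts shared with the implementation."""
    all_vals = [v for g in groups.values() for v in g]
    N = len(all_vals)
    k = len(groups)
    grand = sum(all_vals) / N
    ss_b = 0.0
    ss_w = 0.0
    sum_ni_sq = 0.0
    for g in groups.values():
        m = sum(g) / len(g)
        ss_b += len(g) * (m - grand) ** 2
        sum_ni_sq += len(g) ** 2
        for v in g:
            ss_w += (v - m) ** 2
    ms_p = ss_b / (k - 1)
    ms_r = ss_w / (N - k)
    nbar = N / k if nbar_mode == "mean" else (N - sum_ni_sq / N) / (k - 1)
    var_b = max(0.0, (ms_p - ms_r) / nbar)
    return {
        "ms_participant": ms_p,
        "ms_residual": ms_r,
        "var_between": var_b,
        "var_total": var_b + ms_r,
        "sd": np.sqrt(var_b + ms_r),
        "grand": grand,
    }


def random_fixture(rng):
    k = int(rng.integers(2, 13))
    return {
        f"P{i}": rng.normal(rng.normal(0, 3), 4, size=int(rng.integers(2, 31)))
        for i in range(k)
    }


class TestVariancePartition:
    def test_zero_variance(self):
        ds = DifferenceSet(data={"a": [3.0, 3.0, 3.0], "b": [3.0, 3.0]})
        vp = variance_partition(ds)
        assert vp["ms_participant"] == vp["ms_residual"] == 0.0
        assert vp["sd"] == 0.0

    def test_hand_computed_fixture(self):
        data = {
            "p1": [1.0, 2.0, 3.0, 4.0],
            "p2": [2.5, 3.5, 4.5, 5.5],
            "p3": [-1.0, 0.0, 1.0, 2.0],
        }
        ds = DifferenceSet(data=data)
        vp = variance_partition(ds)
        oracle = brute_force_partition(data)
        for key in ("ms_participant", "ms_residual", "var_between", "var_total", "sd"):
            assert abs(vp[key] - oracle[key]) < 1e-10

    def test_oracle_agreement_100_random_unbalanced(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            data = random_fixture(rng)
            ds = DifferenceSet(data=data)
            for mode in ("mean", "anova_n0"):
                vp = variance_partition(ds, nbar_mode=mode)
                oracle = brute_force_partition(data, nbar_mode=mode)
                for key in ("ms_participant", "ms_residual", "var_between", "var_total", "sd"):
                    assert abs(vp[key] - oracle[key]) < 1e-10

    def test_identical_means_sd_converges_to_within_sd(self):
        rng = np.random.default_rng(8)
        sigma = 2.5
        data = {f"p{i}": rng.normal(0.0, sigma, 200) for i in range(12)}
        vp = variance_partition(DifferenceSet(data=data))
        assert abs(vp["sd"] - sigma) / sigma < 0.05

    def test_single_observation_participant_rejected(self):
        with pytest.raises(ParameterError):
            DifferenceSet(data={"a": [1.0], "b": [1.0, 2.0]})


class TestBlandAltman:
    def test_constant_differences(self):
        ds = DifferenceSet(data={"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        res = bland_altman(ds)
        assert res.bias == 5.0
        assert res.loa_lower == res.loa_upper == 5.0
        assert res.rmse == 0.0

    def test_matches_oracle_on_fixture(self):
        rng = np.random.default_rng(5)
        data = random_fixture(rng)
        res = bland_altman(DifferenceSet(data=data))
        oracle = brute_force_partition(data)
        assert abs(res.bias - oracle["grand"]) < 1e-10
        assert abs(res.loa_lower - (oracle["grand"] - 1.96 * oracle["sd"])) < 1e-10
        assert abs(res.loa_upper - (oracle["grand"] + 1.96 * oracle["sd"])) < 1e-10
        assert abs(res.rmse - np.sqrt(oracle["ms_residual"])) < 1e-10
        assert res.loa_lower <= res.bias <= res.loa_upper
        assert np.isclose(res.var_total, res.var_between + res.ms_residual)

    def test_parameter_recovery_and_coverage(self):
        rng = np.random.default_rng(1234)
        ds = simulate_difference_set(
            bias=2.0, sd_between=3.0, sd_within=4.0,
            n_participants=12, n_obs=500, rng=rng,
        )
        res = bland_altman(ds)
        assert abs(res.bias - 2.0) / 2.0 < 0.05
        assert abs(np.sqrt(res.var_between) - 3.0) / 3.0 < 0.05
        assert abs(res.rmse - 4.0) / 4.0 < 0.05
        assert abs(res.sd - 5.0) / 5.0 < 0.05  # sqrt(9 + 16)
        pooled = ds.pooled()
        cover = np.mean((pooled >= res.loa_lower) & (pooled <= res.loa_upper))
        assert 0.94 <= cover <= 0.96

    @pytest.mark.parametrize("c", [2.0, -3.0, 0.5])
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(6)
        data = random_fixture(rng)
        base = bland_altman(DifferenceSet(data=data))
        scaled = bland_altman(
            DifferenceSet(data={k: c * np.asarray(v) for k, v in data.items()})
        )
        assert np.isclose(scaled.bias, c * base.bias)
        assert np.isclose(scaled.sd, abs(c) * base.sd)
        assert np.isclose(scaled.rmse, abs(c) * base.rmse)
        lo, hi = sorted([c * base.loa_lower, c * base.loa_upper])
        if c < 0:
            lo, hi = c * base.loa_upper, c * base.loa_lower
        assert np.isclose(scaled.loa_lower, lo)
        assert np.isclose(scaled.loa_upper, hi)


class TestAnovaOneway:
    def test_identical_groups(self):
        res = anova_oneway({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.f_statistic == 0.0
        assert res.partial_eta_squared == 0.0
        assert res.cohens_f == 0.0

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(3, 40)))
            b = rng.normal(0.5, 1.3, int(rng.integers(3, 40)))
            res = anova_oneway({"a": a, "b": b})
            t, p = sstats.ttest_ind(a, b, equal_var=True)
            assert abs(res.f_statistic - t**2) < 1e-10
            assert abs(res.p_value - p) < 1e-10

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(12)
        groups = {f"g{i}": rng.normal(i * 0.3, 1.0, 15 + i) for i in range(4)}
        res = anova_oneway(groups)
        f, p = sstats.f_oneway(*groups.values())
        assert abs(res.f_statistic - f) < 1e-8
        assert abs(res.p_value - p) < 1e-8

    def test_effect_size_identity(self):
        rng = np.random.default_rng(13)
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(1, 1, 30)}
        res = anova_oneway(groups)
        assert np.isclose(
            res.cohens_f,
            np.sqrt(res.partial_eta_squared / (1 - res.partial_eta_squared)),
        )

    def test_f_scale_invariance(self):
        rng = np.random.default_rng(14)
        groups = {"a": rng.normal(0, 1, 20), "b": rng.normal(0.7, 1, 25)}
        res1 = anova_oneway(groups)
        res2 = anova_oneway({k: 3.5 * v for k, v in groups.items()})
        assert np.isclose(res1.f_statistic, res2.f_statistic)
        assert np.isclose(res1.partial_eta_squared, res2.partial_eta_squared)

    def test_degenerate_groups(self):
        with pytest.raises(ParameterError):
            anova_oneway({"a": [1.0]})


def _fake_results(rmse_cf, rmse_ik, plane="frontal"):
    from armkin.agreement_stats import AgreementResult

    out = []
    for method, vals in (("CF", rmse_cf), ("IK", rmse_ik)):
        for i, r in enumerate(vals):
            out.append(
                AgreementResult(
                    bias=0, ms_participant=0, ms_residual=r**2, var_between=0,
                    var_total=r**2, sd=r, loa_lower=-r, loa_upper=r, rmse=r,
                    n_participants=12, n_obs=100,
                    labels={"method": method, "placement": plane, "movement": f"m{i}"},
                )
            )
    return out


class TestComparisons:
    def test_identical_rmses_f_zero(self):
        vals = np.linspace(2, 8, 40)
        res = compare_methods(_fake_results(vals, vals), "frontal")
        assert res.f_statistic == 0.0

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(15)
        cf = rng.uniform(5, 15, 40)
        ik = cf - 2.0
        res = compare_methods(_fake_results(cf, ik), "frontal")
        assert res.f_statistic > 0
        assert res.p_value < 0.05

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ParameterError):
            compare_methods(
                _fake_results(np.ones(40) + np.arange(40), np.ones(39)), "frontal"
            )

    def test_compare_planes_shift(self):
        rng = np.random.default_rng(16)
        res_f = _fake_results(rng.uniform(5, 15, 40), rng.uniform(5, 15, 40), "frontal")
        res_s = _fake_results(
            rng.uniform(3, 13, 40), rng.uniform(3, 13, 40), "sagittal"
        )
        res = compare_planes(res_f + res_s, "CF")
        assert isinstance(res, AnovaResult)
        assert res.df_group == 1
        assert res.df_error == 78
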