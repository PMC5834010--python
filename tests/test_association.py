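"""Logistic, Kruskal-Wallis and Cox analyses: oracles and invariances."""
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import tilquant as tq
from tilquant.association import (LogisticResults, build_design, _Z95)
from tilquant.errors import ContractViolation, FitError


def _two_by_two(a, b, c, d):
    """a = exposed events, b = unexposed events, c = exposed non-events,
    d = unexposed non-events."""
    x = [1] * (a + c) + [0] * (b + d)
    y = [1] * a + [0] * c + [1] * b + [0] * d
    return pd.DataFrame({"exposed": np.array(x, float), "pcr": np.array(y, float)})


class TestLogistic:
    def test_single_binary_covariate_equals_cross_product_ratio(self):
        data = _two_by_two(a=10, b=20, c=5, d=40)
        fit = tq.fit_logistic(data, "pcr", ("exposed",))
        assert fit.converged
        assert fit.odds_ratios[0] == pytest.approx(4.0, rel=1e-6)

    def test_reversed_coding_inverts_odds_ratio(self):
        data = _two_by_two(a=10, b=20, c=5, d=40)
        flipped = data.assign(exposed=1 - data["exposed"])
        a = tq.fit_logistic(data, "pcr", ("exposed",))
        b = tq.fit_logistic(flipped, "pcr", ("exposed",))
        assert a.odds_ratios[0] == pytest.approx(1 / b.odds_ratios[0], rel=1e-6)

    def test_density_or_invariant_under_rescaling(self, default_cohort):
        base = tq.fit_logistic(default_cohort, "pcr", ("pre_density",))
        scaled = default_cohort.assign(pre_density=default_cohort["pre_density"] * 10)
        other = tq.fit_logistic(scaled, "pcr", ("pre_density",))
        # beta scales by 1/c, so the OR per original unit is unchanged
        assert other.params[1] * 10 == pytest.approx(base.params[1], rel=1e-6)

    def test_constant_outcome_flagged(self):
        data = _two_by_two(10, 20, 5, 40).assign(pcr=0.0)
        fit = tq.fit_logistic(data, "pcr", ("exposed",))
        assert not fit.converged
        assert fit.flag == "constant_outcome"

    def test_perfect_separation_flagged(self):
        x = np.linspace(-1, 1, 40)
        data = pd.DataFrame({"x": x, "pcr": (x > 0).astype(float)})
        fit = tq.fit_logistic(data, "pcr", ("x",))
        assert not fit.converged
        assert fit.flag == "perfect_separation"

    def test_complete_case_n_reported(self, default_cohort):
        data = default_cohort.head(1000).copy()
        data.loc[data.index[:100], "pre_density"] = np.nan
        fit = tq.fit_logistic(data, "pcr", ("pre_density", "age"))
        assert fit.n_observations == 900

    def test_reference_levels_follow_listed_order(self, default_cohort):
        design = build_design(default_cohort, ("er_status", "arm", "tumour_size_cat"))
        assert list(design.columns) == ["er_status[Positive]", "arm[D FEC]",
                                        "tumour_size_cat[>50 mm]"]

    def test_model_results_api(self, default_cohort):
        model = tq.LogisticModel.from_dataframe(default_cohort, "pcr",
                                                ("pre_density", "er_status"))
        res = model.fit()
        assert isinstance(res, LogisticResults)
        assert res.to_frame().shape[0] == 2
        assert "Logistic regression" in res.summary()
        assert np.all(res.conf_int[:, 0] < res.conf_int[:, 1])
        np.testing.assert_allclose(res.odds_ratios, np.exp(res.params[1:]))


class TestFormatFitTable:
    def _results(self, or_, lo, hi):
        se = (math.log(hi) - math.log(lo)) / (2 * _Z95)
        return LogisticResults(terms=["pre_density"],
                               params=np.array([0.0, math.log(or_)]),
                               bse=np.array([1.0, se]),
                               n_observations=609, converged=True)

    def test_density_row_rendering(self):
        row = tq.format_fit_table(self._results(2.93, 1.77, 4.85)).iloc[0]
        assert row["odds_ratio"] == "2.93"
        assert row["ci_95"] == "1.77–4.85"
        assert row["variable"] == "Median lymphocyte density"
        assert row["n"] == 609

    def test_null_coefficient_renders_unity(self):
        row = tq.format_fit_table(self._results(1.0, 0.5, 2.0)).iloc[0]
        assert row["odds_ratio"] == "1.00"

    def test_protective_effect_rounding(self):
        row = tq.format_fit_table(self._results(0.10, 0.033, 0.31)).iloc[0]
        assert row["odds_ratio"] == "0.10"
        assert row["ci_95"] == "0.03–0.31"

    def test_non_converged_rejected(self):
        res = LogisticResults(terms=["x"], params=np.full(2, np.nan),
                              bse=np.full(2, np.nan), n_observations=10,
                              converged=False, flag="constant_outcome")
        with pytest.raises(ContractViolation):
            tq.format_fit_table(res)


class TestKruskalWallis:
    def test_identical_values_give_zero(self):
        h, p = tq.kruskal_wallis([3.0] * 9, [1, 1, 1, 2, 2, 2, 3, 3, 3])
        assert h == 0.0 and p == 1.0

    def test_hand_computed_three_group_example(self):
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        h, p = tq.kruskal_wallis(values, groups)
        # rank-sum oracle: (12/90) * (3*4 + 3*25 + 3*64) - 30 = 7.2
        assert h == pytest.approx(7.2, abs=1e-12)
        assert p == pytest.approx(scipy.stats.chi2.sf(7.2, 2), rel=1e-12)

    def test_two_groups_equal_squared_wilcoxon_z(self, rng):
        values = rng.normal(size=30)  # continuous, no ties
        groups = np.repeat(["a", "b"], [12, 18])
        h, _ = tq.kruskal_wallis(values, groups)
        ranks = scipy.stats.rankdata(values)
        w = ranks[groups == "a"].sum()
        n1, n2, n = 12, 18, 30
        z = (w - n1 * (n + 1) / 2) / math.sqrt(n1 * n2 * (n + 1) / 12)
        assert h == pytest.approx(z**2, rel=1e-10)

    def test_monotone_transform_invariance(self, rng):
        values = rng.normal(size=40)
        groups = rng.integers(0, 3, size=40)
        h1, _ = tq.kruskal_wallis(values, groups)
        h2, _ = tq.kruskal_wallis(np.exp(values), groups)
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ContractViolation):
            tq.kruskal_wallis([1, 2, 3], ["a", "a", "a"])


def _exponential_cohort(rng, n, beta, censor_rate=0.05, base=0.1):
    x = (rng.random(n) < 0.5).astype(float)
    event_t = rng.exponential(1.0 / (base * np.exp(beta * x)))
    cens_t = rng.exponential(1.0 / censor_rate, size=n)
    return pd.DataFrame({
        "x": x,
        "os_time": np.minimum(event_t, cens_t),
        "os_event": (event_t <= cens_t).astype(int),
    })


class TestCox:
    def test_null_two_arm_effect_within_noise(self, rng):
        data = _exponential_cohort(rng, 2000, beta=0.0)
        res = tq.fit_cox(data, "os", terms=("x",))
        assert abs(res.params[0]) < 3 * res.bse[0]

    def test_known_hazard_ratio_recovered(self, rng):
        data = _exponential_cohort(rng, 5000, beta=math.log(2.0), censor_rate=0.045)
        res = tq.fit_cox(data, "os", terms=("x",))
        lo, hi = res.conf_int[0]
        assert lo <= 2.0 <= hi

    def test_er_stratification(self, default_cohort):
        sub = default_cohort.head(4000)
        res = tq.fit_cox(sub, "os", stratum=("er_status", "Positive"),
                         terms=("pre_density",))
        assert res.stratum == "er_status=Positive"
        assert res.n_observations == (sub["er_status"] == "Positive").sum()
        assert res.n_events >= 1
        assert "Cox PH" in res.summary()

    def test_time_scaling_invariance(self, rng):
        data = _exponential_cohort(rng, 1500, beta=0.4)
        a = tq.fit_cox(data, "os", terms=("x",))
        scaled = data.assign(os_time=data["os_time"] * 365.25)
        b = tq.fit_cox(scaled, "os", terms=("x",))
        assert a.params[0] == pytest.approx(b.params[0], rel=1e-6)

    def test_degenerate_inputs_rejected(self, rng):
        single = _exponential_cohort(rng, 1, beta=0.0)
        with pytest.raises(FitError):
            tq.fit_cox(single, "os", terms=("x",))
        data = _exponential_cohort(rng, 50, beta=0.0)
        no_events = data.assign(os_event=0)
        with pytest.raises(FitError):
            tq.fit_cox(no_events, "os", terms=("x",))
        neg_times = data.assign(os_time=-data["os_time"])
        with pytest.raises(ContractViolation):
            tq.fit_cox(neg_times, "os", terms=("x",))

    def test_dfs_endpoint_selected(self, default_cohort):
        res = tq.fit_cox(default_cohort.head(3000), "dfs", terms=("pre_density",))
        assert res.endpoint == "dfs"


class TestTable1Models:
    def test_univariable_and_multivariable_fits(self, default_cohort):
        fits = tq.table1_models(default_cohort)
        assert set(fits) == {"univariable", "multivariable"}
        assert fits["univariable"].to_frame().shape[0] == 1
        multi = fits["multivariable"].to_frame()
        assert multi.shape[0] == 7
        # generator truth: density effect near its configured log-odds
        beta = multi.set_index("term").loc["pre_density", "coef"]
        se = multi.set_index("term").loc["pre_density", "se"]
        assert abs(beta - math.log(2.13)) < 4 * se
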