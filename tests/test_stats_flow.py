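"""Assumption checks, Dunnett and Conover–Iman comparisons, and routing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from npqkit.errors import DegenerateDataError, InsufficientDataError
from npqkit.stats_flow import (
    GroupedData,
    bh_adjust,
    check_assumptions,
    conover_iman_bh,
    dunnett,
    route_and_test,
    significance_stars,
)


def grouped(values, accession, treatment=None, **kw):
    factors = pd.DataFrame({"accession": accession})
    if treatment is not None:
        factors["treatment"] = treatment
    return GroupedData(np.asarray(values, float), factors, **kw)


class TestAssumptionChecks:
    def test_unequal_variances_detected(self, rng):
        """One group with 16x the variance trips Brown–Forsythe reliably."""
        hits = 0
        for _ in range(100):
            a, b = rng.normal(0, 1, 20), rng.normal(0, 4, 20)
            d = grouped(np.r_[a, b], ["g1"] * 20 + ["g2"] * 20)
            _, bf_p = check_assumptions(d)
            hits += bf_p < 0.05
        assert hits > 90

    def test_exponential_data_fail_shapiro(self, rng):
        hits = 0
        for _ in range(100):
            x = rng.exponential(1.0, 30)
            d = grouped(x, ["g1"] * 15 + ["g2"] * 15)
            sh_p, _ = check_assumptions(d)
            hits += sh_p < 0.05
        assert hits > 90

    def test_null_pvalues_approximately_uniform(self, rng):
        """Identical normal groups: both assumption p-values ~ U(0,1)."""
        sh, bf = [], []
        for _ in range(300):
            x = rng.normal(0, 1, 150)
            d = grouped(x, ["a"] * 50 + ["b"] * 50 + ["c"] * 50)
            s, b = check_assumptions(d)
            sh.append(s)
            bf.append(b)
        assert sps.kstest(sh, "uniform").pvalue > 0.01
        assert sps.kstest(bf, "uniform").pvalue > 0.01

    def test_constant_data_degenerate(self):
        d = grouped([1.0] * 6, ["a"] * 3 + ["b"] * 3)
        sh_p, bf_p = check_assumptions(d)
        assert np.isnan(sh_p) and np.isnan(bf_p)


class TestDunnett:
    def test_single_comparison_equals_two_sided_t_test(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(0.7, 1, 11)
        res = dunnett([a, b], 0)
        t_p = sps.ttest_ind(b, a, equal_var=True).pvalue
        assert res["adjusted_p"].iloc[0] == pytest.approx(t_p, rel=1e-12)

    def test_centered_groups_give_pvalue_near_one(self):
        control = np.array([1.0, 2.0, 3.0, 4.0])
        res = dunnett([control, control + 0.0, control.copy()], 0,
                      rng=np.random.default_rng(0))
        assert (res["adjusted_p"] > 0.99).all()
        assert res["statistic"].abs().max() == pytest.approx(0.0)

    def test_adjusted_never_below_raw(self, rng):
        groups = [rng.normal(0, 1, 8) for _ in range(4)]
        res = dunnett(groups, 0, rng=np.random.default_rng(1))
        assert (res["adjusted_p"] >= res["raw_p"] - 1e-12).all()
        assert res["adjusted_p"].between(0, 1).all()

    def test_matches_monte_carlo_max_t_oracle(self, rng):
        """k=3 balanced, df=12: adjusted p equals a brute-force simulation of
        the null max-|t| distribution within Monte-Carlo tolerance."""
        groups = [rng.normal(0, 1, 5), rng.normal(0.9, 1, 5), rng.normal(0.2, 1, 5)]
        res = dunnett(groups, 0, rng=np.random.default_rng(7))
        n_sim = 200_000
        sim_rng = np.random.default_rng(99)
        sims = sim_rng.standard_normal((n_sim, 3, 5))
        means = sims.mean(axis=2)
        ss = ((sims - means[:, :, None]) ** 2).sum(axis=(1, 2))
        s2 = ss / 12.0
        se = np.sqrt(s2 * (2.0 / 5.0))
        t_null = np.abs(means[:, 1:] - means[:, [0]]) / se[:, None]
        max_t = t_null.max(axis=1)
        for t_obs, p_adj in zip(res["statistic"], res["adjusted_p"]):
            mc_p = float(np.mean(max_t >= abs(t_obs)))
            assert p_adj == pytest.approx(mc_p, abs=0.005)

    def test_seeded_runs_reproducible(self, rng):
        groups = [rng.normal(0, 1, 8) for _ in range(4)]
        p1 = dunnett(groups, 0, rng=np.random.default_rng(5))["adjusted_p"]
        p2 = dunnett(groups, 0, rng=np.random.default_rng(5))["adjusted_p"]
        assert (p1 == p2).all()

    def test_power_against_shifted_control(self, rng):
        """Control shifted by 3 SD: both contrasts flagged essentially always."""
        flagged = 0
        for _ in range(50):
            g = [rng.normal(3.0, 1, 8), rng.normal(0, 1, 8), rng.normal(0, 1, 8)]
            res = dunnett(g, 0, rng=np.random.default_rng(2))
            flagged += res["significant"].all()
        assert flagged >= 49

    def test_small_control_rejected(self):
        with pytest.raises(InsufficientDataError):
            dunnett([np.array([1.0]), np.array([1.0, 2.0, 3.0])], 0)


class TestConoverIman:
    def test_adjusted_at_least_raw_and_bounded(self, rng):
        groups = [rng.normal(0, 1, 10) for _ in range(4)]
        res = conover_iman_bh(groups, 0)
        assert (res["adjusted_p"] >= res["raw_p"] - 1e-12).all()
        assert res["adjusted_p"].between(0, 1).all()

    def test_dominant_group_detected(self, rng):
        hits = 0
        for _ in range(50):
            g = [rng.normal(0, 1, 10), rng.normal(2.0, 1, 10), rng.normal(0, 1, 10)]
            res = conover_iman_bh(g, 0)
            hits += bool(res["significant"].iloc[0])
        assert hits >= 48

    def test_null_rejections_controlled(self, rng):
        rej = 0
        for _ in range(200):
            g = [rng.normal(0, 1, 8) for _ in range(3)]
            rej += conover_iman_bh(g, 0)["significant"].any()
        assert rej / 200 < 0.10

    def test_all_tied_degenerate(self):
        with pytest.raises(DegenerateDataError):
            conover_iman_bh([np.ones(5), np.ones(5)], 0)


def test_bh_step_up_arithmetic():
    adj = bh_adjust([0.01, 0.04])
    assert adj == pytest.approx([0.02, 0.04])
    # monotone under permutation
    adj_rev = bh_adjust([0.04, 0.01])
    assert adj_rev == pytest.approx([0.04, 0.02])


class TestRouting:
    def _frame(self, rng, shift=0.0, dist="normal", n=8):
        vals, acc, trt = [], [], []
        for a in ("MsaRB", "MxgI", "MsiCR"):
            for t in ("warm", "chill"):
                mu = shift if (a == "MsaRB" and t == "chill") else 0.0
                if dist == "normal":
                    x = rng.normal(mu, 1, n)
                else:
                    x = rng.standard_cauchy(n) + mu
                vals.extend(x)
                acc.extend([a] * n)
                trt.extend([t] * n)
        return grouped(vals, acc, trt)

    def test_normal_data_take_parametric_branch(self, rng):
        hits = sum(
            route_and_test(self._frame(rng), seed=0).branch == "parametric"
            for _ in range(20))
        assert hits >= 17

    def test_cauchy_data_route_nonparametric(self, rng):
        hits = sum(
            route_and_test(self._frame(rng, dist="cauchy"), seed=0).branch
            == "nonparametric"
            for _ in range(30))
        assert hits > 27

    def test_both_contrast_families_present(self, rng):
        route = route_and_test(self._frame(rng, shift=3.0), seed=0)
        fams = set(route.comparisons["family"])
        assert fams == {"inter_accession", "intra_accession"}
        # the injected MsaRB-chill effect is detected in both families
        hit = route.comparisons[
            route.comparisons["contrast"].str.startswith("MsaRB vs MsiCR")
            & route.comparisons["contrast"].str.contains("chill")]
        assert hit["significant"].all()

    def test_omnibus_reported(self, rng):
        route = route_and_test(self._frame(rng, shift=3.0), seed=0)
        assert route.omnibus  # factorial ANOVA terms (or KW) present

    def test_log_transform_rescues_lognormal_data(self, rng):
        vals, acc = [], []
        for a in ("MsaRB", "MxgI", "MsiCR"):
            vals.extend(np.exp(rng.normal(0, 1.0, 30)))
            acc.extend([a] * 30)
        route = route_and_test(grouped(vals, acc), seed=0)
        assert route.transform_applied == "log"
        assert route.branch == "parametric"

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            grouped([1.0, 2.0, 3.0], ["a", "a", "a"])


def test_significance_stars_thresholds():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.0004) == "***"
    assert significance_stars(0.2) == ""
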