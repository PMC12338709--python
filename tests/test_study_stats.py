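"""Inference battery: ANOVA vs linear-model oracle, Tukey, correlations,
Steiger's Z."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import segquant as sq
from conftest import make_balanced_table


def ols_anova_oracle(table: pd.DataFrame, response: str = "y"):
    """Brute-force oracle: OLS with participant dummies + anova table.

    For the balanced complete design this reproduces the random-intercept
    model's fixed-effect F tests exactly (pooled within-participant
    error stratum).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    fit = ols(
        f"{response} ~ C(participant) + C(method) * C(session)", data=table
    ).fit()
    an = sm.stats.anova_lm(fit, typ=2)
    return {
        "Method": (an.loc["C(method)", "F"], an.loc["C(method)", "PR(>F)"]),
        "Session": (an.loc["C(session)", "F"], an.loc["C(session)", "PR(>F)"]),
        "Method:Session": (
            an.loc["C(method):C(session)", "F"],
            an.loc["C(method):C(session)", "PR(>F)"],
        ),
        "mse": fit.mse_resid,
        "df_resid": fit.df_resid,
        "participant_ms": an.loc["C(participant)", "sum_sq"]
        / an.loc["C(participant)", "df"],
    }


class TestShapiroScreen:
    def test_normal_groups_mostly_pass(self, rng):
        rows = []
        for met in ("tCr", "tNAA"):
            for meth in ("A", "B", "C"):
                for sess in (1, 2):
                    for v in rng.normal(7, 0.5, 100):
                        rows.append({"metabolite": met, "method": meth,
                                     "session": sess, "conc_mM": v})
        screen = sq.shapiro_normality_screen(pd.DataFrame(rows), "conc_mM")
        assert screen.attrs["bonferroni_m"] == 12
        assert screen["pass_after_correction"].mean() >= 0.95

    def test_heavy_tails_fail_majority(self, rng):
        fails = 0
        for rep in range(20):
            vals = rng.standard_cauchy(50)
            df = pd.DataFrame({"metabolite": "x", "method": "A", "session": 1,
                               "conc_mM": vals})
            screen = sq.shapiro_normality_screen(df, "conc_mM")
            fails += not screen["pass_after_correction"].iloc[0]
        assert fails > 10

    def test_constant_group_flagged(self):
        df = pd.DataFrame({"metabolite": "x", "method": "A", "session": 1,
                           "conc_mM": [3.0] * 10})
        screen = sq.shapiro_normality_screen(df, "conc_mM")
        assert bool(screen["constant"].iloc[0])
        assert not bool(screen["pass_after_correction"].iloc[0])

    def test_small_group_rejected(self):
        df = pd.DataFrame({"metabolite": "x", "method": "A", "session": 1,
                           "conc_mM": [1.0, 2.0]})
        with pytest.raises(ValueError, match="too small"):
            sq.shapiro_normality_screen(df, "conc_mM")


class TestPairedSessionTest:
    def test_identical_sessions(self):
        t, p = sq.paired_session_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_shift_degenerate(self):
        with pytest.raises(ValueError, match="zero-variance"):
            sq.paired_session_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_bonferroni_scaling_capped(self, rng):
        a = rng.normal(0, 1, 10)
        b = a + rng.normal(0.2, 1, 10)
        _, p1 = sq.paired_session_test(a, b, bonferroni_m=1)
        _, p3 = sq.paired_session_test(a, b, bonferroni_m=3)
        assert p3 == pytest.approx(min(1.0, 3 * p1))

    def test_power_matches_noncentral_t(self, rng):
        """Rejection rate under a 1-SD shift matches the closed-form
        power of the paired t-test (noncentral-t oracle)."""
        n, reps, alpha = 13, 1000, 0.05
        rejections = 0
        for _ in range(reps):
            d = rng.normal(1.0, 1.0, n)
            _, p = sq.paired_session_test(np.zeros(n), d, bonferroni_m=1)
            rejections += p < alpha
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        nc = 1.0 * np.sqrt(n)
        power = stats.nct.sf(tcrit, n - 1, nc) + stats.nct.cdf(-tcrit, n - 1, nc)
        assert rejections / reps == pytest.approx(power, abs=0.04)


class TestMethodSessionModel:
    def test_no_method_effect_with_participant_offsets(self, rng):
        t = make_balanced_table(6, rng, method_effects=(0, 0, 0), noise_sd=0.0,
                                participant_sd=2.0)
        fit = sq.method_session_model(t, "y")
        method = fit.anova[0]
        assert method.term == "Method"
        assert method.F == pytest.approx(0.0, abs=1e-18)
        means = [m.mean for m in fit.marginal_means if m.factor == "Method"]
        assert np.ptp(means) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_participants", [3, 5, 13])
    def test_matches_ols_oracle(self, rng, n_participants):
        t = make_balanced_table(n_participants, rng,
                                method_effects=(0.0, 0.4, 0.9),
                                session_effect=0.1)
        fit = sq.method_session_model(t, "y")
        oracle = ols_anova_oracle(t)
        for eff in fit.anova:
            F_o, p_o = oracle[eff.term]
            assert eff.F == pytest.approx(F_o, abs=1e-8, rel=1e-8)
            assert eff.p == pytest.approx(p_o, abs=1e-10)
        assert fit.ms_error == pytest.approx(oracle["mse"], rel=1e-10)
        assert fit.df_error == oracle["df_resid"]
        # EMM CIs from the variance decomposition recomputed from the
        # oracle's mean squares
        m, s, n = 3, 2, n_participants
        sigma_u2 = max(0.0, (oracle["participant_ms"] - oracle["mse"]) / (m * s))
        se = np.sqrt(sigma_u2 / n + oracle["mse"] / (n * s))
        tcrit = stats.t.ppf(0.975, fit.df_error)
        for emm in fit.marginal_means:
            if emm.factor != "Method":
                continue
            cell = t[t["method"] == emm.level]["y"].mean()
            assert emm.mean == pytest.approx(cell, rel=1e-10)
            assert emm.ci_low == pytest.approx(emm.mean - tcrit * se, abs=1e-8)
            assert emm.ci_high == pytest.approx(emm.mean + tcrit * se, abs=1e-8)

    def test_denominator_df_matches_design(self, rng):
        t = make_balanced_table(13, rng)
        fit = sq.method_session_model(t, "y")
        assert all(eff.df_den == 60 for eff in fit.anova)  # (13-1)*(3*2-1)

    def test_marginal_mean_conservation(self, rng):
        t = make_balanced_table(7, rng, method_effects=(0.1, -0.2, 0.5))
        fit = sq.method_session_model(t, "y")
        grand = t["y"].mean()
        for factor in ("Method", "Session"):
            means = [m.mean for m in fit.marginal_means if m.factor == factor]
            assert np.mean(means) == pytest.approx(grand, abs=1e-10)

    def test_unbalanced_rejected(self, rng):
        t = make_balanced_table(4, rng).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            sq.method_session_model(t, "y")


class TestTukeyPairwise:
    def test_equal_means_p_near_one(self, rng):
        t = make_balanced_table(8, rng, method_effects=(0, 0, 0), noise_sd=0.5)
        fit = sq.method_session_model(t, "y")
        contrasts = sq.tukey_pairwise(fit)
        assert len(contrasts) == 3
        # adjusted p >= unadjusted pairwise p, elementwise
        for c in contrasts:
            p_unadj = 2 * stats.t.sf(abs(c.t_ratio), c.df)
            assert c.p_adjusted >= p_unadj - 1e-12

    def test_matches_studentized_range_oracle(self, rng):
        t = make_balanced_table(6, rng, method_effects=(0.0, 0.6, 1.1))
        fit = sq.method_session_model(t, "y")
        oracle = ols_anova_oracle(t)
        n_rep = 6 * 2
        se = np.sqrt(2 * oracle["mse"] / n_rep)
        means = t.groupby("method")["y"].mean()
        for c in sq.tukey_pairwise(fit):
            a, b = c.pair.split(" - ")
            est = means[a] - means[b]
            assert c.estimate == pytest.approx(est, rel=1e-10)
            assert c.se == pytest.approx(se, rel=1e-10)
            q = abs(est / se) * np.sqrt(2)
            p = stats.studentized_range.sf(q, 3, oracle["df_resid"])
            assert c.p_adjusted == pytest.approx(p, abs=1e-10)
            assert np.sign(c.estimate) == np.sign(c.t_ratio)

    def test_published_means_with_tiny_noise(self, rng):
        means = {"ANTS": 7.19, "FSL": 7.59, "SPM": 6.89}
        rows = []
        for i in range(13):
            for meth, mu in means.items():
                for sess in (1, 2):
                    rows.append({"participant": f"P{i}", "method": meth,
                                 "session": sess,
                                 "y": mu + rng.normal(0, 1e-4)})
        fit = sq.method_session_model(pd.DataFrame(rows), "y")
        got = {c.pair: c.estimate for c in sq.tukey_pairwise(fit)}
        assert got["ANTS - FSL"] == pytest.approx(-0.40, abs=1e-3)
        assert got["ANTS - SPM"] == pytest.approx(0.30, abs=1e-3)
        assert got["FSL - SPM"] == pytest.approx(0.70, abs=1e-3)


class TestNormalizedGm:
    def test_equal_split(self):
        assert sq.normalized_gm(sq.TissueFractions(0.5, 0.5, 0.0)) == 0.5

    def test_spm_printed_means(self):
        g = sq.normalized_gm(sq.TissueFractions(0.56, 0.27, 0.17))
        assert g == pytest.approx(0.56 / 0.83, rel=1e-12)

    def test_no_tissue_rejected(self):
        with pytest.raises(ValueError):
            sq.normalized_gm(sq.TissueFractions(0.0, 0.0, 1.0))


class TestPearsonAssociation:
    def test_perfect_negative(self):
        x = np.arange(10.0)
        res = sq.pearson_association(x, -x)
        assert res.r == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(res.r**2, abs=1e-12)

    def test_independent_samples_near_zero(self, rng):
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        assert abs(sq.pearson_association(x, y).r) < 0.05

    def test_hand_computed_value(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        # r = cov/(sx*sy) computed by hand: 1.5/(1*sqrt(7/3))
        expected = 1.5 / (1.0 * np.sqrt(7.0 / 3.0))
        assert sq.pearson_association(x, y).r == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            sq.pearson_association([1, 1, 1], [1, 2, 3])


class TestSteigerDependentZ:
    def test_equal_correlations_give_zero(self):
        res = sq.steiger_dependent_z(0.5, 0.5, 0.3, n=30)
        assert res.z == 0.0
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = sq.steiger_dependent_z(0.5, 0.3, 0.4, n=50)
        b = sq.steiger_dependent_z(0.3, 0.5, 0.4, n=50)
        assert a.z == pytest.approx(-b.z, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_reference_value(self):
        # independently evaluated Z1* (Fisher z difference with pooled
        # r-bar covariance) for (r_xy, r_xz, r_yz, n) = (0.5, 0.3, 0.4, 50)
        res = sq.steiger_dependent_z(0.5, 0.3, 0.4, n=50)
        assert res.z == pytest.approx(1.41645, abs=1e-5)
        assert res.p == pytest.approx(0.15665, abs=1e-5)

    def test_null_calibration_monte_carlo(self, rng):
        """Under r_xy = r_xz the statistic is approximately standard
        normal: simulated Z has unit scale and ~5% rejection."""
        r, ryz, n, reps = 0.4, 0.5, 60, 2000
        cov = np.array([[1.0, r, r], [r, 1.0, ryz], [r, ryz, 1.0]])
        L = np.linalg.cholesky(cov)
        zs = []
        for _ in range(reps):
            data = rng.normal(size=(n, 3)) @ L.T
            c = np.corrcoef(data, rowvar=False)
            zs.append(sq.steiger_dependent_z(c[0, 1], c[0, 2], c[1, 2], n).z)
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.08
        assert 0.9 < zs.std() < 1.1
        assert np.mean(np.abs(zs) > 1.96) == pytest.approx(0.05, abs=0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sq.steiger_dependent_z(1.0, 0.3, 0.2, n=30)
        with pytest.raises(ValueError):
            sq.steiger_dependent_z(0.5, 0.3, 0.2, n=3)
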