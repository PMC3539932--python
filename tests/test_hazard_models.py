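import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from cvdineq._cox import cox_fit
from cvdineq.coding import BLOCKS, MISSING
from cvdineq.hazard_models import (
    MODEL_SEQUENCE,
    AssociationTestError,
    EstimationError,
    ModelSpec,
    build_design,
    fit_model_sequence,
    fit_ph_model,
    select_factors,
)
from cvdineq.hazard_models import test_sep_association as sep_association_p
from conftest import simulate_exponential


def brute_force_breslow_loglik(beta, time, event, x):
    """Written-out Breslow partial log-likelihood for one covariate."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestCoxSolver:
    def test_tiny_fixture_matches_brute_force_oracle(self):
        """n=6, distinct event times: coefficient equals an independent
        scalar maximization of the written-out partial likelihood."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        res = cox_fit(time, event, x)
        oracle = optimize.minimize_scalar(
            lambda b: -brute_force_breslow_loglik(b, time, event, x),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.params[0] == pytest.approx(oracle.x, abs=1e-6)
        assert res.loglik == pytest.approx(-oracle.fun, abs=1e-8)

    def test_matches_statsmodels_breslow_with_ties(self):
        from statsmodels.duration.hazard_regression import PHReg

        rng = np.random.default_rng(5)
        n = 400
        X = rng.binomial(1, 0.4, (n, 3)).astype(float)
        t = np.ceil(rng.exponential(5 / np.exp(X @ [0.5, -0.3, 0.2])))  # tied times
        e = (t <= 8).astype(int)
        t = np.minimum(t, 8)
        ours = cox_fit(t, e, X, ties="breslow")
        ref = PHReg(t, X, status=e, ties="breslow").fit(disp=False, method="newton")
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.bse, np.asarray(ref.bse), atol=1e-6)

    def test_matches_lifelines_efron_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(6)
        n = 400
        X = rng.binomial(1, 0.4, (n, 2)).astype(float)
        t = np.ceil(rng.exponential(5 / np.exp(X @ [0.6, -0.2])))
        e = (t <= 8).astype(int)
        t = np.minimum(t, 8)
        ours = cox_fit(t, e, X, ties="efron")
        df = pd.DataFrame(X, columns=["a", "b"])
        df["T"], df["E"] = t, e
        ref = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(ours.params, ref.params_.values, atol=1e-5)
        assert ours.loglik == pytest.approx(ref.log_likelihood_, abs=1e-4)

    def test_null_covariate_ci_covers_one(self):
        """Covariate independent of the hazard: HR ~ 1, ~95% CI coverage."""
        covered = 0
        reps = 200
        for seed in range(reps):
            time, event, x = simulate_exponential(300, 0.0, 0.4, seed)
            res = cox_fit(time, event, x)
            lo = res.params[0] - 1.96 * res.bse[0]
            hi = res.params[0] + 1.96 * res.bse[0]
            covered += lo <= 0.0 <= hi
        assert 0.90 <= covered / reps <= 0.99

    def test_no_events_raises(self):
        with pytest.raises(Exception):
            cox_fit([1.0, 2.0], [0, 0], [0.0, 1.0])


class TestModelSequence:
    def test_nesting_structure(self):
        assert MODEL_SEQUENCE[1].covariates == ("adulthood_sep",)
        assert set(MODEL_SEQUENCE[6].covariates) == set(
            ("adulthood_sep",) + BLOCKS["material"] + BLOCKS["behavioural"] + BLOCKS["psychosocial"]
        )
        assert set(MODEL_SEQUENCE[7].covariates) == set(MODEL_SEQUENCE[6].covariates) | {
            "childhood_sep"
        }

    def test_loglik_monotone_in_nesting(self, male_analysis_frames):
        surv, coded = male_analysis_frames
        fits = fit_model_sequence(surv, coded)
        ll = {m: f.log_partial_likelihood for m, f in fits.items()}
        assert ll[2] >= ll[1] - 1e-6
        assert ll[3] >= ll[1] - 1e-6
        assert ll[6] >= max(ll[3], ll[4], ll[5]) - 1e-6
        assert ll[7] >= max(ll[6], ll[2]) - 1e-6

    def test_reference_levels_absent_from_terms(self, male_analysis_frames):
        surv, coded = male_analysis_frames
        fit = fit_ph_model(surv, coded, MODEL_SEQUENCE[1])
        sep_terms = fit.terms[fit.terms["covariate"] == "adulthood_sep"]
        assert "4_high" not in set(sep_terms["level"])
        assert (fit.terms["ci_low"] <= fit.terms["hr"]).all()
        assert (fit.terms["hr"] <= fit.terms["ci_high"]).all()
        assert fit.n_events <= fit.n

    def test_permuted_level_order_same_contrasts(self, male_analysis_frames):
        surv, coded = male_analysis_frames
        time = surv["time_years"].to_numpy()
        event = surv["event"].to_numpy()
        levels_fwd = {"adulthood_sep": ("4_high", "3_mid_high", "2_mid_low", "1_low")}
        levels_rev = {"adulthood_sep": ("4_high", "1_low", "2_mid_low", "3_mid_high")}
        X1, lab1 = build_design(coded, ["adulthood_sep"], levels_fwd)
        X2, lab2 = build_design(coded, ["adulthood_sep"], levels_rev)
        f1 = cox_fit(time, event, X1)
        f2 = cox_fit(time, event, X2)
        b1 = dict(zip([l for _, l in lab1], f1.params))
        b2 = dict(zip([l for _, l in lab2], f2.params))
        for level in ("1_low", "2_mid_low", "3_mid_high"):
            assert b1[level] == pytest.approx(b2[level], abs=1e-8)

    def test_no_events_is_estimation_error(self, male_analysis_frames):
        surv, coded = male_analysis_frames
        dead = surv.copy()
        dead["event"] = 0
        with pytest.raises(EstimationError):
            fit_ph_model(dead, coded, MODEL_SEQUENCE[1])

    def test_parameter_recovery_binary_covariate(self):
        """Configured log-HR 0.6 recovered within Monte-Carlo error."""
        estimates = []
        for seed in range(60):
            time, event, x = simulate_exponential(2000, 0.6, 0.3, 1000 + seed)
            estimates.append(cox_fit(time, event, x).params[0])
        mcse = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 0.6) < 3 * mcse


class TestSepAssociation:
    def test_identical_distributions_give_p_one(self):
        cov = pd.Series(["a", "b"] * 50)
        sep = pd.Series((["1_low"] * 2 + ["4_high"] * 2) * 25)
        assert sep_association_p(cov, sep) == pytest.approx(1.0)

    def test_hand_computed_2x2_oracle(self):
        # table [[10,20],[20,10]]: X2 = 60*(10*10-20*20)^2/(30*30*30*30) = 6.6667
        cov = pd.Series(["a"] * 30 + ["b"] * 30)
        sep = pd.Series(["1_low"] * 10 + ["4_high"] * 20 + ["1_low"] * 20 + ["4_high"] * 10)
        expected = stats.chi2.sf(20.0 / 3.0, df=1)
        assert sep_association_p(cov, sep) == pytest.approx(expected, abs=1e-9)

    def test_p_uniform_under_independence(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(1000):
            cov = pd.Series(rng.choice(["a", "b"], 120))
            sep = pd.Series(rng.choice(["1_low", "2_mid_low", "4_high"], 120))
            ps.append(sep_association_p(cov, sep))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_missing_level_excluded(self):
        cov = pd.Series(["a", "b", MISSING] * 40)
        sep = pd.Series(["1_low", "4_high"] * 60)
        p = sep_association_p(cov, sep)  # must not fail on the MISSING rows
        assert 0 <= p <= 1

    def test_degenerate_table_raises(self):
        with pytest.raises(AssociationTestError):
            sep_association_p(pd.Series(["a"] * 10), pd.Series(["1_low"] * 10))


class TestFactorSelection:
    def _frames(self, effect: float, gradient: float, seed=0, n=4000):
        """Synthetic coded data with a single 'tenure' factor whose mortality
        effect and SEP gradient are controlled directly."""
        rng = np.random.default_rng(seed)
        sep = rng.choice(["1_low", "2_mid_low", "3_mid_high", "4_high"], n)
        u = pd.Series(sep).map(
            {"1_low": 1.0, "2_mid_low": 0.67, "3_mid_high": 0.33, "4_high": 0.0}
        ).to_numpy()
        renter = rng.random(n) < 1 / (1 + np.exp(-(-0.5 + gradient * u)))
        child = rng.choice(["professional", "white_collar", "blue_collar"], n)
        lam = 0.02 * np.exp(effect * renter)
        t = rng.exponential(1 / lam)
        event = (t <= 16.5).astype(int)
        coded = pd.DataFrame(
            {
                "adulthood_sep": sep,
                "childhood_sep": child,
                "tenure": np.where(renter, "renter", "owner"),
                "age_baseline": rng.uniform(40, 75, n),
            }
        )
        surv = pd.DataFrame({"time_years": np.minimum(t, 16.5), "event": event})
        return surv, coded

    def test_effect_and_gradient_selected(self):
        surv, coded = self._frames(effect=0.7, gradient=1.5)
        sel = select_factors(surv, coded, "male", candidates=["tenure"])
        row = sel.evidence.iloc[0]
        assert row["selected"]
        assert row["p_mortality"] < 0.05 and row["p_sep"] < 0.05

    def test_effect_without_gradient_not_selected(self):
        surv, coded = self._frames(effect=0.7, gradient=0.0)
        sel = select_factors(surv, coded, "male", candidates=["tenure"])
        row = sel.evidence.iloc[0]
        assert not row["selected"]
        assert row["p_mortality"] < 0.05 and row["p_sep"] >= 0.05

    def test_gradient_without_effect_not_selected(self):
        surv, coded = self._frames(effect=0.0, gradient=1.5)
        sel = select_factors(surv, coded, "male", candidates=["tenure"])
        row = sel.evidence.iloc[0]
        assert not row["selected"]
        assert row["p_sep"] < 0.05 and row["p_mortality"] >= 0.05
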