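"""Cox model contracts: construct covariate, Firth penalization,
separation handling, and the adjusted study models."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from conftest import breslow_loglik_oracle
from cpegx.survival import (
    CONSTRUCT_LEVELS, build_design, cox_fit, fit_paper_models, make_construct,
)
from cpegx.synthetic import SyntheticConfig, gen_survival_data


def _sim(n=200, beta=0.5, seed=0, censor_scale=1.5):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t_ev = np.exp(-beta * x) * rng.exponential(size=n)
    c = rng.exponential(censor_scale, size=n)
    return (pd.DataFrame({"x": x}), np.minimum(t_ev, c),
            (t_ev <= c).astype(int))


class TestConstruct:
    def test_reference_level(self):
        assert make_construct("no", "0") == CONSTRUCT_LEVELS[0]

    @pytest.mark.parametrize("load", ["1-3", "4+"])
    def test_node_positive_collapses_load(self, load):
        assert make_construct("yes", load) == "AST/node+"

    def test_all_four_levels_reachable(self):
        combos = [("no", "0"), ("yes", "0"), ("no", "1-3"), ("yes", "4+")]
        assert {make_construct(a, l) for a, l in combos} == set(CONSTRUCT_LEVELS)

    def test_unknown_categories_error(self):
        with pytest.raises(ValueError, match="AST"):
            make_construct("maybe", "0")
        with pytest.raises(ValueError, match="axillary"):
            make_construct("yes", "lots")


class TestCoxFit:
    def test_matches_brute_force_partial_likelihood_maximizer(self):
        design, time, event = _sim(n=80, beta=0.8, seed=1)
        fit = cox_fit(design, time, event, penalize="none")
        X = design.to_numpy()
        res = minimize(lambda b: -breslow_loglik_oracle(X, time, event, b),
                       x0=[0.0], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10})
        assert fit.terms["x"].beta == pytest.approx(res.x[0], abs=1e-5)

    def test_matches_lifelines_multivariable(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(2)
        n = 150
        design = pd.DataFrame({"a": rng.normal(size=n),
                               "b": rng.binomial(1, 0.4, size=n).astype(float)})
        lp = 0.5 * design["a"] - 0.7 * design["b"]
        t_ev = np.exp(-lp.to_numpy()) * rng.exponential(size=n)
        c = rng.exponential(2.0, size=n)
        time, event = np.minimum(t_ev, c), (t_ev <= c).astype(int)
        fit = cox_fit(design, time, event, penalize="none")
        df = design.assign(T=time, E=event)
        cph = CoxPHFitter().fit(df, "T", "E")
        for col in ("a", "b"):
            assert fit.terms[col].beta == pytest.approx(cph.params_[col], abs=1e-5)
            assert fit.terms[col].se == pytest.approx(cph.standard_errors_[col],
                                                      rel=1e-3)

    def test_firth_close_to_mle_without_separation(self):
        design, time, event = _sim(n=1000, beta=0.7, seed=3)
        f = cox_fit(design, time, event, penalize="firth")
        m = cox_fit(design, time, event, penalize="none")
        assert abs(f.terms["x"].beta - m.terms["x"].beta) < 0.02

    def test_separation_finite_under_firth_flagged_unpenalized(self):
        # binary covariate perfectly ordering the event times
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
        time = np.arange(1.0, 9.0)
        event = np.ones(8, int)
        design = pd.DataFrame({"x": x})
        with pytest.warns(UserWarning, match="monotone"):
            mle = cox_fit(design, time, event, penalize="none")
        assert mle.monotone_likelihood and not mle.converged
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            firth = cox_fit(design, time, event, penalize="firth")
        est = firth.terms["x"]
        assert abs(est.beta) < 10
        assert np.isfinite(est.ci_low) and np.isfinite(est.ci_high)
        assert firth.converged

    def test_firth_invariant_to_recentering(self):
        design, time, event = _sim(n=120, beta=0.5, seed=4)
        a = cox_fit(design, time, event, penalize="firth")
        b = cox_fit(design + 100.0, time, event, penalize="firth")
        assert a.terms["x"].beta == pytest.approx(b.terms["x"].beta, abs=1e-6)

    def test_fitted_likelihood_not_below_null(self):
        design, time, event = _sim(n=100, seed=5)
        fit = cox_fit(design, time, event, penalize="firth")
        from cpegx.survival import _penalized_loglik
        ll0, _, _ = _penalized_loglik(design.to_numpy(), time, event,
                                      np.zeros(1), True)
        assert fit.loglik >= ll0 - 1e-12

    def test_profile_ci_close_to_wald_when_well_behaved(self):
        design, time, event = _sim(n=400, beta=0.5, seed=6)
        wald = cox_fit(design, time, event, penalize="firth", ci="wald")
        prof = cox_fit(design, time, event, penalize="firth", ci="profile")
        w, p = wald.terms["x"], prof.terms["x"]
        assert p.ci_low == pytest.approx(w.ci_low, rel=0.15)
        assert p.ci_high == pytest.approx(w.ci_high, rel=0.15)
        assert p.ci_low < p.hr < p.ci_high

    def test_collinear_design_raises(self):
        design, time, event = _sim(n=50, seed=7)
        design["x2"] = design["x"] * 2.0
        with pytest.raises(ValueError, match="collinear|singular"):
            cox_fit(design, time, event, penalize="none")

    def test_missing_values_rejected_and_epv_warning(self):
        design, time, event = _sim(n=40, seed=8)
        bad = design.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cox_fit(bad, time, event)
        few = design.iloc[:12]
        with pytest.warns(UserWarning, match="events per df"):
            cox_fit(few, time[:12], np.array([1, 1, 1] + [0] * 9))


class TestGenSurvival:
    def test_no_censoring_means_all_events(self):
        cov = pd.DataFrame({"x": np.random.default_rng(0).normal(size=50)})
        out = gen_survival_data(cov, {"x": 0.5}, censoring_rate=0.0, seed=1)
        assert (out["event"] == 1).all()
        assert (out["time"] > 0).all()

    def test_censoring_calibrated_at_large_n(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame({"x": rng.normal(size=800)})
        for target in (0.3, 0.6, 0.85):
            out = gen_survival_data(cov, {"x": 0.5}, censoring_rate=target,
                                    seed=2)
            realized = 1.0 - out["event"].mean()
            assert abs(realized - target) < 0.05

    def test_missing_beta_column_errors(self):
        cov = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="absent"):
            gen_survival_data(cov, {"y": 1.0})

    def test_coefficient_recovery(self):
        rng = np.random.default_rng(3)
        estimates = []
        for _ in range(40):
            cov = pd.DataFrame({"x": rng.binomial(1, 0.5, 300).astype(float)})
            out = gen_survival_data(cov, {"x": 0.5}, censoring_rate=0.3,
                                    seed=int(rng.integers(2**31)))
            fit = cox_fit(cov, out["time"], out["event"], penalize="none")
            estimates.append(fit.terms["x"].beta)
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.08)

    def test_null_betas_logrank_uniform(self):
        from lifelines.statistics import logrank_test
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(30):
            grp = rng.binomial(1, 0.5, 120)
            cov = pd.DataFrame({"g": grp.astype(float)})
            out = gen_survival_data(cov, {"g": 0.0}, censoring_rate=0.3,
                                    seed=int(rng.integers(2**31)))
            res = logrank_test(out.loc[grp == 1, "time"], out.loc[grp == 0, "time"],
                               out.loc[grp == 1, "event"], out.loc[grp == 0, "event"])
            pvals.append(res.p_value)
        # uniform p-values: mean near 0.5, no pile-up of rejections
        assert 0.3 < np.mean(pvals) < 0.7
        assert np.mean(np.array(pvals) < 0.05) <= 0.15


class TestPaperModels:
    def test_design_layout_and_complete_case(self, small_cohort):
        clin = small_cohort.clinical.copy()
        clin.loc[0, "age"] = np.nan
        with pytest.warns(UserWarning, match="incomplete"):
            design, time, event = build_design(clin)
        assert len(design) == len(clin) - 1
        expected = ["age", "size_mm", "grade_2", "grade_3"] + \
            [f"construct[{l}]" for l in CONSTRUCT_LEVELS[1:]]
        assert list(design.columns) == expected

    def test_three_model_variants(self, small_cohort):
        clin = small_cohort.clinical
        z = small_cohort.cpe_z
        pc1 = small_cohort.truth.latent_pc_scores
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cpe_only = fit_paper_models(clin, cpe=z, which="cpe_only")
            both = fit_paper_models(clin, cpe=z, pc1=pc1, which="both")
        assert "cpe" in cpe_only.terms and "pc1" not in cpe_only.terms
        assert {"cpe", "pc1"} <= set(both.terms)
        assert cpe_only.penalized
        for t in cpe_only.terms.values():
            assert t.hr == pytest.approx(np.exp(t.beta))
            assert t.ci_low < t.hr < t.ci_high

    def test_planted_cpe_effect_recovered_with_negative_hr(self, small_cohort):
        clin = small_cohort.clinical
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_paper_models(clin, cpe=small_cohort.cpe_z, which="cpe_only")
        est = fit.terms["cpe"]
        planted = small_cohort.truth.survival_betas_used["cpe"]
        assert est.hr < 1.0
        assert abs(est.beta - planted) < 2 * est.se
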