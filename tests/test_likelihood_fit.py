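"""Mixed-scale likelihood, gradient, and constrained MLE."""

import numpy as np
import pytest
import statsmodels.api as smapi

import colreg.synthetic_data as sd
from colreg.basis import BernsteinBasis, StepBasis, SupportWindow
from colreg.likelihood_fit import (
    FitOptions,
    FreeParameterization,
    Observation,
    _negloglik_grad,
    _Packed,
    fit,
    fit_binary_reduction,
    loglik_contribution,
    total_negloglik,
)
from colreg.model_core import ModelSpec, ParameterVector, cdf

from conftest import exact_observations, two_cov_config


class TestObservation:
    def test_exact_xor_interval(self):
        with pytest.raises(ValueError):
            Observation(stratum="s", exact=24.0, lower=20.0)
        with pytest.raises(ValueError):
            Observation(stratum="s", lower=25.0, upper=20.0)
        with pytest.raises(ValueError):
            Observation(stratum="s", exact=24.0, weight=-1.0)

    def test_sentinels_allowed(self):
        o = Observation(stratum="s")  # (hard_lower, hard_upper]
        assert not o.is_exact


class TestContributions:
    def test_whole_line_interval_contributes_zero(self, toy_model):
        spec, params = toy_model
        obs = Observation(stratum="a", x=(0.0, 0.0))
        assert loglik_contribution(obs, params, spec) == pytest.approx(0.0)

    def test_half_line_at_zero_transform(self):
        w = SupportWindow(10.0, 50.0, 0.0, np.inf)
        spec = ModelSpec(("s",), (), BernsteinBasis(1, w), "logit")
        params = ParameterVector(np.array([[-2.0, 2.0]]), ())
        obs = Observation(stratum="s", upper=30.0)  # transform(30) = 0
        assert loglik_contribution(obs, params, spec) == pytest.approx(np.log(0.5))

    def test_weight_scales_contribution(self, toy_model):
        spec, params = toy_model
        o1 = Observation(stratum="a", x=(0.1, 0.2), lower=20.0, upper=25.0)
        o3 = Observation(stratum="a", x=(0.1, 0.2), lower=20.0, upper=25.0, weight=3.0)
        assert loglik_contribution(o3, params, spec) == pytest.approx(
            3.0 * loglik_contribution(o1, params, spec)
        )

    def test_exact_approximates_narrow_interval(self, toy_model):
        """The density contribution is the h->0 limit of the interval
        contribution: log P(b-h < Y <= b+h) - log(2h) -> log f(b)."""
        spec, params = toy_model
        h = 1e-4
        for b in (18.0, 25.0, 31.5, 40.0):
            exact = loglik_contribution(
                Observation(stratum="a", x=(0.3, -0.1), exact=b), params, spec
            )
            narrow = loglik_contribution(
                Observation(stratum="a", x=(0.3, -0.1), lower=b - h, upper=b + h),
                params,
                spec,
            ) - np.log(2 * h)
            assert exact == pytest.approx(narrow, abs=1e-4)


class TestTotalNegloglik:
    def test_single_observation(self, toy_model):
        spec, params = toy_model
        obs = Observation(stratum="a", x=(0.0, 1.0), exact=27.0)
        assert total_negloglik([obs], params, spec) == pytest.approx(
            -loglik_contribution(obs, params, spec)
        )

    def test_doubling_weights_doubles(self, toy_model):
        spec, params = toy_model
        rng = np.random.default_rng(1)
        obs = [
            Observation(stratum="a", x=tuple(rng.normal(size=2)),
                        exact=float(rng.uniform(15, 40)))
            for _ in range(50)
        ]
        obs2 = [
            Observation(stratum=o.stratum, x=o.x, exact=o.exact, weight=2.0)
            for o in obs
        ]
        assert total_negloglik(obs2, params, spec) == pytest.approx(
            2.0 * total_negloglik(obs, params, spec)
        )

    def test_matches_naive_summation(self, toy_model):
        spec, params = toy_model
        rng = np.random.default_rng(2)
        obs = []
        for _ in range(100):
            s = rng.choice(["a", "b"])
            x = tuple(rng.normal(size=2))
            if rng.random() < 0.5:
                obs.append(Observation(stratum=s, x=x, exact=float(rng.uniform(15, 40))))
            else:
                lo = float(rng.uniform(15, 35))
                obs.append(Observation(stratum=s, x=x, lower=lo, upper=lo + 2.0))
        naive = -sum(loglik_contribution(o, params, spec) for o in obs)
        assert total_negloglik(obs, params, spec) == pytest.approx(naive, abs=1e-10)

    def test_permutation_invariance_of_likelihood(self, toy_model):
        spec, params = toy_model
        rng = np.random.default_rng(3)
        obs = [
            Observation(stratum="a", x=tuple(rng.normal(size=2)),
                        exact=float(rng.uniform(15, 40)))
            for _ in range(200)
        ]
        v1 = total_negloglik(obs, params, spec)
        v2 = total_negloglik([obs[i] for i in rng.permutation(200)], params, spec)
        assert v1 == pytest.approx(v2, abs=1e-10 * abs(v1))

    def test_empty_data_rejected(self, toy_model):
        spec, params = toy_model
        with pytest.raises(ValueError):
            total_negloglik([], params, spec)


class TestFreeParameterization:
    def test_roundtrip_and_monotonicity(self, toy_model):
        spec, params = toy_model
        fp = FreeParameterization(spec)
        free = fp.to_free(params)
        back = fp.to_natural(free)
        np.testing.assert_allclose(back.theta, params.theta, atol=1e-9)
        np.testing.assert_allclose(back.beta, params.beta)
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = fp.to_natural(rng.normal(size=fp.n_free) * 3)
            assert p.is_monotone()

    def test_jacobian_matches_finite_difference(self, toy_model):
        spec, _ = toy_model
        fp = FreeParameterization(spec)
        rng = np.random.default_rng(4)
        free = rng.normal(size=fp.n_free)
        J = fp.jacobian(free)
        h = 1e-7
        for j in range(fp.n_free):
            fplus, fminus = free.copy(), free.copy()
            fplus[j] += h
            fminus[j] -= h
            col = (
                fp.to_natural(fplus).flatten() - fp.to_natural(fminus).flatten()
            ) / (2 * h)
            np.testing.assert_allclose(J[:, j], col, atol=1e-6)


def test_analytic_gradient_matches_finite_difference(toy_model):
    spec, params = toy_model
    rng = np.random.default_rng(9)
    obs = []
    for _ in range(120):
        s = rng.choice(["a", "b"])
        x = tuple(rng.normal(size=2))
        r = rng.random()
        if r < 0.4:
            obs.append(Observation(stratum=s, x=x, exact=float(rng.uniform(15, 40))))
        elif r < 0.7:
            lo = float(rng.uniform(15, 35))
            obs.append(Observation(stratum=s, x=x, lower=lo, upper=lo + 2.0))
        else:
            obs.append(Observation(stratum=s, x=x, upper=float(rng.uniform(18, 35))))
    fp = FreeParameterization(spec)
    packed = _Packed(obs, spec)
    free = fp.to_free(params) + 0.1 * rng.normal(size=fp.n_free)
    _, grad, _ = _negloglik_grad(free, packed, spec, fp, 1e-12)
    for j in range(fp.n_free):
        h = 1e-6 * (1 + abs(free[j]))
        fplus, fminus = free.copy(), free.copy()
        fplus[j] += h
        fminus[j] -= h
        fd = (
            _negloglik_grad(fplus, packed, spec, fp, 1e-12)[0]
            - _negloglik_grad(fminus, packed, spec, fp, 1e-12)[0]
        ) / (2 * h)
        assert grad[j] == pytest.approx(fd, rel=1e-4, abs=1e-5)


class TestFit:
    def test_recovers_empirical_cdf(self, single_stratum_fit):
        res = single_stratum_fit["fit"]
        frame = single_stratum_fit["sim"].frame
        spec = single_stratum_fit["sim"].spec
        assert res.converged
        assert res.params.is_monotone()
        grid = np.linspace(spec.window.lower, spec.window.upper, 150)
        fitted = cdf(grid, spec.strata[0], None, res.params, spec)
        empirical = np.array([(frame.bmi <= g).mean() for g in grid])
        assert float(np.abs(fitted - empirical).max()) < 0.05

    def test_negloglik_not_worse_than_init(self, single_stratum_fit):
        res = single_stratum_fit["fit"]
        obs = single_stratum_fit["obs"]
        spec = single_stratum_fit["sim"].spec
        init = single_stratum_fit["sim"].params
        assert total_negloglik(obs, res.params, spec) <= total_negloglik(
            obs, init, spec
        ) + 1e-8

    def test_vcov_symmetric_psd(self, small_exact_fit):
        v = small_exact_fit["fit"].vcov
        np.testing.assert_allclose(v, v.T, atol=1e-10)
        assert np.min(np.linalg.eigvalsh((v + v.T) / 2)) > -1e-8

    def test_estimates_permutation_invariant(self):
        config = two_cov_config(800, 13)
        obs, sim = exact_observations(config)
        opts = FitOptions(compute_vcov=False, gtol=1e-12)
        r1 = fit(obs, sim.spec, options=opts)
        rng = np.random.default_rng(0)
        r2 = fit([obs[i] for i in rng.permutation(len(obs))], sim.spec, options=opts)
        assert float(np.abs(r1.params.flatten() - r2.params.flatten()).max()) < 1e-5

    def test_empty_stratum_rejected(self, toy_model):
        spec, _ = toy_model
        obs = [Observation(stratum="a", x=(0.0, 0.0), exact=25.0)]
        with pytest.raises(ValueError, match="no observations"):
            fit(obs, spec)

    def test_collinear_design_rejected(self):
        w = SupportWindow(10.0, 50.0, 0.0, np.inf)
        spec = ModelSpec(("s",), ("x1", "x2"), BernsteinBasis(3, w), "logit")
        rng = np.random.default_rng(0)
        obs = [
            Observation(stratum="s", x=(v, 2 * v), exact=float(rng.uniform(18, 35)))
            for v in rng.normal(size=40)
        ]
        with pytest.raises(ValueError, match="rank"):
            fit(obs, spec)

    def test_nan_parameters_rejected(self, toy_model):
        spec, params = toy_model
        bad = ParameterVector(params.theta * np.nan, params.beta)
        obs = Observation(stratum="a", x=(0.0, 0.0), exact=25.0)
        with pytest.raises(FloatingPointError):
            total_negloglik([obs], bad, spec)

    def test_all_four_scales_converge_and_information_orders(self):
        """The same sample coarsened four ways: every likelihood is
        maximizable, and exact measurements are at least as informative
        about beta as WHO categories (smaller standard errors)."""
        config = two_cov_config(1200, 13)
        sim = sd.generate(config)
        fits = {}
        for kind in ("who", "fixed_width", "rounding", "exact"):
            frame = sd.apply_scheme(sim.frame, sd.MeasurementScheme(kind))
            obs = sd.to_observations(frame, config)
            if kind == "who":
                spec = ModelSpec(
                    sim.spec.strata,
                    sim.spec.covariate_names,
                    StepBasis((18.5, 25.0, 30.0), config.window),
                    "logit",
                )
            else:
                spec = sim.spec
            fits[kind] = fit(obs, spec)
            assert fits[kind].converged, kind
            assert np.isfinite(fits[kind].loglik)
        for c in sim.spec.covariate_names:
            assert fits["exact"].beta_se(c) <= fits["who"].beta_se(c)


class TestStepFitEquivalence:
    def test_who_fit_matches_bruteforce_proportional_odds(self):
        """Step-basis MLE on WHO-categorized data equals the categorical
        proportional-odds MLE computed by an independent implementation
        (direct likelihood coding + generic optimizer)."""
        from scipy.optimize import minimize
        from scipy.special import expit

        config = two_cov_config(800, 21)
        obs, sim = exact_observations(config)
        frame = sd.apply_scheme(sim.frame, sd.MeasurementScheme("who"))
        obs_who = sd.to_observations(frame, config)
        spec = ModelSpec(
            sim.spec.strata,
            sim.spec.covariate_names,
            StepBasis((18.5, 25.0, 30.0), config.window),
            "logit",
        )
        ours = fit(obs_who, spec)
        assert ours.converged

        X = np.array([o.x for o in obs])
        S = np.array([sim.spec.strata.index(o.stratum) for o in obs])
        cats = np.array(
            [int(np.searchsorted([18.5, 25, 30], o.exact, side="left")) for o in obs]
        )

        def oracle_nll(p):
            A = p[:6].reshape(2, 3)
            eta = A[S] + (X @ p[6:])[:, None]
            cum = np.concatenate(
                [np.zeros((len(S), 1)), expit(eta), np.ones((len(S), 1))], axis=1
            )
            pr = cum[np.arange(len(S)), cats + 1] - cum[np.arange(len(S)), cats]
            return -np.sum(np.log(np.maximum(pr, 1e-300)))

        p0 = np.concatenate([np.tile([-2.0, 0.0, 2.0], 2), np.zeros(2)])
        sol = minimize(oracle_nll, p0, method="Nelder-Mead",
                       options={"maxiter": 40_000, "xatol": 1e-10, "fatol": 1e-12})
        sol = minimize(oracle_nll, sol.x, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 5000})
        mine = np.concatenate([ours.params.theta.ravel(), ours.params.beta])
        assert float(np.abs(mine - sol.x).max()) < 1e-4

    def test_who_fit_matches_statsmodels_ordered_model(self):
        """Cross-check against the established ordinal regression
        implementation (note its parameterization is F(th_j - x'b), so
        the slope signs flip)."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        config = two_cov_config(800, 22)
        obs, sim = exact_observations(config)
        frame = sd.apply_scheme(sim.frame, sd.MeasurementScheme("who"))
        obs_who = sd.to_observations(frame, config)
        spec = ModelSpec(
            ("Never:Female", "Never:Male"),
            sim.spec.covariate_names,
            StepBasis((18.5, 25.0, 30.0), config.window),
            "logit",
        )
        ours = fit(obs_who, spec)
        # single-stratum comparison: restrict to one sex
        sub = [o for o in obs if o.stratum == "Never:Female"]
        obs_sub = [o for o in obs_who if o.stratum == "Never:Female"]
        spec1 = ModelSpec(
            ("Never:Female",), sim.spec.covariate_names,
            StepBasis((18.5, 25.0, 30.0), config.window), "logit",
        )
        mine = fit(obs_sub, spec1)
        y = np.array(
            [int(np.searchsorted([18.5, 25, 30], o.exact, side="left")) for o in sub]
        )
        X = np.array([o.x for o in sub])
        sm_fit = OrderedModel(y, X, distr="logit").fit(
            method="bfgs", disp=0, gtol=1e-10
        )
        np.testing.assert_allclose(
            mine.params.beta, -sm_fit.params[:2], atol=5e-4
        )
        np.testing.assert_allclose(
            mine.params.theta[0],
            sm_fit.model.transform_threshold_params(sm_fit.params)[1:-1],
            atol=5e-4,
        )


class TestBinaryReduction:
    def test_matches_statsmodels_logit(self):
        config = two_cov_config(1000, 31)
        obs, sim = exact_observations(config)
        res = fit_binary_reduction(obs, 25.0, sim.spec)
        assert res.converged
        y = np.array([float(o.exact <= 25.0) for o in obs])
        X = np.array([o.x for o in obs])
        D = np.column_stack(
            [
                (np.array([o.stratum for o in obs]) == s).astype(float)
                for s in sim.spec.strata
            ]
        )
        oracle = smapi.Logit(y, np.hstack([D, X])).fit(
            disp=0, method="newton", tol=1e-12
        )
        mine = np.concatenate([res.params.theta.ravel(), res.params.beta])
        assert float(np.abs(mine - oracle.params).max()) < 1e-5

    def test_covariate_free_matches_empirical_proportions(self):
        config = sd.GeneratorConfig(
            n=1500, seed=8, strata_probs={"Never:Female": 0.5, "Never:Male": 0.5}
        )
        obs, sim = exact_observations(config)
        res = fit_binary_reduction(obs, 25.0, sim.spec)
        for s in sim.spec.strata:
            sub = [o for o in obs if o.stratum == s]
            prop = np.mean([o.exact <= 25.0 for o in sub])
            fitted = cdf(25.0, s, None, res.params, res.spec)
            assert fitted == pytest.approx(prop, abs=1e-8)

    def test_separation_flagged(self):
        """A cutoff with zero events in a stratum has no finite MLE; the
        fit must come back flagged, not silently wrong."""
        rng = np.random.default_rng(5)
        w = SupportWindow(15.0, 40.0, 0.0, np.inf)
        spec = ModelSpec(("s1", "s2"), (), BernsteinBasis(5, w), "logit")
        obs = [
            Observation(stratum="s1", exact=float(v))
            for v in rng.uniform(20, 35, 200)
        ] + [
            Observation(stratum="s2", exact=float(v))
            for v in rng.uniform(20, 35, 200)  # nobody below 18.5 in s2
        ]
        res = fit_binary_reduction(obs, 18.5, spec)
        assert not res.converged
        assert "divergence" in res.message

    def test_straddling_interval_rejected(self, toy_model):
        spec, _ = toy_model
        obs = [Observation(stratum="a", x=(0.0, 0.0), lower=20.0, upper=30.0)]
        with pytest.raises(ValueError, match="straddle"):
            fit_binary_reduction(obs, 25.0, spec)


def test_floored_probabilities_counted(toy_model):
    spec, params = toy_model
    # interval entirely in the far flat tail has ~zero probability
    obs = [
        Observation(stratum="a", x=(0.0, 0.0), exact=25.0),
        Observation(stratum="a", x=(0.0, 0.0), lower=400.0, upper=401.0),
    ]
    packed = _Packed(obs, spec)
    fp = FreeParameterization(spec)
    _, _, n_floored = _negloglik_grad(
        fp.to_free(params), packed, spec, fp, 1e-12
    )
    assert n_floored == 1
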