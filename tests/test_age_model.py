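"""Tests for the Bayesian logarithmic age model.

Independent oracles: a dense-grid quadrature posterior for the
3-parameter model, and exact leave-one-out refitting for the LOOIC.
"""

import math

import numpy as np
import pytest

from marshequiv import (
    AgeDataset,
    MarshEquivError,
    SamplerConfig,
    fit_age_model,
    fit_null_model,
    loo_compare,
    looic,
    posterior_predictive_check,
    prob_overlap_zero,
)
from marshequiv.age_model import (
    AgeModelPosterior,
    PRIOR_BETA0,
    PRIOR_BETA1,
    _LOG2PI,
)
from marshequiv.study import SITE_AGES_YEARS


def _dataset(seed=0, n=13, beta0=-0.3, beta1=0.25, sigma=0.6):
    rng = np.random.default_rng(seed)
    ages = np.resize(np.array(SITE_AGES_YEARS, dtype=float), n)
    y = beta0 + beta1 * np.log(ages) + rng.normal(0, sigma, size=n)
    return AgeDataset(y=y, age=ages)


# ---------------------------------------------------------------------------
# grid-quadrature oracle (independent of the MCMC code path)


def _grid_oracle(y, age, has_age=True):
    """Posterior means/SDs by brute-force quadrature on a dense grid."""
    lx = np.log(age)
    n = y.size

    def moments(b0_grid, b1_grid, s_grid):
        if has_age:
            mu = b0_grid[:, None, None] + b1_grid[None, :, None] * lx[None, None, :]
            sse = ((y[None, None, :] - mu) ** 2).sum(axis=2)  # (b0, b1)
        else:
            sse = ((y[None, :] - b0_grid[:, None]) ** 2).sum(axis=1)[:, None]
            b1_grid = np.array([0.0])
        lp_b0 = -0.5 * ((b0_grid - PRIOR_BETA0[0]) / PRIOR_BETA0[1]) ** 2
        lp_b1 = (-0.5 * ((b1_grid - PRIOR_BETA1[0]) / PRIOR_BETA1[1]) ** 2
                 if has_age else np.zeros(1))
        logpost = np.empty((b0_grid.size, b1_grid.size, s_grid.size))
        for k, s in enumerate(s_grid):
            logpost[:, :, k] = (-sse / (2 * s * s) - n * math.log(s) - s
                                + lp_b0[:, None] + lp_b1[None, :])
        logpost -= logpost.max()
        wgt = np.exp(logpost)
        wgt /= wgt.sum()
        out = {}
        for name, grid, axis in (("beta0", b0_grid, (1, 2)),
                                 ("beta1", b1_grid, (0, 2)),
                                 ("sigma", s_grid, (0, 1))):
            marg = wgt.sum(axis=axis)
            m = float((grid * marg).sum())
            sd = float(np.sqrt(((grid - m) ** 2 * marg).sum()))
            out[name] = (m, sd)
        return out

    est = moments(np.linspace(-4, 4, 201),
                  np.linspace(-3, 3.5, 201),
                  np.linspace(0.005, 4.0, 240))
    for _ in range(2):  # refine around the located mass twice
        grids = {}
        for p in ("beta0", "beta1", "sigma"):
            m, sd = est[p]
            lo, hi = m - 8 * sd, m + 8 * sd
            if p == "sigma":
                lo = max(lo, 1e-4)
            grids[p] = np.linspace(lo, hi, 220)
        est = moments(grids["beta0"], grids["beta1"], grids["sigma"])
    return est


class TestSampler:
    def test_seeded_runs_are_identical(self, quick_sampler):
        data = _dataset()
        a = fit_age_model(data, quick_sampler)
        b = fit_age_model(data, quick_sampler)
        for p in a.draws:
            np.testing.assert_array_equal(a.draws[p], b.draws[p])

    def test_nonpositive_age_rejected(self):
        with pytest.raises(MarshEquivError):
            AgeDataset(y=np.zeros(3), age=np.array([1.0, 0.0, 2.0]))

    def test_prior_recovery_with_no_data(self):
        """Likelihood switched off -> posterior reproduces the priors."""
        cfg = SamplerConfig(chains=4, iterations=30_000, warmup=3_000,
                            thin=2, seed=1)
        post = fit_age_model(None, cfg)
        b0 = post.draws["beta0"].ravel()
        b1 = post.draws["beta1"].ravel()
        sg = post.draws["sigma"].ravel()
        assert b1.mean() == pytest.approx(0.25, abs=0.05)
        assert b1.std(ddof=1) == pytest.approx(0.75, abs=0.05)
        assert b0.mean() == pytest.approx(0.0, abs=0.07)
        assert b0.std(ddof=1) == pytest.approx(1.0, abs=0.07)
        assert sg.mean() == pytest.approx(1.0, abs=0.07)  # Exp(1)

    def test_grid_oracle_matches_mcmc_at_n13(self):
        data = _dataset(seed=4)
        cfg = SamplerConfig(chains=4, iterations=50_000, warmup=5_000,
                            thin=2, seed=5)
        post = fit_age_model(data, cfg)
        oracle = _grid_oracle(data.y, data.age)
        for p in ("beta0", "beta1", "sigma"):
            m_mcmc = post.draws[p].ravel().mean()
            m_grid, sd_grid = oracle[p]
            assert abs(m_mcmc - m_grid) < 0.02 * sd_grid, p

    def test_parameter_recovery_large_n(self):
        truth = dict(beta0=-0.5, beta1=0.3, sigma=0.2)
        rng = np.random.default_rng(7)
        ages = np.tile(np.arange(2.0, 17.0), 14)[:200]
        y = truth["beta0"] + truth["beta1"] * np.log(ages) \
            + rng.normal(0, truth["sigma"], 200)
        cfg = SamplerConfig(chains=4, iterations=20_000, warmup=4_000,
                            thin=2, seed=8)
        post = fit_age_model(AgeDataset(y=y, age=ages), cfg)
        for p, tv in truth.items():
            d = post.draws[p].ravel()
            assert abs(d.mean() - tv) < 3 * d.std(ddof=1), p

    def test_convergence_diagnostics_reported(self, quick_sampler):
        post = fit_age_model(_dataset(), quick_sampler)
        s = post.summary()
        assert {"rhat", "ess_bulk"} <= set(s.columns)
        assert (s["ess_bulk"] > 100).all()

    def test_null_model_shrinks_towards_prior_mean(self):
        """Constant y with tiny noise: beta0 concentrates near the
        constant, slightly shrunk toward the N(0,1) prior mean."""
        y = np.full(13, 0.8) + np.random.default_rng(3).normal(0, 0.05, 13)
        cfg = SamplerConfig(chains=4, iterations=20_000, warmup=4_000,
                            thin=2, seed=9)
        post = fit_null_model(
            AgeDataset(y=y, age=np.array(SITE_AGES_YEARS, float)), cfg)
        b0 = post.draws["beta0"].ravel()
        assert 0.7 < b0.mean() < 0.8
        # grid oracle for the 2-parameter null model
        oracle = _grid_oracle(y, np.array(SITE_AGES_YEARS, float),
                              has_age=False)
        assert abs(b0.mean() - oracle["beta0"][0]) < 0.05 * oracle["beta0"][1]


class TestLoo:
    def test_same_model_delta_zero(self, quick_sampler):
        post = fit_age_model(_dataset(), quick_sampler)
        comp = loo_compare(post, post)
        assert comp.delta == 0.0

    def test_same_seed_same_looic(self, quick_sampler):
        data = _dataset()
        a = looic(fit_null_model(data, quick_sampler))[0]
        b = looic(fit_null_model(data, quick_sampler))[0]
        assert a == b

    def test_zero_age_signal_keeps_models_close(self):
        rng = np.random.default_rng(12)
        y = rng.normal(0.0, 0.4, 13)
        data = AgeDataset(y=y, age=np.array(SITE_AGES_YEARS, float))
        cfg = SamplerConfig(chains=4, iterations=16_000, warmup=3_000,
                            thin=2, seed=13)
        comp = loo_compare(fit_age_model(data, cfg),
                           fit_null_model(data, cfg))
        assert abs(comp.delta) < 4.0

    def test_psis_matches_exact_refit_loo(self):
        """PSIS-LOO agrees with brute-force 13-refit leave-one-out."""
        data = _dataset(seed=21)
        cfg = SamplerConfig(chains=4, iterations=20_000, warmup=4_000,
                            thin=2, seed=22)
        post = fit_age_model(data, cfg)
        psis_looic = looic(post)[0]

        elpd = 0.0
        for i in range(data.y.size):
            keep = np.arange(data.y.size) != i
            sub = AgeDataset(y=data.y[keep], age=data.age[keep])
            p_i = fit_age_model(sub, cfg)
            mu = (p_i.draws["beta0"].ravel()
                  + p_i.draws["beta1"].ravel() * data.log_age[i])
            sg = p_i.draws["sigma"].ravel()
            ll = (-0.5 * ((data.y[i] - mu) / sg) ** 2
                  - np.log(sg) - 0.5 * _LOG2PI)
            m = ll.max()
            elpd += m + math.log(np.exp(ll - m).mean())
        exact_looic = -2.0 * elpd
        assert abs(psis_looic - exact_looic) < 1.0


class TestPosteriorPredictive:
    def test_calibration_under_the_model(self):
        """Data generated from the model: observed mean falls inside the
        central 95% of replicated means in nearly all runs."""
        cfg = SamplerConfig(chains=4, iterations=6_000, warmup=1_000,
                            thin=2, seed=0)
        hits = 0
        n_runs = 20
        for s in range(n_runs):
            data = _dataset(seed=300 + s)
            post = fit_age_model(data, cfg)
            ppc = posterior_predictive_check(post, n_reps=500, seed=s)
            if 0.025 < ppc["p_mean"] < 0.975:
                hits += 1
        assert hits >= n_runs - 3

    def test_degenerate_posterior_collapses_to_sigma_draws(self):
        data = _dataset(seed=2)
        draws = {"beta0": np.zeros((2, 100)),
                 "beta1": np.zeros((2, 100)),
                 "sigma": np.full((2, 100), 0.5)}
        post = AgeModelPosterior(draws=draws, log_lik=None, data=data,
                                 has_age_term=True, config=SamplerConfig())
        ppc = posterior_predictive_check(post, n_reps=2000, seed=1)
        # replicated SDs estimate the fixed sigma = 0.5
        assert np.mean(ppc["rep_sd"]) == pytest.approx(0.5, rel=0.05)

    def test_heavy_tailed_data_flagged(self, quick_sampler):
        clean = _dataset(seed=6, sigma=0.2)
        post = fit_age_model(clean, quick_sampler)
        spiked = AgeDataset(y=np.r_[clean.y[:-1], 8.0], age=clean.age)
        ppc = posterior_predictive_check(post, data=spiked, n_reps=1000,
                                         seed=2)
        assert ppc["p_sd"] > 0.99  # observed SD in the extreme upper tail


class TestOverlapZero:
    def test_all_positive_draws(self):
        draws = {"beta0": np.zeros((2, 10)), "sigma": np.ones((2, 10)),
                 "beta1": np.abs(np.random.default_rng(0).normal(1, .1, (2, 10)))}
        post = AgeModelPosterior(draws=draws, log_lik=None, data=None,
                                 has_age_term=True, config=SamplerConfig())
        assert prob_overlap_zero(post) == 0.0

    def test_symmetric_draws_near_half(self):
        rng = np.random.default_rng(5)
        draws = {"beta0": np.zeros((2, 5000)), "sigma": np.ones((2, 5000)),
                 "beta1": rng.normal(0, 1, (2, 5000))}
        post = AgeModelPosterior(draws=draws, log_lik=None, data=None,
                                 has_age_term=True, config=SamplerConfig())
        assert prob_overlap_zero(post) == pytest.approx(0.5, abs=0.03)

    def test_null_model_has_no_age_term(self, quick_sampler):
        post = fit_null_model(_dataset(), quick_sampler)
        with pytest.raises(MarshEquivError):
            prob_overlap_zero(post)
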