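"""Bayesian mixing model: likelihood geometry, sampler correctness, diagnostics.

The independent oracle for the sampler is a fine-grid numerical posterior on
two-source/one-isotope problems, where the diet proportion is a scalar and
the posterior can be integrated by quadrature.
"""

import numpy as np
import pytest

import arviz as az

from isofoodweb.mixing import (
    MeasurementError,
    MixingModelConfig,
    PosteriorDraws,
    SourceSet,
    TrophicEnrichment,
    effective_sample_size,
    fit_simm,
    gelman_rubin,
    posterior_summary,
)
from isofoodweb.synthetic import generate_consumer_from_mixture


def small_config(**kw):
    defaults = dict(isotopes=("d13C",), chains=3, iterations=30_000,
                    burn_in=15_000, thinning=5, seed=42)
    defaults.update(kw)
    return MixingModelConfig(**defaults)


def grid_posterior_p1(X, sources, tef, meas, n_grid=2001):
    """Quadrature posterior for the first source's proportion (K=2, J=1)."""
    p1 = np.linspace(1e-6, 1 - 1e-6, n_grid)
    p = np.stack([p1, 1 - p1], axis=1)
    m = p @ (sources.mu[:, 0] + tef.delta[0])
    v = (p ** 2) @ (sources.sigma[:, 0] ** 2 + tef.sd[0] ** 2) + meas.sd[0] ** 2
    x = np.asarray(X).ravel()
    ll = np.sum(-0.5 * np.log(2 * np.pi * v[:, None])
                - (x[None, :] - m[:, None]) ** 2 / (2 * v[:, None]), axis=1)
    w = np.exp(ll - ll.max())
    return p1, w / w.sum()


def total_variation(draws, grid, weights, bins=40):
    edges = np.linspace(0, 1, bins + 1)
    emp, _ = np.histogram(draws, bins=edges)
    emp = emp / emp.sum()
    idx = np.clip(np.digitize(grid, edges) - 1, 0, bins - 1)
    theory = np.bincount(idx, weights=weights, minlength=bins)
    return 0.5 * np.abs(emp - theory).sum()


class TestFitSimm:
    def test_single_source_posterior_degenerate(self, two_source_1d):
        sources, tef, meas = two_source_1d
        one = SourceSet(("only",), ("d13C",), sources.mu[:1], sources.sigma[:1])
        res = fit_simm(np.array([[-29.5]]), one, tef, meas, small_config())
        assert np.all(res.draws.p == 1.0)
        assert res.summary.loc["only", "mean"] == 1.0

    def test_consumer_at_source_vertex_concentrates(self):
        sources = SourceSet(("a", "b"), ("d13C",),
                            np.array([[-30.0], [-10.0]]),
                            np.array([[0.1], [0.1]]))
        tef = TrophicEnrichment(("d13C",), np.array([1.0]), np.array([0.0]))
        meas = MeasurementError(("d13C",), np.array([0.1]))
        X = np.full((15, 1), -29.0)   # exactly the TEF-shifted mean of a
        res = fit_simm(X, sources, tef, meas, small_config())
        assert res.summary.loc["a", "mean"] > 0.9

    def test_mcmc_marginal_matches_grid_posterior(self, two_source_1d):
        """Sampler vs quadrature on scalar problems: TV below 0.05."""
        sources, tef, meas = two_source_1d
        rng = np.random.default_rng(7)
        X = rng.normal(-24.0, 1.0, size=(12, 1))
        res = fit_simm(X, sources, tef, meas, small_config())
        grid, w = grid_posterior_p1(X, sources, tef, meas)
        tv = total_variation(res.draws.p[:, 0], grid, w)
        assert tv < 0.05

    def test_every_draw_on_simplex(self, three_sources_2d):
        sources, tef, meas = three_sources_2d
        X = generate_consumer_from_mixture(
            sources, [0.5, 0.3, 0.2], tef, meas, n=10, seed=3)
        res = fit_simm(X, sources, tef, meas,
                       small_config(isotopes=("d13C", "d15N")))
        p = res.draws.p
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)

    def test_source_reordering_invariance(self, three_sources_2d):
        sources, tef, meas = three_sources_2d
        X = generate_consumer_from_mixture(
            sources, [0.6, 0.3, 0.1], tef, meas, n=15, seed=5)
        cfg = small_config(isotopes=("d13C", "d15N"))
        res = fit_simm(X, sources, tef, meas, cfg)
        rev = SourceSet(sources.names[::-1], sources.isotopes,
                        sources.mu[::-1], sources.sigma[::-1])
        res_rev = fit_simm(X, rev, tef, meas, cfg)
        for name in sources.names:
            assert res.summary.loc[name, "mean"] == pytest.approx(
                res_rev.summary.loc[name, "mean"], abs=0.03)

    def test_equal_mixture_of_symmetric_sources_gives_uniform_mean(self):
        sources = SourceSet(("lo", "hi"), ("d13C",),
                            np.array([[-25.0], [-15.0]]),
                            np.array([[1.0], [1.0]]))
        tef = TrophicEnrichment(("d13C",), np.array([0.0]), np.array([0.0]))
        meas = MeasurementError(("d13C",), np.array([0.05]))
        X = np.array([[-20.0]])    # exactly the midpoint
        res = fit_simm(X, sources, tef, meas, small_config())
        assert res.summary.loc["lo", "mean"] == pytest.approx(0.5, abs=0.03)

    def test_prior_only_recovers_dirichlet_moments(self):
        K, alpha = 4, 1.0
        sources = SourceSet(tuple("abcd"), ("d13C",),
                            np.zeros((K, 1)), np.ones((K, 1)))
        tef = TrophicEnrichment(("d13C",), np.array([0.0]), np.array([0.0]))
        meas = MeasurementError(("d13C",), np.array([0.1]))
        res = fit_simm(np.array([[0.0]]), sources, tef, meas,
                       small_config(alpha=alpha), prior_only=True)
        p = res.draws.p
        np.testing.assert_allclose(p.mean(axis=0), 1 / K, atol=0.02)
        # Dirichlet(1) marginals are Beta(1, K-1): var = (K-1)/(K^2 (K+1))
        expected_var = (K - 1) / (K ** 2 * (K + 1))
        np.testing.assert_allclose(p.var(axis=0), expected_var, atol=0.005)

    def test_parameter_recovery_covers_truth(self, three_sources_2d):
        sources, tef, meas = three_sources_2d
        p_true = np.array([0.7, 0.2, 0.1])
        X = generate_consumer_from_mixture(sources, p_true, tef, meas,
                                           n=20, seed=11)
        res = fit_simm(X, sources, tef, meas,
                       small_config(isotopes=("d13C", "d15N")), ci_level=0.9)
        for k, name in enumerate(sources.names):
            lo = res.summary.loc[name, "ci_low"]
            hi = res.summary.loc[name, "ci_high"]
            assert lo - 0.05 <= p_true[k] <= hi + 0.05

    def test_isotope_mismatch_raises(self, two_source_1d):
        sources, tef, meas = two_source_1d
        cfg = small_config(isotopes=("d13C", "d15N"))
        with pytest.raises(ValueError, match="isotope"):
            fit_simm(np.zeros((3, 2)), sources, tef, meas, cfg)

    def test_residual_error_absorbs_overdispersion(self, two_source_1d):
        sources, tef, meas = two_source_1d
        rng = np.random.default_rng(2)
        X = rng.normal(-20.0, 4.0, size=(20, 1))   # wider than any source
        res = fit_simm(X, sources, tef, meas,
                       small_config(residual_error=True))
        assert res.draws.resid_sd is not None
        assert np.median(res.draws.resid_sd) > 1.0


class TestGelmanRubin:
    def test_iid_chains_near_one(self, rng):
        chains = rng.normal(size=(3, 500, 2))
        r = gelman_rubin(chains)
        assert np.all((r >= 0.99) & (r <= 1.05))

    def test_disjoint_chains_flagged(self, rng):
        a = rng.normal(0, 1, size=(1, 400, 1))
        b = rng.normal(50, 1, size=(1, 400, 1))
        r = gelman_rubin(np.concatenate([a, b]))
        assert r[0] > 1.1

    def test_constant_chains_return_one(self):
        chains = np.ones((3, 100, 1))
        assert gelman_rubin(chains)[0] == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100, 1)))

    def test_matches_arviz_split_rhat(self, rng):
        chains = rng.normal(size=(4, 300)) + np.linspace(0, 1, 4)[:, None]
        ours = gelman_rubin(chains[:, :, None])[0]
        theirs = float(az.rhat(az.convert_to_dataset(chains))["x"])
        assert ours == pytest.approx(theirs, abs=0.02)


class TestPosteriorSummary:
    def _draws(self, p):
        p = np.asarray(p, dtype=float)
        return PosteriorDraws(sources=tuple(f"s{i}" for i in range(p.shape[1])),
                              p=p, chain=np.zeros(p.shape[0], dtype=int))

    def test_degenerate_draws_at_vertex(self):
        p = np.tile([1.0, 0.0, 0.0], (50, 1))
        s = posterior_summary(self._draws(p), level=0.9)
        assert s["mean"].tolist() == [1.0, 0.0, 0.0]
        assert (s["ci_high"] - s["ci_low"]).abs().max() == 0.0

    def test_symmetric_two_source_posterior(self, rng):
        x = rng.beta(5, 5, size=4000)
        p = np.stack([x, 1 - x], axis=1)
        s = posterior_summary(self._draws(p))
        assert s["mean"].iloc[0] == pytest.approx(0.5, abs=0.02)

    def test_interval_nesting(self, rng):
        x = rng.beta(2, 3, size=3000)
        p = np.stack([x, 1 - x], axis=1)
        s50 = posterior_summary(self._draws(p), level=0.5)
        s95 = posterior_summary(self._draws(p), level=0.95)
        assert (s95["ci_low"] <= s50["ci_low"]).all()
        assert (s95["ci_high"] >= s50["ci_high"]).all()

    def test_level_validation(self, rng):
        p = np.stack([np.full(10, 0.5), np.full(10, 0.5)], axis=1)
        with pytest.raises(ValueError):
            posterior_summary(self._draws(p), level=1.5)

    def test_means_sum_to_one(self, rng):
        x = rng.dirichlet([1, 2, 3], size=2000)
        s = posterior_summary(self._draws(x))
        assert s["mean"].sum() == pytest.approx(1.0, abs=1e-12)


class TestEffectiveSampleSize:
    def test_iid_draws_give_near_nominal_ess(self, rng):
        chains = rng.normal(size=(3, 400, 1))
        ess = effective_sample_size(chains)[0]
        assert ess > 0.5 * 3 * 400

    def test_correlated_draws_give_smaller_ess(self, rng):
        T = 400
        chains = np.empty((3, T, 1))
        for c in range(3):
            x = 0.0
            for t in range(T):
                x = 0.95 * x + rng.normal(scale=0.3)
                chains[c, t, 0] = x
        ess = effective_sample_size(chains)[0]
        assert ess < 0.3 * 3 * T
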