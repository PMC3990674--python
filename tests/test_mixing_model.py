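"""Mixing model: likelihood algebra, sampler behaviour, oracle agreement."""

import dataclasses

import numpy as np
import pytest

from isoniche.errors import InvalidInputError
from isoniche.isotope_io import SourceDistribution
from isoniche.mixing_model import (MCMCSettings, MixingModelSpec, apply_tdf,
                                   fit, log_likelihood, tdf_sensitivity,
                                   with_tdf)
from isoniche.synthetic_data import ScenarioConfig, generate_sources


def src(cat, mu, omega, tdf=(0.0, 0.0), tdf_sd=(0.0, 0.0)):
    return SourceDistribution(cat, mu, omega, tdf, tdf_sd)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class TestLogLikelihood:
    def test_standard_normal_at_mode(self):
        # K=1, consumer at mu+lambda, total variance 1 per isotope
        s = [src("OC", (-24.0, 4.0), (np.sqrt(0.5), np.sqrt(0.5)),
                 tdf=(2.1, 2.7), tdf_sd=(0.5, 0.5))]
        spec = MixingModelSpec(consumers=[[-21.9, 6.7]], sources=s)
        ll = log_likelihood(np.array([1.0]), np.sqrt(0.25), spec)
        assert ll == pytest.approx(2 * (-0.5 * np.log(2 * np.pi)))

    def test_duplicating_consumers_doubles_loglik(self, rng):
        s = [src("OC", (-24.0, 4.0), (0.5, 0.5)),
             src("AR", (-20.0, 8.0), (0.5, 0.5))]
        x = rng.normal([-22, 6], 1.0, size=(5, 2))
        spec1 = MixingModelSpec(consumers=x, sources=s)
        spec2 = MixingModelSpec(consumers=np.vstack([x, x]), sources=s)
        p = np.array([0.3, 0.7])
        assert log_likelihood(p, [0.3, 0.4], spec2) == \
            pytest.approx(2 * log_likelihood(p, [0.3, 0.4], spec1))

    def test_matches_naive_reimplementation(self, rng):
        """Per-term scalar oracle agrees to 1e-10 on random inputs."""
        K, n = 4, 6
        sources = [src(f"S{k}", tuple(rng.normal(-22, 3, 2)),
                       tuple(rng.uniform(0.1, 1, 2)),
                       tdf=(2.1, 2.7), tdf_sd=(0.08, 0.5)) for k in range(K)]
        x = rng.normal(-20, 2, size=(n, 2))
        spec = MixingModelSpec(consumers=x, sources=sources)
        p = rng.dirichlet(np.ones(K))
        sigma = rng.uniform(0.1, 1, 2)
        # naive: explicit loops over consumers, isotopes, sources
        total = 0.0
        for i in range(n):
            for j in range(2):
                m = sum(p[k] * (sources[k].mu[j] + sources[k].tdf_mu[j])
                        for k in range(K))
                v = sum(p[k] ** 2 * (sources[k].omega[j] ** 2
                                     + sources[k].tdf_sd[j] ** 2)
                        for k in range(K)) + sigma[j] ** 2
                total += -0.5 * np.log(2 * np.pi * v) - (x[i, j] - m) ** 2 / (2 * v)
        assert log_likelihood(p, sigma, spec) == pytest.approx(total, abs=1e-10)

    def test_zero_variance_off_mean_is_minus_inf(self):
        s = [src("OC", (-24.0,), (0.0,))]
        spec = MixingModelSpec(consumers=[[-23.0]], sources=s)
        assert log_likelihood(np.array([1.0]), 0.0, spec) == -np.inf

    def test_rejects_off_simplex(self):
        s = [src("OC", (-24.0,), (0.5,)), src("AR", (-20.0,), (0.5,))]
        spec = MixingModelSpec(consumers=[[-22.0]], sources=s)
        with pytest.raises(InvalidInputError):
            log_likelihood(np.array([0.8, 0.8]), 0.3, spec)


# ---------------------------------------------------------------------------
# TDF application
# ---------------------------------------------------------------------------

class TestApplyTdf:
    def test_shift_and_quadrature(self):
        s = [src("OC", (-24.0, 4.0), (0.3, 0.3), tdf=(2.1, 2.7),
                 tdf_sd=(0.5, 0.5))]
        out = apply_tdf(s)
        assert out.loc[0, "mean_d13c"] == pytest.approx(-21.9)
        assert out.loc[0, "sd_d13c"] == pytest.approx(np.sqrt(0.34))

    def test_zero_tdf_is_identity(self):
        s = [src("OC", (-24.0, 4.0), (0.3, 0.4))]
        out = apply_tdf(s)
        assert out.loc[0, "mean_d13c"] == -24.0
        assert out.loc[0, "sd_d15n"] == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

class TestFit:
    def test_single_source_posterior_is_point_mass(self, fast_mcmc):
        s = [src("OC", (-24.0, 4.0), (0.5, 0.5))]
        spec = MixingModelSpec(consumers=[[-23.8, 4.1]], sources=s,
                               mcmc=fast_mcmc)
        est = fit(spec, keep_draws=True)
        assert np.allclose(est.draws, 1.0)
        assert est.mean[0] == 1.0

    def test_draws_on_simplex(self, fast_mcmc, rng):
        sources = generate_sources(ScenarioConfig())
        x = rng.normal([-22.5, 6.5], 0.5, size=(2, 2))
        est = fit(MixingModelSpec(consumers=x, sources=sources,
                                  mcmc=fast_mcmc), keep_draws=True)
        assert np.all(est.draws >= 0)
        assert np.allclose(est.draws.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(est.q025 <= est.q975)
        assert est.mean.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_source_grid_posterior_oracle(self):
        """K=2 on one isotope: MCMC mean within 0.02 of quadrature truth."""
        s = [src("A", (0.0,), (0.01,)), src("B", (10.0,), (0.01,))]
        x = np.full((20, 1), 5.0)
        sigma = 1.0
        spec = MixingModelSpec(
            consumers=x, sources=s, sigma_fixed=[sigma],
            mcmc=MCMCSettings(burn_in=4000, n_samples=16000, thin=4, seed=5))
        est = fit(spec)
        # trapezoid-integrated exact posterior over p in [0, 1]
        grid = np.linspace(1e-6, 1 - 1e-6, 20001)
        ll = np.array([
            sum(-0.5 * np.log(2 * np.pi * v) - (xi - m) ** 2 / (2 * v)
                for xi in x[:, 0]
                for m, v in [(10 * (1 - g),
                              g ** 2 * 1e-4 + (1 - g) ** 2 * 1e-4 + sigma ** 2)])
            for g in grid])
        w = np.exp(ll - ll.max())
        mean_a = np.trapezoid(grid * w, grid) / np.trapezoid(w, grid)
        assert abs(est.mean[0] - mean_a) < 0.02
        assert est.mean[0] == pytest.approx(0.5, abs=0.02)

    def test_consumer_at_source_mean_tiny_sds(self, fast_mcmc):
        """Flat prior, one consumer exactly on a TDF-shifted source."""
        # sources in general position: no other mixture reproduces B's mean
        sources = [src(c, mu, (0.05, 0.05), tdf=(1.0, 1.0))
                   for c, mu in zip("ABCD", [(-24.0, 3.0), (-20.0, 9.0),
                                             (-16.0, 4.0), (-12.0, 8.0)])]
        x = [[-19.0, 10.0]]  # source B shifted by TDF (1, 1)
        mc = dataclasses.replace(fast_mcmc, burn_in=4000, n_samples=16000)
        est = fit(MixingModelSpec(consumers=x, sources=sources,
                                  sigma_fixed=[0.05, 0.05], mcmc=mc))
        assert est.mean[1] > 0.9

    def test_permutation_equivariance(self, fast_mcmc):
        """Relabelling sources permutes the posterior (up to MC error)."""
        sources = [src(c, (mu, mu2), (0.4, 0.4))
                   for c, mu, mu2 in zip("ABC", (-24.0, -21.0, -18.0),
                                         (3.0, 7.0, 5.0))]
        x = [[-21.5, 5.2], [-20.8, 5.6]]
        est1 = fit(MixingModelSpec(consumers=x, sources=sources, mcmc=fast_mcmc))
        perm = [2, 0, 1]
        est2 = fit(MixingModelSpec(consumers=x,
                                   sources=[sources[i] for i in perm],
                                   mcmc=fast_mcmc))
        for k_new, k_old in enumerate(perm):
            assert est2.mean[k_new] == pytest.approx(est1.mean[k_old], abs=0.03)


# ---------------------------------------------------------------------------
# TDF sensitivity
# ---------------------------------------------------------------------------

class TestSensitivity:
    def test_baseline_only_grid_is_zero_change(self, fast_mcmc):
        sources = generate_sources(ScenarioConfig())
        x = [[-22.5, 6.5], [-22.2, 6.8]]
        spec = MixingModelSpec(consumers=x, sources=sources, mcmc=fast_mcmc)
        sens = tdf_sensitivity(spec, [2.1], [2.7])
        assert (sens["is_baseline"]).all()
        assert np.allclose(sens["abs_change_pp"], 0.0)

    def test_baseline_must_be_in_grid(self, fast_mcmc):
        sources = generate_sources(ScenarioConfig())
        spec = MixingModelSpec(consumers=[[-22.5, 6.5]], sources=sources,
                               mcmc=fast_mcmc)
        with pytest.raises(InvalidInputError):
            tdf_sensitivity(spec, [1.6, 2.6], [2.2, 2.7, 3.2])

    def test_symmetric_geometry_symmetric_changes(self):
        """Mirror-image sources respond symmetrically to a TDF shift."""
        sources = [src("A", (-2.0,), (0.3,), tdf=(0.0,), tdf_sd=(0.1,)),
                   src("B", (2.0,), (0.3,), tdf=(0.0,), tdf_sd=(0.1,))]
        x = np.zeros((10, 1))
        mc = MCMCSettings(burn_in=3000, n_samples=12000, thin=4, seed=9)
        spec = MixingModelSpec(consumers=x, sources=sources,
                               sigma_fixed=[0.5], mcmc=mc)
        sens = tdf_sensitivity(spec, [-0.5, 0.0, 0.5], [0.0])
        off = sens[~sens.is_baseline]
        up = off[off.tdf_c == 0.5].set_index("category")["abs_change_pp"]
        dn = off[off.tdf_c == -0.5].set_index("category")["abs_change_pp"]
        # shifting +0.5 moves mass to A exactly as -0.5 moves it to B
        assert up["A"] == pytest.approx(dn["B"], abs=1.5)
        assert up["B"] == pytest.approx(dn["A"], abs=1.5)

    def test_with_tdf_replaces_values(self):
        sources = generate_sources(ScenarioConfig())
        out = with_tdf(sources, (1.6, 2.7))
        assert all(s.tdf_mu == (1.6, 2.7) for s in out)
        assert all(s.tdf_sd == (0.08, 0.5) for s in out)
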