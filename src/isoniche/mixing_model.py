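"""SIAR-class Bayesian stable-isotope mixing model.

Consumer isotope values are modelled as proportion-weighted mixtures of K
prey source distributions shifted by trophic discrimination factors (TDFs):
for consumer i and isotope j,

    X_ij ~ Normal( sum_k p_k (mu_jk + lambda_j),
                   sum_k p_k^2 (omega_jk^2 + tau_j^2) + sigma_j^2 )

with diet proportions p on the simplex under a Dirichlet prior and a
per-isotope residual SD sigma_j under a Uniform(0, sigma_max) prior.  TDF
uncertainty (tau) enters the variance term rather than being resampled per
draw, matching the mean/variance composition of the SIAR formulation and
keeping the model amenable to an exact grid-posterior cross-check.

Sampling is random-walk Metropolis on log-ratio-transformed proportions
(K-1 free coordinates, softmax inverse) with adaptive step scaling during
burn-in, run as >= 2 independent chains and gated on split-R-hat <= 1.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConvergenceError, InvalidInputError
from .isotope_io import SourceDistribution

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MCMCSettings:
    """Chain configuration.  ``n_samples`` counts post-burn-in iterations per
    chain; every ``thin``-th is retained.  On split-R-hat > ``rhat_tol`` the
    sampler extends each chain up to ``max_extensions`` times (doubling the
    retained sample each time) before failing."""

    n_chains: int = 2
    burn_in: int = 10_000
    n_samples: int = 40_000
    thin: int = 10
    seed: int = 0
    rhat_tol: float = 1.05
    max_extensions: int = 2

    def validate(self):
        if self.n_chains < 2:
            raise InvalidInputError("need >= 2 chains for split-R-hat")
        if min(self.burn_in, self.n_samples, self.thin) < 1:
            raise InvalidInputError("burn_in, n_samples and thin must be >= 1")


@dataclass
class MixingModelSpec:
    """One mixing-model problem: consumers, sources, priors, chains.

    ``consumers`` is (n, J) with J isotopes in the order of the source
    tuples (d13c, d15n for the standard two-isotope case; J = 1 inputs are
    accepted for reduced problems).  ``sigma_fixed`` pins the residual SDs
    instead of sampling them (used by oracle cross-checks).
    """

    consumers: np.ndarray
    sources: Sequence[SourceDistribution]
    prior_alpha: np.ndarray | None = None
    sigma_max: float = 20.0
    sigma_fixed: np.ndarray | None = None
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    # arrays built in __post_init__
    mu: np.ndarray = field(init=False, repr=False)      # (J, K) TDF-shifted means
    var_src: np.ndarray = field(init=False, repr=False)  # (J, K) omega^2 + tau^2

    def __post_init__(self):
        x = np.atleast_2d(np.asarray(self.consumers, dtype=float))
        if x.shape[0] == 0:
            raise InvalidInputError("need at least one consumer")
        self.consumers = x
        k = len(self.sources)
        if k < 1:
            raise InvalidInputError("need at least one source")
        j = x.shape[1]
        mu = np.array([s.mu[:j] for s in self.sources], dtype=float).T
        om = np.array([s.omega[:j] for s in self.sources], dtype=float).T
        lam = np.asarray(self.sources[0].tdf_mu[:j], dtype=float)
        tau = np.asarray(self.sources[0].tdf_sd[:j], dtype=float)
        self.mu = mu + lam[:, None]
        self.var_src = om ** 2 + tau[:, None] ** 2
        if self.prior_alpha is None:
            self.prior_alpha = np.ones(k)
        else:
            self.prior_alpha = np.asarray(self.prior_alpha, dtype=float)
            if self.prior_alpha.shape != (k,) or (self.prior_alpha <= 0).any():
                raise InvalidInputError("prior_alpha must be a positive K-vector")
        if self.sigma_fixed is not None:
            self.sigma_fixed = np.broadcast_to(
                np.asarray(self.sigma_fixed, dtype=float), (j,)).copy()
            if (self.sigma_fixed < 0).any():
                raise InvalidInputError("sigma_fixed must be >= 0")

    @property
    def n_isotopes(self) -> int:
        return self.consumers.shape[1]

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def categories(self) -> list[str]:
        return [s.category for s in self.sources]


@dataclass
class DietEstimate:
    """Posterior summary of one territory-year's diet proportions."""

    key: tuple | str | None
    categories: list[str]
    mean: np.ndarray
    sd: np.ndarray
    q025: np.ndarray
    q975: np.ndarray
    sigma_mean: np.ndarray
    rhat: pd.Series
    n_effective: pd.Series
    draws: np.ndarray | None = None        # (n_draws, K) pooled, optional
    sigma_draws: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"category": self.categories, "mean": self.mean,
                             "sd": self.sd, "q025": self.q025, "q975": self.q975})


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def log_likelihood(p: np.ndarray, sigma: np.ndarray, spec: MixingModelSpec) -> float:
    """Gaussian mixing-model log likelihood summed over consumers/isotopes.

    A zero total variance on any isotope yields -inf when any consumer sits
    off the mixture mean on that isotope; exact-at-the-mean point masses
    contribute nothing (their degenerate density is treated as 1).
    """
    p = np.asarray(p, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (spec.n_isotopes,))
    if p.shape != (spec.n_sources,):
        raise InvalidInputError("p has wrong length")
    if (p < -1e-12).any() or abs(p.sum() - 1) > 1e-9:
        raise InvalidInputError("p must lie on the simplex")
    if (sigma < 0).any():
        raise InvalidInputError("sigma must be >= 0")
    mean = spec.mu @ p                                 # (J,)
    var = spec.var_src @ (p ** 2) + sigma ** 2          # (J,)
    resid2 = (spec.consumers - mean) ** 2               # (n, J)
    n = spec.consumers.shape[0]
    total = 0.0
    for j in range(spec.n_isotopes):
        if var[j] <= 0.0:
            if resid2[:, j].max(initial=0.0) > 0.0:
                return -np.inf
            continue
        total += -0.5 * n * (_LOG2PI + np.log(var[j])) \
                 - resid2[:, j].sum() / (2.0 * var[j])
    return float(total)


def apply_tdf(sources: Sequence[SourceDistribution]) -> pd.DataFrame:
    """TDF-shifted source table: mean mu + lambda, SD sqrt(omega^2 + tau^2)."""
    rows = []
    for s in sources:
        rows.append({
            "category": s.category,
            "mean_d13c": s.mu[0] + s.tdf_mu[0],
            "mean_d15n": s.mu[1] + s.tdf_mu[1],
            "sd_d13c": float(np.hypot(s.omega[0], s.tdf_sd[0])),
            "sd_d15n": float(np.hypot(s.omega[1], s.tdf_sd[1]))})
    return pd.DataFrame(rows)


def with_tdf(sources: Sequence[SourceDistribution],
             tdf_mu: tuple[float, float],
             tdf_sd: tuple[float, float] | None = None) -> list[SourceDistribution]:
    """Copies of ``sources`` with a different TDF (SDs kept unless given)."""
    return [replace(s, tdf_mu=tuple(tdf_mu),
                    tdf_sd=tuple(tdf_sd) if tdf_sd is not None else s.tdf_sd)
            for s in sources]


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _alr_forward(p: np.ndarray) -> np.ndarray:
    return np.log(p[:-1]) - np.log(p[-1])


def _alr_inverse(z: np.ndarray) -> np.ndarray:
    ez = np.exp(np.concatenate([z, [0.0]]) - max(np.max(z, initial=0.0), 0.0))
    return ez / ez.sum()


def _log_posterior(z, sigma, spec, alpha):
    """Unnormalized log posterior on the (z, sigma) chart.

    Dirichlet(alpha) prior on p plus the log-ratio Jacobian sum_k log p_k;
    sigma has a flat prior on (0, sigma_max) enforced by the caller.
    """
    p = _alr_inverse(z)
    if (p <= 0).any():  # underflow at the simplex boundary
        return -np.inf, p
    lp = log_likelihood(p, sigma, spec)
    if not np.isfinite(lp):
        return -np.inf, p
    logp = np.log(p)
    lp += float(((alpha - 1.0) * logp).sum() + logp.sum())
    return lp, p


def _run_chain(spec: MixingModelSpec, rng: np.random.Generator,
               n_keep_iter: int):
    """One adaptive RWM chain; returns (p draws, sigma draws) thinned.

    The joint state is theta = (z, sigma).  During burn-in the proposal
    covariance adapts to the empirical covariance of the chain (scaled by
    the classic 2.38^2/d factor) with a scalar multiplier tuned towards a
    ~25% acceptance rate; adaptation freezes when sampling starts.
    """
    k = spec.n_sources
    j = spec.n_isotopes
    mc = spec.mcmc
    alpha = spec.prior_alpha
    am1 = alpha - 1.0
    sample_sigma = spec.sigma_fixed is None
    sigma_fixed = None if sample_sigma else spec.sigma_fixed

    # hot-path views
    x = spec.consumers
    n_cons = x.shape[0]
    mu = spec.mu                  # (J, K)
    var_src = spec.var_src        # (J, K)
    smax = spec.sigma_max

    def logpost(theta):
        z = theta[:k - 1]
        sig = theta[k - 1:] if sample_sigma else sigma_fixed
        if sample_sigma and ((sig <= 0.0).any() or (sig >= smax).any()):
            return -np.inf
        ez = np.exp(np.concatenate([z, [0.0]]) - max(z.max(initial=0.0), 0.0))
        p = ez / ez.sum()
        if (p <= 0.0).any():
            return -np.inf
        mean = mu @ p
        var = var_src @ (p * p) + sig * sig
        if (var <= 0.0).any():
            return -np.inf
        resid2 = (x - mean) ** 2
        ll = -0.5 * (n_cons * (_LOG2PI + np.log(var)).sum()
                     + (resid2 / var).sum(axis=0) @ np.ones(j))
        logp = np.log(p)
        return float(ll + (am1 * logp).sum() + logp.sum())

    d = (k - 1) + (j if sample_sigma else 0)
    theta = np.concatenate([np.zeros(k - 1),
                            np.full(j, min(1.0, smax / 2)) if sample_sigma else []])
    lp = logpost(theta)

    if d == 0:  # K = 1 with fixed sigma: posterior is a point mass
        n_keep = n_keep_iter // mc.thin
        return (np.ones((n_keep, 1)),
                np.tile(sigma_fixed, (n_keep, 1)))

    scale = 0.5
    chol = np.eye(d)
    opt = 2.38 ** 2 / d
    # running moments for adaptive covariance
    run_mean = theta.copy()
    run_cov = np.eye(d) * 0.1
    n_adapt = 0

    n_total = mc.burn_in + n_keep_iter
    n_keep = n_keep_iter // mc.thin
    kept_p = np.empty((n_keep, k))
    kept_s = np.empty((n_keep, j))
    acc = 0
    i_keep = 0
    normals = None
    for it in range(n_total):
        if it % 1024 == 0:  # draw innovations in blocks
            normals = rng.standard_normal((min(1024, n_total - it), d))
            unifs = np.log(rng.random(normals.shape[0]))
        prop = theta + scale * (chol @ normals[it % 1024])
        lp_prop = logpost(prop)
        if unifs[it % 1024] < lp_prop - lp:
            theta, lp = prop, lp_prop
            acc += 1
        if it < mc.burn_in:
            n_adapt += 1
            delta = theta - run_mean
            run_mean += delta / n_adapt
            run_cov += (np.outer(delta, theta - run_mean) - run_cov) / max(n_adapt, 20)
            if it % 200 == 199:
                rate = acc / 200.0
                scale *= float(np.exp(0.5 * (rate - 0.25)))
                acc = 0
                if n_adapt > 500:
                    try:
                        chol = np.linalg.cholesky(
                            opt * run_cov + 1e-8 * np.eye(d))
                    except np.linalg.LinAlgError:
                        pass
        elif it == mc.burn_in:
            acc = 0
        if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == mc.thin - 1:
            kept_p[i_keep] = _alr_inverse(theta[:k - 1])
            kept_s[i_keep] = theta[k - 1:] if sample_sigma else sigma_fixed
            i_keep += 1
    return kept_p[:i_keep], kept_s[:i_keep]


def _diagnostics(chains_p: np.ndarray, chains_s: np.ndarray,
                 categories: list[str], sample_sigma: bool):
    import arviz as az
    names, rhats, esss = [], [], []
    for k, cat in enumerate(categories):
        arr = chains_p[:, :, k]
        if np.ptp(arr) < 1e-12:      # constant parameter (e.g. K = 1)
            rhats.append(1.0)
            esss.append(float(arr.size))
        else:
            rhats.append(float(az.rhat(arr)))
            esss.append(float(az.ess(arr)))
        names.append(f"p_{cat}")
    if sample_sigma:
        for j in range(chains_s.shape[2]):
            arr = chains_s[:, :, j]
            rhats.append(float(az.rhat(arr)))
            esss.append(float(az.ess(arr)))
            names.append(f"sigma_{j}")
    return pd.Series(rhats, index=names), pd.Series(esss, index=names)


def fit(spec: MixingModelSpec, key=None, keep_draws: bool = False) -> DietEstimate:
    """Posterior diet proportions for one consumer group.

    Runs the configured chains, extends them (doubling the retained sample)
    while any split-R-hat exceeds the tolerance, and raises
    :class:`ConvergenceError` carrying the R-hat table if the gate is still
    violated after ``max_extensions`` extensions.
    """
    mc = spec.mcmc
    mc.validate()
    categories = spec.categories
    sample_sigma = spec.sigma_fixed is None

    for attempt in range(mc.max_extensions + 1):
        # each extension doubles both the adaptation and the retained sample
        mc_run = replace(mc, burn_in=mc.burn_in * 2 ** attempt)
        n_iter = mc.n_samples * 2 ** attempt
        run_spec = replace(spec, mcmc=mc_run)
        seeds = np.random.SeedSequence(mc.seed + attempt).spawn(mc.n_chains)
        chains_p, chains_s = [], []
        for c in range(mc.n_chains):
            kp, ks = _run_chain(run_spec, np.random.default_rng(seeds[c]), n_iter)
            chains_p.append(kp)
            chains_s.append(ks)
        chains_p = np.stack(chains_p)   # (chains, draws, K)
        chains_s = np.stack(chains_s)
        rhat, ess = _diagnostics(chains_p, chains_s, categories, sample_sigma)
        if rhat.max() <= mc.rhat_tol:
            break
        logger.warning("fit %s: max split-R-hat %.3f > %.2f, extending chains "
                       "(attempt %d)", key, rhat.max(), mc.rhat_tol, attempt + 1)
    else:
        raise ConvergenceError(
            f"mixing model did not converge for {key!r}: "
            f"max split-R-hat {rhat.max():.3f}", rhat=rhat)

    pooled = chains_p.reshape(-1, spec.n_sources)
    pooled_s = chains_s.reshape(-1, spec.n_isotopes)
    est = DietEstimate(
        key=key, categories=categories,
        mean=pooled.mean(axis=0), sd=pooled.std(axis=0, ddof=1),
        q025=np.percentile(pooled, 2.5, axis=0),
        q975=np.percentile(pooled, 97.5, axis=0),
        sigma_mean=pooled_s.mean(axis=0),
        rhat=rhat, n_effective=ess,
        draws=pooled if keep_draws else None,
        sigma_draws=pooled_s if keep_draws else None)
    return est


# ---------------------------------------------------------------------------
# TDF sensitivity protocol
# ---------------------------------------------------------------------------

def tdf_sensitivity(spec: MixingModelSpec,
                    c_values: Sequence[float],
                    n_values: Sequence[float]) -> pd.DataFrame:
    """Refit the model across a TDF grid and report posterior-mean shifts.

    The grid varies one isotope's TDF at a time (the other held at its
    baseline), holding the TDF SDs fixed.  The baseline TDF must appear in
    both value lists.  Returns a tidy table with one row per (grid point,
    source): posterior mean, absolute change vs baseline in percentage
    points, and a baseline flag.  Failed grid fits are recorded with NaN
    and do not abort the remaining cells.
    """
    tdf = spec.sources[0].tdf_mu
    one_isotope = len(tdf) < 2 or spec.n_isotopes < 2
    base_c = tdf[0]
    base_n = None if one_isotope else tdf[1]
    if not any(np.isclose(base_c, c) for c in c_values):
        raise InvalidInputError("baseline d13C TDF must be in c_values")
    if not one_isotope and not any(np.isclose(base_n, n) for n in n_values):
        raise InvalidInputError("baseline d15N TDF must be in n_values")

    grid: list[tuple] = []
    for c in c_values:
        grid.append((float(c),) if one_isotope else (float(c), float(base_n)))
    if not one_isotope:
        for n in n_values:
            pt = (float(base_c), float(n))
            if pt not in grid:
                grid.append(pt)

    results: dict[tuple, np.ndarray | None] = {}
    for pt in grid:
        sub = MixingModelSpec(
            consumers=spec.consumers,
            sources=with_tdf(spec.sources, pt),
            prior_alpha=spec.prior_alpha, sigma_max=spec.sigma_max,
            sigma_fixed=spec.sigma_fixed, mcmc=replace(spec.mcmc))
        try:
            results[pt] = fit(sub, key=pt).mean
        except ConvergenceError as exc:  # keep going on other cells
            logger.warning("tdf_sensitivity: fit failed at TDF %s: %s", pt, exc)
            results[pt] = None

    base_pt = (float(base_c),) if one_isotope else (float(base_c), float(base_n))
    base = results[base_pt]
    if base is None:
        raise ConvergenceError("baseline TDF fit failed")
    rows = []
    for pt, mean in results.items():
        for k, cat in enumerate(spec.categories):
            m = np.nan if mean is None else mean[k]
            chg = np.nan if mean is None else abs(m - base[k]) * 100.0
            rows.append({"tdf_c": pt[0],
                         "tdf_n": np.nan if one_isotope else pt[1],
                         "category": cat, "mean": m, "abs_change_pp": chg,
                         "is_baseline": pt == base_pt})
    return pd.DataFrame(rows)


def grand_mean_abs_change(sensitivity: pd.DataFrame) -> float:
    """Mean absolute posterior-mean change (percentage points) over all
    non-baseline grid points and sources."""
    off = sensitivity[~sensitivity["is_baseline"]]
    return float(off["abs_change_pp"].mean())
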