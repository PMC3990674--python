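"""Study-shaped synthetic data with known ground truth.

Emulates a three-population feather-isotope study of a territorial raptor:
seven population-years of 12-25 sampled territories, eight prey source
categories, nestling feather d13C/d15N generated from territory-level true
diet proportions through the same mixture moments the mixing model assumes,
and binary productivity (one vs two fledged chicks) driven by pair age, mate
replacement, diet specificity (PSi) and diet diversity (H').

Every stage consumes a single seeded generator, so a fixed
:class:`ScenarioConfig` reproduces byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InvalidInputError
from .isotope_io import (CATEGORIES, ConsumerRecord, SourceDistribution,
                         aggregate_siblings, write_consumers)

# Default source geometry in consumer space (tissue mean + TDF), chosen so
# the TDF-shifted mixing polygon spans the observed consumer envelope
# (d13C -24.85..-19.26, d15N 2.34..11.03 permil) and the corn-fed dovecote
# pigeons (CLd) sit at the d13C-rich extreme (C4 maize signal).
_SHIFTED_MEANS = {
    "OC": (-23.6, 5.2),    # European rabbit
    "AR": (-22.4, 3.8),    # red-legged partridge
    "CP": (-24.2, 7.6),    # wood pigeon
    "CLw": (-23.2, 9.2),   # domestic pigeon, crop foraging
    "CLd": (-19.2, 8.2),   # domestic pigeon, dovecote / corn
    "PAS": (-22.0, 11.1),  # passerines
    "SV": (-24.9, 4.6),    # red squirrel
    "TL": (-21.2, 2.3),    # ocellated lizard
}

_DEFAULT_POPULATION_YEARS = (
    ("France", 2010), ("France", 2011),
    ("Catalonia", 2008), ("Catalonia", 2009),
    ("Catalonia", 2010), ("Catalonia", 2011),
    ("Andalusia", 2011),
)

_DEFAULT_N_TERRITORIES = (20, 12, 20, 17, 25, 24, 12)

_BASE_DIET = {"OC": 0.24, "AR": 0.17, "CP": 0.11, "CLw": 0.12,
              "CLd": 0.05, "PAS": 0.09, "SV": 0.07, "TL": 0.12}
_TIGHT_DIET = {"OC": 0.30, "AR": 0.24, "CP": 0.10, "CLw": 0.12,
               "CLd": 0.03, "PAS": 0.07, "SV": 0.05, "TL": 0.09}
_SPECIALIST_DIET = {"OC": 0.45, "AR": 0.25, "CP": 0.06, "CLw": 0.06,
                    "CLd": 0.02, "PAS": 0.05, "SV": 0.04, "TL": 0.07}


def _diet_vector(d: dict[str, float]) -> np.ndarray:
    v = np.array([d[c] for c in CATEGORIES], dtype=float)
    return v / v.sum()


@dataclass
class ScenarioConfig:
    """Everything needed to simulate one complete study.

    Concentrations are Dirichlet precision parameters: territory diets are
    drawn from Dirichlet(concentration * mean_diet).  The ``tight`` regime
    (homogeneous, preferred-prey-rich diets, Andalusia-like) applies to the
    population-years listed in ``tight_population_years``; elsewhere a
    fraction ``specialist_fraction`` of territories draw from a
    rabbit/partridge-concentrated specialist component.
    """

    population_years: tuple = _DEFAULT_POPULATION_YEARS
    n_territories: tuple = _DEFAULT_N_TERRITORIES
    tight_population_years: tuple = (("Andalusia", 2011),)

    shifted_means: dict = field(default_factory=lambda: dict(_SHIFTED_MEANS))
    omega: tuple = (0.5, 0.6)          # tissue SD per isotope, permil
    tdf_mu: tuple = (2.1, 2.7)         # feather TDF means, permil
    tdf_sd: tuple = (0.08, 0.5)        # feather TDF SDs, permil
    residual_sd: tuple = (0.25, 0.30)  # per-chick residual SD, permil
    n_source_samples: int = 12         # raw prey samples per category

    base_diet: dict = field(default_factory=lambda: dict(_BASE_DIET))
    tight_diet: dict = field(default_factory=lambda: dict(_TIGHT_DIET))
    specialist_diet: dict = field(default_factory=lambda: dict(_SPECIALIST_DIET))
    spread_concentration: float = 12.0
    tight_concentration: float = 60.0
    specialist_concentration: float = 40.0
    specialist_fraction: float = 0.15

    # breeding model: logit P(two chicks) = beta . (1, nonadult, replacement,
    # PSi, PSi^2, H') + u_territory + u_population:year, on raw covariates
    beta: dict = field(default_factory=lambda: {
        "intercept": 9.6, "nonadult": -0.9, "replacement": -0.8,
        "ps": -18.72, "ps2": 12.0, "h": -1.2})
    sd_territory: float = 0.45
    sd_popyear: float = 0.25
    p_nonadult: float = 0.10
    p_replacement: float = 0.15
    success_rate: float = 0.62  # successful pairs / monitored pairs

    seed: int = 20140417

    def validate(self) -> None:
        if len(self.population_years) != len(self.n_territories):
            raise InvalidInputError("population_years and n_territories lengths differ")
        for name in ("spread_concentration", "tight_concentration",
                     "specialist_concentration"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        for sd in (*self.omega, *self.tdf_sd, *self.residual_sd,
                   self.sd_territory, self.sd_popyear):
            if sd < 0:
                raise InvalidInputError("SDs must be >= 0")
        if not 0 <= self.specialist_fraction <= 1:
            raise InvalidInputError("specialist_fraction must be in [0, 1]")
        if not 0 < self.success_rate <= 1:
            raise InvalidInputError("success_rate must be in (0, 1]")


# ---------------------------------------------------------------------------
# sources
# ---------------------------------------------------------------------------

def generate_sources(config: ScenarioConfig) -> list[SourceDistribution]:
    """The eight prey source distributions implied by the config geometry.

    Tissue means are the configured consumer-space means minus the TDF, so
    that TDF-shifted sources land exactly on the configured geometry.
    """
    config.validate()
    out = []
    for cat in CATEGORIES:
        sx, sy = config.shifted_means[cat]
        out.append(SourceDistribution(
            category=cat,
            mu=(sx - config.tdf_mu[0], sy - config.tdf_mu[1]),
            omega=tuple(config.omega),
            tdf_mu=tuple(config.tdf_mu),
            tdf_sd=tuple(config.tdf_sd),
            n_samples=config.n_source_samples))
    return out


def generate_source_samples(config: ScenarioConfig,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Raw prey-sample table (one row per individual), pigeons merged.

    The two domestic-pigeon groups are emitted under the single raw category
    ``CL`` so that the I/O layer's d13c split is exercised end to end.
    """
    rows = []
    for src in generate_sources(config):
        raw_cat = "CL" if src.category in ("CLw", "CLd") else src.category
        draws = rng.normal(src.mu, src.omega, size=(config.n_source_samples, 2))
        for d13c, d15n in draws:
            rows.append((raw_cat, d13c, d15n))
    return pd.DataFrame(rows, columns=["category", "d13c", "d15n"])


# ---------------------------------------------------------------------------
# territory diets
# ---------------------------------------------------------------------------

def generate_territory_diets(config: ScenarioConfig,
                             population_year: tuple[str, int],
                             rng: np.random.Generator) -> np.ndarray:
    """True diet proportion vectors, one simplex row per territory."""
    config.validate()
    idx = list(config.population_years).index(tuple(population_year))
    n = config.n_territories[idx]
    tight = tuple(population_year) in {tuple(t) for t in config.tight_population_years}
    if tight:
        alpha = config.tight_concentration * _diet_vector(config.tight_diet)
        return rng.dirichlet(alpha, size=n)
    alpha_spread = config.spread_concentration * _diet_vector(config.base_diet)
    alpha_spec = config.specialist_concentration * _diet_vector(config.specialist_diet)
    is_spec = rng.random(n) < config.specialist_fraction
    p = np.empty((n, len(CATEGORIES)))
    for i in range(n):
        p[i] = rng.dirichlet(alpha_spec if is_spec[i] else alpha_spread)
    return p


# ---------------------------------------------------------------------------
# feathers
# ---------------------------------------------------------------------------

def mixture_moments(p: np.ndarray, sources: list[SourceDistribution],
                    residual_sd: tuple[float, float] = (0.0, 0.0)
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Consumer mean and variance per isotope under the mixing model.

    mean_j = sum_k p_k (mu_jk + lambda_j);
    var_j  = sum_k p_k^2 (omega_jk^2 + tau_j^2) + sigma_j^2.
    """
    p = np.asarray(p, dtype=float)
    mu = np.array([s.mu for s in sources]).T          # (2, K)
    om = np.array([s.omega for s in sources]).T
    lam = np.array(sources[0].tdf_mu)
    tau = np.array(sources[0].tdf_sd)
    mean = (mu + lam[:, None]) @ p
    var = (om ** 2 + tau[:, None] ** 2) @ (p ** 2) + np.asarray(residual_sd) ** 2
    return mean, var


def generate_feathers(p: np.ndarray, sources: list[SourceDistribution],
                      config: ScenarioConfig, rng: np.random.Generator,
                      population: str, year: int, territory: str,
                      n_chicks: int) -> list[ConsumerRecord]:
    """Feather isotope records for one territory-year.

    Siblings share the territory's true diet and the territory-level
    source-sampling noise (which is a property of the prey actually taken in
    that territory); each chick adds independent residual noise.  The total
    per-chick variance therefore equals the mixing-model variance
    sum_k p_k^2 (omega^2 + tau^2) + sigma^2.
    """
    p = np.asarray(p, dtype=float)
    if p.min() < -1e-12 or abs(p.sum() - 1) > 1e-9:
        raise InvalidInputError("diet vector must lie on the simplex")
    mean, var_mix = mixture_moments(p, sources)
    territory_sd = np.sqrt(var_mix)  # source + TDF sampling, shared by siblings
    e_territory = rng.normal(0.0, territory_sd)
    out = []
    for c in range(n_chicks):
        e_chick = rng.normal(0.0, config.residual_sd)
        d13c, d15n = mean + e_territory + e_chick
        out.append(ConsumerRecord(population, year, territory,
                                  f"{territory}_c{c + 1}", float(d13c), float(d15n)))
    return out


# ---------------------------------------------------------------------------
# breeding outcomes
# ---------------------------------------------------------------------------

def breeding_linear_predictor(config: ScenarioConfig, nonadult, replacement,
                              ps, h) -> np.ndarray:
    b = config.beta
    return (b["intercept"] + b["nonadult"] * np.asarray(nonadult)
            + b["replacement"] * np.asarray(replacement)
            + b["ps"] * np.asarray(ps) + b["ps2"] * np.asarray(ps) ** 2
            + b["h"] * np.asarray(h))


def generate_breeding(truth: pd.DataFrame, config: ScenarioConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Breeding outcomes for successful pairs from diet truth.

    ``truth`` needs columns population, year, territory, ps, h.  Fledgling
    counts (1 or 2) are drawn from a logit model on pair age, mate
    replacement, PSi (linear + quadratic) and H', with random intercepts for
    territory and population:year.
    """
    config.validate()
    df = truth.copy()
    n = len(df)
    nonadult = (rng.random(n) < config.p_nonadult).astype(int)
    replacement = (rng.random(n) < config.p_replacement).astype(int)

    territories = df["territory"].astype(str).to_numpy()
    u_terr = {t: rng.normal(0.0, config.sd_territory)
              for t in dict.fromkeys(territories)}
    popyears = list(zip(df["population"], df["year"]))
    u_py = {k: rng.normal(0.0, config.sd_popyear) for k in dict.fromkeys(popyears)}

    eta = breeding_linear_predictor(config, nonadult, replacement,
                                    df["ps"].to_numpy(), df["h"].to_numpy())
    eta = eta + np.array([u_terr[t] for t in territories]) \
              + np.array([u_py[k] for k in popyears])
    two = rng.random(n) < expit(eta)
    out = df[["population", "year", "territory"]].copy()
    out["pair_age"] = np.where(nonadult == 1, "nonadult", "adult")
    out["replacement"] = replacement
    out["fledglings"] = np.where(two, 2, 1)
    return out


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

@dataclass
class ScenarioData:
    """A complete simulated study with its ground truth."""

    config: ScenarioConfig
    sources: list
    source_samples: pd.DataFrame
    consumers: list
    breeding: pd.DataFrame
    truth: pd.DataFrame           # per territory-year: true p, H', PSi
    popyear_summary: pd.DataFrame

    def observations(self):
        return aggregate_siblings(self.consumers)


def generate_scenario(config: ScenarioConfig | None = None,
                      seed: int | None = None) -> ScenarioData:
    """Simulate the whole study: sources, diets, breeding, feathers.

    Stage order (sources, diets, breeding covariates/outcomes, feathers) is
    fixed so a given seed yields identical output across runs.
    """
    config = config if config is not None else ScenarioConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    sources = generate_sources(config)
    source_samples = generate_source_samples(config, rng)

    diet_rows = []
    for py, n in zip(config.population_years, config.n_territories):
        p = generate_territory_diets(config, py, rng)
        for i in range(n):
            diet_rows.append((py[0], py[1], f"{py[0][:3].upper()}{py[1]}_T{i + 1:02d}", p[i]))
    pmat = np.array([r[3] for r in diet_rows])

    from .diet_indices import proportional_similarity, shannon_diversity
    q = pmat.mean(axis=0)
    q = q / q.sum()
    truth = pd.DataFrame(
        [(pop, yr, terr) for pop, yr, terr, _ in diet_rows],
        columns=["population", "year", "territory"])
    for k, cat in enumerate(CATEGORIES):
        truth[f"p_{cat}"] = pmat[:, k]
    truth["h"] = [shannon_diversity(p) for p in pmat]
    truth["ps"] = [proportional_similarity(p, q) for p in pmat]

    breeding = generate_breeding(truth, config, rng)

    consumers = []
    for (_, brow), (pop, yr, terr, p) in zip(breeding.iterrows(), diet_rows):
        consumers.extend(generate_feathers(
            p, sources, config, rng, pop, yr, terr, int(brow["fledglings"])))

    summary = breeding.groupby(["population", "year"], sort=False).agg(
        n_successful=("fledglings", "size"),
        total_fledglings=("fledglings", "sum")).reset_index()
    summary["n_monitored"] = np.ceil(
        summary["n_successful"] / config.success_rate).astype(int)
    summary["prod_successful"] = summary["total_fledglings"] / summary["n_successful"]
    summary["prod_whole"] = summary["total_fledglings"] / summary["n_monitored"]

    return ScenarioData(config, sources, source_samples, consumers,
                        breeding, truth, summary)


def write_scenario(data: ScenarioData, outdir) -> dict[str, str]:
    """Write consumers/sources/breeding/truth CSVs; returns the paths."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "consumers": os.path.join(outdir, "consumers.csv"),
        "sources": os.path.join(outdir, "sources.csv"),
        "breeding": os.path.join(outdir, "breeding.csv"),
        "truth": os.path.join(outdir, "truth.csv"),
        "popyears": os.path.join(outdir, "popyears.csv"),
    }
    write_consumers(data.consumers, paths["consumers"])
    data.source_samples.to_csv(paths["sources"], index=False, float_format="%.6f")
    data.breeding.to_csv(paths["breeding"], index=False)
    data.truth.to_csv(paths["truth"], index=False, float_format="%.8f")
    data.popyear_summary.to_csv(paths["popyears"], index=False, float_format="%.6f")
    return paths
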