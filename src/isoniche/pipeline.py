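"""End-to-end orchestration: data to study-shaped report tables.

Stage order mirrors the study design: load or simulate raw tables ->
sibling aggregation -> prey pooling (with the domestic-pigeon split) ->
per-territory-year Bayesian mixing fits -> diet indices -> population-year
niche metrics -> candidate-model ranking -> population-scale correlations.
Outputs are written both presentation-rounded (1 decimal for percentages,
2-3 for metrics) and at raw precision; a JSON manifest records the config,
seed and library versions needed to reproduce any table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InvalidInputError
from .isotope_io import (CATEGORIES, aggregate_siblings, load_breeding,
                         load_consumers, load_sources, observations_to_frame,
                         pool_sources)
from .mixing_model import (MCMCSettings, MixingModelSpec, fit,
                           grand_mean_abs_change, tdf_sensitivity)
from .niche_metrics import (DEFAULT_BOOTSTRAP_B, DEFAULT_BOOTSTRAP_M,
                            niche_table)
from .diet_indices import (population_mean_diet, preferred_prey_screen,
                           proportional_similarity, shannon_diversity)
from .fitness_models import population_level_tests, rank_model_set
from .synthetic_data import ScenarioConfig, generate_scenario

logger = logging.getLogger(__name__)

#: pipeline-scale chain settings: lighter than the single-fit default
#: because a full run performs one fit per territory-year
PIPELINE_MCMC = MCMCSettings(n_chains=2, burn_in=3000, n_samples=12_000, thin=6)


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Exactly one of ``scenario`` (simulate) or ``consumers_path`` +
    ``sources_path`` + ``breeding_path`` (load) must be provided.  The
    global ``seed`` is propagated to every stochastic stage (simulation,
    each mixing fit, the niche bootstrap).
    """

    scenario: ScenarioConfig | None = None
    consumers_path: str | None = None
    sources_path: str | None = None
    breeding_path: str | None = None

    tdf_mu: tuple = (2.1, 2.7)
    tdf_sd: tuple = (0.08, 0.5)
    prior_alpha: float = 1.0
    mcmc: MCMCSettings = field(default_factory=lambda: dataclasses.replace(PIPELINE_MCMC))

    boot_b: int = DEFAULT_BOOTSTRAP_B
    boot_m: int = DEFAULT_BOOTSTRAP_M

    model_ids: tuple | None = None     # subset of candidate model ids
    run_sensitivity: bool = True
    sens_c_values: tuple = (1.6, 2.1, 2.6)
    sens_n_values: tuple = (2.2, 2.7, 3.2)
    sens_max_territories: int = 10     # sensitivity protocol subsample

    #: successful pairs / monitored pairs, used to scale whole-population
    #: productivity when the input data lack unsuccessful pairs
    assumed_success_rate: float = 1.0

    outdir: str = "isoniche_out"
    seed: int = 0

    def validate(self):
        have_paths = all(p is not None for p in
                         (self.consumers_path, self.sources_path, self.breeding_path))
        if (self.scenario is None) == (not have_paths):
            raise InvalidInputError(
                "provide either a scenario or all three input paths, not both")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scenario" in raw and raw["scenario"] is not None:
            sc = dict(raw["scenario"])
            for key in ("population_years", "n_territories",
                        "tight_population_years", "omega", "tdf_mu", "tdf_sd",
                        "residual_sd"):
                if key in sc and isinstance(sc[key], list):
                    sc[key] = tuple(tuple(v) if isinstance(v, list) else v
                                    for v in sc[key])
            raw["scenario"] = ScenarioConfig(**sc)
        if "mcmc" in raw and raw["mcmc"] is not None:
            raw["mcmc"] = MCMCSettings(**raw["mcmc"])
        for key in ("tdf_mu", "tdf_sd", "sens_c_values", "sens_n_values",
                    "model_ids"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class PipelineResult:
    config: PipelineConfig
    observations: pd.DataFrame
    sources: list
    diet_estimates: pd.DataFrame   # long: territory-year x category posterior
    diet_table: pd.DataFrame       # wide: p_<cat>, h, ps per territory-year
    niche: pd.DataFrame            # table 1 shape
    consumption: pd.DataFrame      # table 2 shape
    model_report: pd.DataFrame     # table 3 shape
    prey_screen: pd.DataFrame
    population_tests: pd.DataFrame
    sensitivity: pd.DataFrame | None
    paths: dict


def summarize_consumption(diet_table: pd.DataFrame,
                          grouping=("population", "year")) -> pd.DataFrame:
    """Mean and range (max - min) consumption % per group and prey category.

    Input is the wide per-territory table with ``p_<cat>`` columns of
    posterior-mean proportions.  Groups with no territory are omitted with
    a warning (pandas drops empty groups); a single territory yields range 0.
    """
    pcols = [f"p_{c}" for c in CATEGORIES if f"p_{c}" in diet_table.columns]
    if not pcols:
        raise InvalidInputError("diet table has no p_<category> columns")
    rows = []
    for key, grp in diet_table.groupby(list(grouping), sort=False):
        if grp.empty:
            logger.warning("summarize_consumption: empty group %s omitted", key)
            continue
        for col in pcols:
            vals = grp[col].to_numpy(dtype=float) * 100.0
            rows.append({**dict(zip(grouping, key if isinstance(key, tuple) else (key,))),
                         "category": col[2:],
                         "mean_pct": vals.mean(),
                         "range_pct": float(np.ptp(vals)),
                         "n": len(vals)})
    return pd.DataFrame(rows)


def _formatted_consumption(consumption: pd.DataFrame,
                           grouping=("population", "year")) -> pd.DataFrame:
    """Pivot the consumption summary to 'Mean (range) %' strings,
    categories as rows and population-years as columns."""
    df = consumption.copy()
    df["cell"] = [f"{m:.1f} ({r:.1f})" for m, r in
                  zip(df["mean_pct"], df["range_pct"])]
    df["group"] = ["-".join(str(v) for v in t) for t in
                   zip(*[df[g] for g in grouping])]
    wide = df.pivot(index="category", columns="group", values="cell")
    return wide.reindex([c for c in CATEGORIES if c in wide.index])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the report bundle to ``config.outdir``."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    seed_seq = np.random.SeedSequence(config.seed)
    scenario_data = None

    # -- stage 1: load or generate -----------------------------------------
    if config.scenario is not None:
        scenario_data = generate_scenario(config.scenario, seed=config.seed)
        consumers = scenario_data.consumers
        source_samples = scenario_data.source_samples
        breeding = scenario_data.breeding
    else:
        consumers = load_consumers(config.consumers_path)
        source_samples = load_sources(config.sources_path)
        breeding = load_breeding(config.breeding_path)
    logger.info("stage=load consumers=%d prey_samples=%d breeding_rows=%d "
                "(successful pairs only)", len(consumers), len(source_samples),
                len(breeding))

    # -- stage 2: sibling aggregation --------------------------------------
    obs = aggregate_siblings(consumers)
    obs_df = observations_to_frame(obs)
    logger.info("stage=aggregate chicks=%d territory_years=%d",
                len(consumers), len(obs_df))

    # -- stage 3: prey pooling ---------------------------------------------
    sources = pool_sources(source_samples, config.tdf_mu, config.tdf_sd)
    logger.info("stage=pool categories=%d", len(sources))

    # -- stage 4: per-territory mixing fits --------------------------------
    fit_seeds = seed_seq.spawn(len(obs_df))
    by_key = {}
    for rec in consumers:
        by_key.setdefault((rec.population, rec.year, rec.territory), []).append(rec)
    long_rows, wide_rows = [], []
    alpha = np.full(len(sources), config.prior_alpha)
    for i, row in obs_df.iterrows():
        key = (row["population"], row["year"], row["territory"])
        chicks = by_key[key]
        x = np.array([[c.d13c, c.d15n] for c in chicks])
        mc = dataclasses.replace(config.mcmc,
                                 seed=int(fit_seeds[i].generate_state(1)[0] % (2 ** 31)))
        est = fit(MixingModelSpec(consumers=x, sources=sources,
                                  prior_alpha=alpha, mcmc=mc), key=key)
        for k, cat in enumerate(est.categories):
            long_rows.append({"population": key[0], "year": key[1],
                              "territory": key[2], "category": cat,
                              "mean": est.mean[k], "sd": est.sd[k],
                              "q025": est.q025[k], "q975": est.q975[k]})
        wide_rows.append({"population": key[0], "year": key[1],
                          "territory": key[2],
                          **{f"p_{c}": est.mean[k]
                             for k, c in enumerate(est.categories)}})
    diet_estimates = pd.DataFrame(long_rows)
    diet_table = pd.DataFrame(wide_rows)
    logger.info("stage=mixing fits=%d", len(diet_table))

    # -- stage 5: diet indices ---------------------------------------------
    pmat = diet_table[[f"p_{c}" for c in CATEGORIES]].to_numpy(dtype=float)
    q = population_mean_diet(pmat)
    diet_table["h"] = [shannon_diversity(p / p.sum()) for p in pmat]
    diet_table["ps"] = [proportional_similarity(p / p.sum(), q) for p in pmat]
    prey_screen = preferred_prey_screen(diet_table)
    logger.info("stage=diet_indices territories=%d preferred=%s",
                len(diet_table),
                list(prey_screen.loc[prey_screen["preferred"], "category"]))

    # -- stage 6: niche metrics --------------------------------------------
    boot_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
    niche = niche_table(obs_df, m=config.boot_m, B=config.boot_b, seed=boot_seed)
    logger.info("stage=niche population_years=%d", len(niche))

    # -- stage 7: model ranking --------------------------------------------
    merged = breeding.merge(diet_table, on=["population", "year", "territory"],
                            how="inner")
    merged["oc"] = merged["p_OC"]
    merged["ar"] = merged["p_AR"]
    models = None
    if config.model_ids is not None:
        from .fitness_models import candidate_models
        wanted = set(config.model_ids)
        models = [m for m in candidate_models() if m.id in wanted]
    model_report, _fits = rank_model_set(merged, models=models)
    logger.info("stage=fitness rows=%d models=%d", len(merged), len(model_report))

    # -- stage 8: population-scale tests -----------------------------------
    prod = breeding.groupby(["population", "year"], sort=False).agg(
        n_successful=("fledglings", "size"),
        total_fledglings=("fledglings", "sum")).reset_index()
    prod["prod_successful"] = prod["total_fledglings"] / prod["n_successful"]
    if scenario_data is not None:
        prod = prod.merge(
            scenario_data.popyear_summary[["population", "year", "n_monitored"]],
            on=["population", "year"])
        prod["prod_whole"] = prod["total_fledglings"] / prod["n_monitored"]
    else:
        prod["prod_whole"] = prod["prod_successful"] * config.assumed_success_rate
    popyear_table = prod.merge(niche[["population", "year", "sea_c", "sdnnd_b"]],
                               on=["population", "year"])
    population_tests = population_level_tests(popyear_table)
    logger.info("stage=population_tests population_years=%d", len(popyear_table))

    # -- stage 9: consumption summary --------------------------------------
    consumption = summarize_consumption(diet_table)

    # -- stage 10: sensitivity protocol ------------------------------------
    sensitivity = None
    if config.run_sensitivity:
        sens_keys = list(by_key)[:config.sens_max_territories]
        frames = []
        for j, key in enumerate(sens_keys):
            x = np.array([[c.d13c, c.d15n] for c in by_key[key]])
            mc = dataclasses.replace(
                config.mcmc,
                seed=int(fit_seeds[j].generate_state(2)[1] % (2 ** 31)))
            sens = tdf_sensitivity(
                MixingModelSpec(consumers=x, sources=sources,
                                prior_alpha=alpha, mcmc=mc),
                config.sens_c_values, config.sens_n_values)
            sens.insert(0, "territory", key[2])
            frames.append(sens)
        sensitivity = pd.concat(frames, ignore_index=True)
        logger.info("stage=sensitivity territories=%d grand_mean_abs_change=%.2fpp",
                    len(sens_keys), grand_mean_abs_change(sensitivity))

    # -- write outputs ------------------------------------------------------
    paths = _write_outputs(config, obs_df, niche, consumption, model_report,
                           diet_estimates, diet_table, prey_screen,
                           population_tests, sensitivity)
    return PipelineResult(config, obs_df, sources, diet_estimates, diet_table,
                          niche, consumption, model_report, prey_screen,
                          population_tests, sensitivity, paths)


def _write_outputs(config, obs_df, niche, consumption, model_report,
                   diet_estimates, diet_table, prey_screen,
                   population_tests, sensitivity) -> dict:
    out = config.outdir
    paths = {}

    t1 = niche.copy()
    for col in ("mean_d13c", "mean_d15n", "cr_b", "nr_b", "cd_b", "sdnnd_b",
                "sea_c"):
        t1[col] = t1[col].round(2)
    paths["table1"] = os.path.join(out, "table1.csv")
    t1.to_csv(paths["table1"], index=False)
    niche.to_csv(os.path.join(out, "table1_raw.csv"), index=False,
                 float_format="%.8f")

    paths["table2"] = os.path.join(out, "table2.csv")
    _formatted_consumption(consumption).to_csv(paths["table2"])
    consumption.to_csv(os.path.join(out, "table2_raw.csv"), index=False,
                       float_format="%.8f")

    t3 = model_report.copy()
    for col, nd in (("delta_aicc", 3), ("aicc_w", 3), ("r2m", 3), ("r2c", 3)):
        t3[col] = t3[col].round(nd)
    paths["table3"] = os.path.join(out, "table3.csv")
    t3.to_csv(paths["table3"], index=False)
    model_report.to_csv(os.path.join(out, "table3_raw.csv"), index=False,
                        float_format="%.8f")

    for name, df in (("diet_estimates", diet_estimates),
                     ("diet_table", diet_table),
                     ("observations", obs_df),
                     ("prey_screen", prey_screen),
                     ("population_tests", population_tests)):
        paths[name] = os.path.join(out, f"{name}.csv")
        df.to_csv(paths[name], index=False, float_format="%.8f")

    if sensitivity is not None:
        paths["sensitivity"] = os.path.join(out, "sensitivity.csv")
        sensitivity.to_csv(paths["sensitivity"], index=False,
                           float_format="%.8f")

    manifest = {
        "seed": config.seed,
        "config": _jsonable(dataclasses.asdict(config)),
        "versions": {"isoniche": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    paths["manifest"] = os.path.join(out, "manifest.json")
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
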