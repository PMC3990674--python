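"""Rank the 15 candidate productivity models by AICc.

The response is whether a successful pair fledged two chicks rather than
one, modelled as binomial-logit GLMMs with territory and year-in-population
random intercepts.  Every model carries pair age and mate replacement; the
candidates add preferred-prey consumption, diet diversity H' or diet
specificity PSi terms.  Models are ranked by AICc; the Akaike weight is the
probability a model is the best of the set, and R2m/R2c give the variance
explained by fixed effects alone vs fixed plus random effects.
"""

from isoniche import ScenarioConfig, generate_scenario, rank_model_set

data = generate_scenario(ScenarioConfig(), seed=8)
table = data.breeding.merge(data.truth, on=["population", "year", "territory"])
table["oc"] = table["p_OC"]
table["ar"] = table["p_AR"]

report, fits = rank_model_set(table)
cols = ["model", "delta_aicc", "aicc_w", "r2m", "r2c", "supported"]
print(report[cols].round(3).to_string(index=False))
best = fits[0]
print(f"\nbest model: {best.model.name}")
print(f"  sigma_territory = {best.sigma_territory:.2f}, "
      f"sigma_year:population = {best.sigma_popyear:.2f} (logit scale)")
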