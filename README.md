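# isoniche

Two-scale diet–fitness analysis for territorial raptors from feather
stable isotopes.

Field studies of breeding raptors can rarely watch what every nest eats,
but a few mantle feathers from each chick carry a chemical record of its
diet: δ¹³C and δ¹⁵N values (‰) that mix the isotopic signatures of the
prey species delivered to the nest. `isoniche` turns tables of such feather
values, prey tissue samples and breeding outcomes into the quantities a
trophic ecologist works with, at two scales:

- **Territory scale** — a Bayesian stable-isotope mixing model (SIAR-class)
  estimates each territory-year's diet proportions p over K = 8 prey
  categories from its chicks' isotope pairs,

      X_ij ~ Normal( Σ_k p_k (μ_jk + λ_j),  Σ_k p_k²(ω_jk² + τ_j²) + σ_j² ),

  with Dirichlet-prior proportions and trophic discrimination factors
  (TDFs) λ ± τ. Posterior-mean diets feed the Shannon–Weaver diversity
  H′ = −Σ p ln p, the proportional similarity to the population mean diet
  PSᵢ = 1 − ½ Σ |p_ik − q_k|, a preferred-prey Spearman screen, and a set
  of 15 binomial-logit mixed models (territory and year-in-population
  random intercepts, Laplace likelihood) relating the probability that a
  successful pair fledges two chicks to pair age, mate replacement and the
  diet covariates, ranked by AICc with Akaike weights and
  Nakagawa–Schielzeth R²m/R²c.
- **Population scale** — bootstrapped Layman metrics (CR_b, NR_b, CD_b,
  SDNND_b) and the small-sample-corrected standard ellipse area
  SEAc = π √det Σ̂ · (n−1)/(n−2) summarise each population-year's isotopic
  niche, and Spearman tests (exact p at small n) relate mean productivity
  to niche width and evenness.

Because raw field data of this kind are rarely deposited, the package
includes a first-class synthetic-study generator
(`isoniche.synthetic_data`) that simulates the whole design — seven
population-years of 12–25 territories, eight prey sources, 1–2 chicks per
nest, breeding outcomes driven by known coefficients — so every stage has
a parameter-recovery test with known ground truth. See `docs/methods.md`
for the models, defaults and numerical choices.

## Worked example

`examples/` holds one short script per capability. A single territory fit
(`python examples/02_mixing_model.py`) prints:

```
territory FRA2010_T01 (France 2010), 2 chick(s)
category  mean    sd  q025  q975  truth
      OC 0.153 0.127 0.005 0.469  0.368
      AR 0.147 0.123 0.006 0.453  0.174
      CP 0.130 0.110 0.005 0.409  0.101
     CLw 0.098 0.092 0.003 0.349  0.053
     CLd 0.082 0.076 0.003 0.287  0.091
     PAS 0.078 0.076 0.001 0.283  0.014
      SV 0.172 0.139 0.005 0.501  0.051
      TL 0.139 0.111 0.004 0.401  0.148
max split-R-hat: 1.030  (gate 1.05)
true proportions inside the 95% interval: 8/8
```

Each row is one prey category's posterior diet share for that territory:
with only two chicks the posteriors are wide, the credible intervals admit
the simulated truth for all 8 categories here, and the R̂ line confirms
the two chains agree. The other examples simulate a full study, compute
niche metrics and diet indices, rank the productivity models and run the
complete pipeline (`isoniche run` does the same from the shell, writing
`table1.csv`, `table2.csv`, `table3.csv`, `sensitivity.csv` and a
reproducibility manifest).

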