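# Methods

`isoniche` implements a two-scale analysis of nestling diet and breeding
performance for a territorial raptor, working from feather stable-isotope
values (δ¹³C vs PDB, δ¹⁵N vs AIR, both in ‰). The pipeline has four
statistical layers — a Bayesian stable-isotope mixing model, isotopic niche
metrics, diet diversity/specificity indices, and binomial mixed models of
productivity — plus a synthetic-study generator that provides ground truth
for every layer. This note documents the models, the defaults and why, the
numerical choices, and what the synthetic data do and do not emulate.

## Data model

The analysis unit at the fine scale is the **territory-year**: one breeding
territory observed in one season, represented by the feathers of its one or
two chicks. Sibling chicks are averaged into a single observation for niche
metrics (they share a diet and show very similar isotope values); for the
mixing model the individual chicks enter as separate consumer rows. The
coarse-scale unit is the **population-year** (e.g. Catalonia 2009).

Prey fall into eight categories: rabbit (OC), red-legged partridge (AR),
wood pigeon (CP), domestic pigeons split into crop-foraging (CLw) and
dovecote/corn-fed (CLd) groups, passerines (PAS), red squirrel (SV) and
ocellated lizard (TL). Raw prey tables may carry domestic pigeons as one
category (`CL`); `pool_sources` splits them on δ¹³C because corn is a C4
plant and drives dovecote birds to much higher δ¹³C. No cutoff value is
assumed: the split is an exact 1-D two-cluster k-means (contiguity of 1-D
clusters in sorted order makes the scan over split points exact), with an
optional fixed-threshold override. The lower-δ¹³C cluster is CLw, the
higher CLd.

Missing isotope values are rejected, not imputed: every statistic here is
defined on complete (δ¹³C, δ¹⁵N) pairs, and silently imputing a feather
value would propagate into diet proportions untraceably.

## Mixing model

For consumer i and isotope j, with K sources of tissue mean μ_jk and SD
ω_jk, trophic discrimination factor (TDF) mean λ_j and SD τ_j:

    X_ij ~ Normal( Σ_k p_k (μ_jk + λ_j),
                   Σ_k p_k² (ω_jk² + τ_j²) + σ_j² )

with diet proportions p on the simplex under a Dirichlet(α) prior (default
α = 1: flat) and residual SDs σ_j under Uniform(0, 20 ‰). TDF uncertainty
enters the variance term rather than being resampled per draw; this matches
the mean/variance composition of the SIAR family and keeps the model
amenable to an exact quadrature cross-check. Default TDFs are 2.1 ± 0.08 ‰
(δ¹³C) and 2.7 ± 0.5 ‰ (δ¹⁵N), feather values for a raptor fed on bird
muscle. The 20 ‰ σ bound is far beyond any observed feather spread, so the
prior is effectively flat over the plausible range.

Sampling is random-walk Metropolis on log-ratio coordinates. The simplex is
charted by K−1 additive-log-ratio coordinates (softmax inverse) rather than
the centered log-ratio, because the CLR is rank-deficient (coordinates sum
to zero) and a full-rank chart is required for a well-defined proposal
density; the Dirichlet prior is mapped through the chart with its Jacobian
Σ log p_k. The proposal adapts during burn-in: the empirical covariance of
the chain, scaled by 2.38²/d, with a scalar multiplier tuned towards ~25 %
acceptance; adaptation freezes when sampling starts, so the retained chain
is a valid time-homogeneous Markov chain.

Defaults are 2 chains × (10,000 burn-in + 40,000 draws, thinned by 10).
Convergence is gated on split-R̂ ≤ 1.05 for every p_k and σ_j (rank-
normalized R̂ via arviz); on failure the fit re-runs with doubled burn-in
and draws, up to two extensions, then raises an error carrying the R̂
table. Each territory-year is fitted independently — no hierarchical
pooling across territories — because the downstream indices are defined on
per-territory diets. The pipeline uses lighter per-fit chains
(3,000 + 12,000, thin 6) since a full run performs one fit per
territory-year; single-fit analyses keep the heavier default.

The TDF sensitivity protocol refits the model along one-at-a-time TDF
shifts (default grid 1.6/2.1/2.6 ‰ for δ¹³C and 2.2/2.7/3.2 ‰ for δ¹⁵N,
holding the TDF SDs fixed) and reports the absolute change in posterior
mean contributions versus baseline, in percentage points, plus the grand
mean over sources, territories and non-baseline grid points. Shared seeds
across grid cells reduce Monte-Carlo noise in the differences.

## Niche metrics

Layman-style metrics on the territory-year cloud in δ-space: CR and NR
(δ¹³C and δ¹⁵N ranges), CD (mean Euclidean distance to the centroid,
trophic diversity) and SDNND (SD of nearest-neighbour distances, trophic
evenness). SDNND uses the population SD (denominator n); a convention had
to be fixed and this one is seed-stable for small n. To compare
population-years with different territory counts, the four metrics are
bootstrapped: B = 10,000 replicates, each drawing one shared resample of
size m = 12 (the smallest population-year in the study design) with
replacement, evaluating all four metrics on that resample, and averaging.
One shared resample per replicate keeps the four metrics of a replicate
mutually consistent; sub-sampling without replacement is available behind a
flag. Bootstrapped ranges are necessarily ≤ the full-sample ranges.

Niche width is the standard ellipse area SEA = π √det(Σ̂) with Σ̂ the
sample covariance (denominator n−1), corrected for small samples as
SEAc = SEA (n−1)/(n−2), n ≥ 3. The standard ellipse is the 1-SD ellipse —
boundary at squared Mahalanobis distance 1 — whose area is exactly
π √det Σ; for bivariate normal data the squared Mahalanobis distance is
χ²₂, so the expected fraction of points inside is 1 − e^(−1/2) ≈ 0.3935,
the "core ~40 %" of the data. (A boundary at distance² = 2 would contain
63 %, which is inconsistent with both the area formula and the 40 % figure;
the package uses distance² ≤ 1 throughout.)

## Diet indices

Diet diversity is Shannon–Weaver H′ = −Σ p ln p in nats, computed on the
posterior-mean diet vector; with K = 8 the ceiling is ln 8 ≈ 2.079, which
is why natural logs are the right base for this system. Diet specificity is
the proportional similarity PSᵢ = 1 − ½ Σ |p_ik − q_k| between territory i
and the population mean diet q (the unweighted mean over all territory-
years in the study area, renormalized; a leave-one-out q is available but
not the default, as its effect is O(1/n)). PSᵢ equals one minus the total
variation distance, so PSᵢ = 1 exactly when the territory eats the mean
diet. Indices are computed on posterior means — a per-draw variant exists
but is not part of the headline pipeline, whose downstream models take one
covariate value per territory.

The preferred-prey screen Spearman-correlates each category's consumption
with H′ across territories: prey whose higher consumption *reduces* diet
diversity behave like preferred prey. A category is flagged when ρ < 0 with
two-sided p < 0.05. Spearman ρ is the Pearson correlation of mid-ranks; the
p-value is exact (full enumeration of n! orderings, counting |ρ| ≥ |ρ_obs|)
for n ≤ 9 and the t approximation with n−2 df otherwise. Constant inputs
yield an undefined ρ reported as missing with a warning.

## Productivity models

The territory-scale response is whether a *successful* pair fledged two
chicks rather than one (unsuccessful pairs cannot be sampled for feathers,
so the data conditions on success). Fifteen candidate binomial-logit GLMMs
are ranked; all contain pair age (adult/non-adult) and mate replacement,
and the candidates add rabbit and/or partridge consumption (separately or
summed), H′ (± quadratic), PSᵢ (± quadratic) or the H′×PSᵢ interaction.
Quadratic and interaction terms are built from z-scored continuous
predictors (standardization stabilizes these fits); the z-scoring is
applied per model fit and can be disabled for recovery studies.

Random intercepts: territory, and year-within-population coded as the
population×year factor. The marginal likelihood is approximated by Laplace
(appropriate for crossed random effects, where adaptive quadrature does not
factorize). The fit is staged: (1) a fast profiled PIRLS — the lme4 scheme
with spherical effects u = σv, v ~ N(0, I), jointly optimizing (β, v) —
provides starting values; (2) the exact Laplace deviance is minimized over
(β, σ_territory, σ_popyear) by L-BFGS-B with the random-effect mode solved
per evaluation. β belongs in the outer optimization because the log-
determinant term depends on β through the IRLS weights; profiling β inside
PIRLS yields a visibly different (inferior) optimum. The spherical
parametrization keeps the objective smooth at σ = 0, where the model
collapses exactly to plain logistic regression. Wald SEs are the Schur
complement of the joint (β, u) Hessian at the conditional mode — the
convention lme4 reports — which matches glmer SEs to a few percent on
shared test problems, including strongly collinear quadratic designs.

Model ranking uses AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k = fixed
coefficients + 2 variance components and n = territory-year observations
(both conventions have to be fixed; these mirror common mixed-model AIC
accounting), Akaike weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2), and
Nakagawa–Schielzeth R²: σ²_f is the variance of the fixed-effect linear
predictor, the distribution-specific variance is π²/3 for the logit link,
R²m = σ²_f / (σ²_f + σ²_terr + σ²_py + π²/3), and R²c adds the random
variances to the numerator. Models with ΔAICc < 2 are flagged as supported.

At the population scale, mean productivity (per population-year, both
successful-pairs-only and whole-population) is Spearman-correlated with
SEAc and SDNND_b — four (ρ, p) pairs, exact p at the study's n = 7. When
input data contain only successful pairs, whole-population productivity is
scaled by a configurable success rate (the synthetic generator records the
true one).

## Synthetic studies

The generator emulates the study shape: seven population-years
(France 2010–11, Catalonia 2008–11, Andalusia 2011) with 20, 12, 20, 17,
25, 24 and 12 sampled territories. Territory diets are Dirichlet draws;
an Andalusia-like "tight" regime uses a high concentration (60) around a
preferred-prey-rich mean, while the "spread" regime (concentration 12)
mixes in a specialist component (concentration 40, mass on OC+AR) for a
configurable fraction of territories (default 0.15). These defaults put the
true H′ and PSᵢ ranges in territory between ~1.2–2.0 nats and ~0.57–0.91,
overlapping the observed field ranges.

Source geometry is configuration, not code: no per-category prey isotope
table is published for this system, so the default places the eight
TDF-shifted source means to span the observed consumer envelope
(δ¹³C −24.85…−19.26 ‰, δ¹⁵N 2.34…11.03 ‰) with CLd at the δ¹³C-rich
extreme, and mixture diets then fall inside the mixing polygon. Tissue SDs
default to (0.5, 0.6) ‰ and chick residual SDs to (0.25, 0.30) ‰ —
magnitudes typical of feather studies and small enough that ≥ 99 % of
simulated chicks stay inside the source hull.

Feathers are drawn from the same mixture moments the mixing model assumes.
Siblings share the territory's diet and its source-sampling noise (the prey
actually taken in a territory are a territory-level realization), and add
independent per-chick residuals; the total per-chick variance equals the
model variance, so parameter-recovery tests are exact calibration checks.

Breeding outcomes follow logit P(two chicks) = β·(1, nonadult, replacement,
PSᵢ, PSᵢ², H′) + u_territory + u_population:year on *raw* covariates, with
defaults β = (9.6, −0.9, −0.8, −18.72, 12, −1.2) and random SDs
(0.45, 0.25). The PS coefficients encode a parabola 12(PSᵢ − 0.78)² —
productivity is highest at both PS extremes and H′ depresses it — and the
intercept sets P(two) ≈ 0.55 at typical covariates, giving successful-pair
productivity of ~1.3–1.6 fledglings per population-year. Whole-population
productivity divides total fledglings by monitored pairs inferred from a
configurable success rate (default 0.62).

What the generator does *not* emulate: spatial structure in prey
availability, year-to-year turnover dynamics beyond the Bernoulli
replacement flag, isotopic routing or concentration dependence, prey
biomass, and measurement drift. Passing recovery tests therefore certify
the statistical machinery under a correctly specified forward model, not
robustness to these field realities.

## Problem sizes and determinism

Everything stochastic flows from one seed: the generator consumes a single
`numpy` Generator in fixed stage order (byte-identical CSVs per config),
and the pipeline derives per-fit MCMC seeds and the bootstrap seed from its
global seed via `SeedSequence`. Tests and the reproduction script use
scaled problem sizes chosen as the smallest that leave the checks
informative: sensitivity protocols run on 6–10 territory-years with
(3,000–5,000 burn-in + 12,000–20,000 draws) chains; calibration suites use
50 replicates; GLMM recovery uses 200 territories × 2 years. Tolerances on
stochastic checks are set from binomial/Monte-Carlo standard errors at
those sizes, not tuned to outcomes.

## Known limitations

- The Laplace approximation is biased for Bernoulli responses with few
  observations per group; variance components for a factor with one
  observation per level are weakly identified, and fitted σ̂ may be
  positive in finite samples even when the truth is zero (this is correct
  ML behaviour, not a defect).
- Wald intervals for strongly collinear raw-scale quadratics (e.g. PSᵢ and
  PSᵢ² over [0.6, 1]) are wide and can be unreliable near quasi-separation;
  the ranking pipeline works on standardized predictors where this is much
  milder.
- The RWM sampler's effective sample size per retained draw is modest for
  diffuse 8-source posteriors with 1–2 consumers; posterior means carry
  ~1 pp Monte-Carlo error at pipeline settings. Convergence gating plus
  seed-sharing across sensitivity grids keeps reported contrasts stable.
- Exact Spearman p-values enumerate n! orderings and are restricted to
  n ≤ 9 by design.
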