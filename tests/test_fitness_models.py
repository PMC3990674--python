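"""GLMMs, AICc ranking, Nakagawa R2 and population-scale correlations."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from isoniche.errors import InvalidInputError
from isoniche.fitness_models import (GLMMResult, aicc,
                                     akaike_weights, build_design,
                                     candidate_models, fit_binomial_glmm,
                                     nakagawa_r2, population_level_tests,
                                     rank_model_set)

S2D = np.pi ** 2 / 3


# ---------------------------------------------------------------------------
# candidate set and design matrices
# ---------------------------------------------------------------------------

class TestCandidates:
    def test_fifteen_models_all_contain_age_replacement(self):
        models = candidate_models()
        assert [m.id for m in models] == list(range(1, 16))
        for m in models:
            X, names = build_design(self._data(), m.terms)
            assert names[:3] == ["intercept", "nonadult", "replacement"]

    def test_quadratics_built_from_scored_values(self):
        data = self._data()
        X, names = build_design(data, ("ps", "ps2"))
        ps = X[:, names.index("ps")]
        assert X[:, names.index("ps2")] == pytest.approx(ps ** 2)

    def _data(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "pair_age": np.where(rng.random(n) < 0.2, "nonadult", "adult"),
            "replacement": rng.integers(0, 2, n),
            "oc": rng.uniform(0.1, 0.5, n), "ar": rng.uniform(0.05, 0.3, n),
            "h": rng.uniform(1.2, 2.0, n), "ps": rng.uniform(0.6, 0.95, n)})


# ---------------------------------------------------------------------------
# GLMM core
# ---------------------------------------------------------------------------

def _simulate(n_terr=60, n_years=2, beta=(0.3, -0.8), sd_t=0.0, sd_p=0.0,
              seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    u_t = rng.normal(0, sd_t, n_terr)
    u_p = rng.normal(0, sd_p, 2 * n_years)
    for i in range(n_terr):
        pop = i % 2
        for yv in range(n_years):
            x = rng.normal()
            eta = beta[0] + beta[1] * x + u_t[i] + u_p[pop * n_years + yv]
            rows.append((f"T{i}", f"P{pop}:Y{yv}", x,
                         float(rng.random() < 1 / (1 + np.exp(-eta)))))
    return pd.DataFrame(rows, columns=["t", "p", "x", "y"])


class TestGLMM:
    def test_zero_variance_matches_plain_logistic(self):
        """With no group structure in truth, the GLMM collapses to a GLM."""
        import statsmodels.api as sm
        d = _simulate(n_terr=100, sd_t=0.0, sd_p=0.0, seed=3)
        X = np.column_stack([np.ones(len(d)), d["x"]])
        res = fit_binomial_glmm(d["y"].to_numpy(), X, d["t"].to_numpy(),
                                d["p"].to_numpy())
        glm = sm.Logit(d["y"].to_numpy(), X).fit(disp=0)
        assert np.abs(res.beta - glm.params).max() < 1e-3
        assert abs(res.loglik - glm.llf) < 1e-2

    def test_intercept_only_balanced_outcomes(self):
        d = _simulate(n_terr=50, beta=(0.0, 0.0), seed=1)
        y = np.zeros(len(d))
        y[: len(d) // 2] = 1.0  # exactly balanced
        X = np.ones((len(d), 1))
        res = fit_binomial_glmm(y, X, d["t"].to_numpy(), d["p"].to_numpy())
        assert abs(res.beta[0]) < 1e-4

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent oracle: lme4's Laplace glmer on identical data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        d = _simulate(n_terr=80, n_years=3, beta=(0.4, 0.7),
                      sd_t=0.8, sd_p=0.4, seed=6)
        csv = tmp_path / "d.csv"
        d.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x + (1|t) + (1|p), data=d, family=binomial)
            v <- as.data.frame(VarCorr(m))
            cat(fixef(m), v$sdcor, as.numeric(logLik(m)), sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        b0, b1, sd_t, sd_p, ll = map(float, out.stdout.strip().split("\n"))
        X = np.column_stack([np.ones(len(d)), d["x"]])
        res = fit_binomial_glmm(d["y"].to_numpy(), X, d["t"].to_numpy(),
                                d["p"].to_numpy())
        assert res.beta == pytest.approx([b0, b1], abs=5e-3)
        assert res.sigma_territory == pytest.approx(sd_t, abs=5e-3)
        assert res.sigma_popyear == pytest.approx(sd_p, abs=5e-3)
        assert res.loglik == pytest.approx(ll, abs=5e-3)

    def test_rejects_nonbinary_response(self):
        with pytest.raises(InvalidInputError):
            fit_binomial_glmm(np.array([0.0, 2.0]), np.ones((2, 1)),
                              np.array(["a", "b"]), np.array(["p", "p"]))


# ---------------------------------------------------------------------------
# AICc and weights
# ---------------------------------------------------------------------------

class TestInformationCriteria:
    def test_equal_aicc_equal_weights(self):
        assert akaike_weights([100.0, 100.0]) == pytest.approx([0.5, 0.5])

    def test_delta_two_closed_form(self):
        w = akaike_weights([0.0, 2.0])
        e = np.exp(-1.0)
        assert w == pytest.approx([1 / (1 + e), e / (1 + e)])

    def test_weights_invariant_to_constant_shift(self, rng):
        a = rng.uniform(100, 120, 10)
        assert akaike_weights(a) == pytest.approx(akaike_weights(a + 57.3))

    def test_aicc_formula_and_domain(self):
        assert aicc(-50.0, 3, 30) == pytest.approx(100 + 6 + 24 / 26)
        with pytest.raises(InvalidInputError):
            aicc(-50.0, 10, 11)

    def test_aicc_approaches_aic_for_large_n(self):
        aic = -2 * (-50.0) + 2 * 3
        diffs = [aicc(-50.0, 3, n) - aic for n in (20, 200, 2000)]
        assert diffs[0] > diffs[1] > diffs[2] > 0
        assert diffs[2] < 0.02


class TestNakagawaR2:
    def _result(self, linpred, sd_t=0.0, sd_p=0.0):
        return GLMMResult(beta=np.zeros(1), se=np.zeros(1), beta_names=["b0"],
                          sigma_territory=sd_t, sigma_popyear=sd_p,
                          loglik=0.0, n=len(linpred), k=3,
                          fixed_linpred=np.asarray(linpred, dtype=float))

    def test_intercept_only_marginal_zero(self):
        r2m, r2c = nakagawa_r2(self._result(np.full(20, 0.7), sd_t=0.5))
        assert r2m == pytest.approx(0.0, abs=1e-12)
        assert r2c == pytest.approx(0.25 / (0.25 + S2D))

    def test_no_random_variance_equal_r2(self, rng):
        lp = rng.normal(size=50)
        r2m, r2c = nakagawa_r2(self._result(lp))
        assert r2m == r2c

    def test_half_when_fixed_variance_is_pi2_over_3(self):
        lp = np.array([-1.0, 1.0]) * np.sqrt(S2D)  # ddof=0 variance pi^2/3
        r2m, _ = nakagawa_r2(self._result(lp))
        assert r2m == pytest.approx(0.5)

    def test_invariant_to_affine_predictor_recoding(self):
        """Refit with x -> 2x + 1: identical R2 (standardisation off)."""
        d = _simulate(n_terr=80, beta=(0.2, 0.9), seed=9)
        X1 = np.column_stack([np.ones(len(d)), d["x"]])
        X2 = np.column_stack([np.ones(len(d)), 2.0 * d["x"] + 1.0])
        r1 = fit_binomial_glmm(d["y"].to_numpy(), X1, d["t"].to_numpy(),
                               d["p"].to_numpy())
        r2 = fit_binomial_glmm(d["y"].to_numpy(), X2, d["t"].to_numpy(),
                               d["p"].to_numpy())
        assert nakagawa_r2(r1) == pytest.approx(nakagawa_r2(r2), abs=1e-4)


# ---------------------------------------------------------------------------
# model-set ranking
# ---------------------------------------------------------------------------

def _breeding_table(n=120, seed=0, ps2_effect=0.0, h_effect=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "population": rng.choice(["A", "B"], n),
        "year": rng.choice([2010, 2011], n),
        "territory": [f"T{i}" for i in range(n)],
        "pair_age": np.where(rng.random(n) < 0.15, "nonadult", "adult"),
        "replacement": rng.integers(0, 2, n),
        "oc": rng.uniform(0.1, 0.5, n), "ar": rng.uniform(0.05, 0.3, n),
        "h": rng.uniform(1.2, 2.0, n), "ps": rng.uniform(0.6, 0.95, n)})
    ps_c = (df["ps"] - df["ps"].mean()) / df["ps"].std(ddof=0)
    h_c = (df["h"] - df["h"].mean()) / df["h"].std(ddof=0)
    eta = 0.2 - 0.6 * (df["pair_age"] == "nonadult") - 0.5 * df["replacement"] \
        + ps2_effect * ps_c ** 2 + h_effect * h_c
    df["fledglings"] = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), 2, 1)
    return df


class TestRanking:
    def test_report_shape_and_weight_sum(self):
        report, fits = rank_model_set(_breeding_table(seed=2))
        assert len(report) == 15
        assert report["aicc_w"].sum() == pytest.approx(1.0, abs=1e-9)
        assert list(report.columns[:6]) == ["model_id", "model", "delta_aicc",
                                            "aicc_w", "r2m", "r2c"]
        assert report["delta_aicc"].iloc[0] == 0.0
        assert (report["delta_aicc"].diff().dropna() >= 0).all()
        assert all((f.model.id == report["model_id"].iloc[i])
                   for i, f in enumerate(fits))

    def test_quadratic_ps_effect_beats_h_model(self):
        """A generated PSi^2 effect ranks model 2 above the H'-only model
        in most replicates (selection consistency, scaled down)."""
        wins = 0
        subset = [m for m in candidate_models() if m.id in (2, 3)]
        for seed in range(8):
            data = _breeding_table(n=150, seed=seed, ps2_effect=1.2)
            report, _ = rank_model_set(data, models=subset)
            wins += report["model_id"].iloc[0] == 2
        assert wins >= 6

    def test_model_subset_respected(self):
        subset = [m for m in candidate_models() if m.id in (1, 3)]
        report, _ = rank_model_set(_breeding_table(seed=4), models=subset)
        assert sorted(report["model_id"]) == [1, 3]


class TestPopulationLevel:
    def _table(self, prod, sea, sdnnd=None):
        n = len(prod)
        return pd.DataFrame({
            "prod_successful": prod, "prod_whole": np.array(prod) * 0.6,
            "sea_c": sea,
            "sdnnd_b": sdnnd if sdnnd is not None else np.linspace(0.2, 0.9, n)})

    def test_constant_productivity_undefined(self):
        out = population_level_tests(self._table([1.5] * 7,
                                                 np.linspace(1, 6, 7)))
        assert out["rho"].isna().all()

    def test_antimonotone_gives_minus_one(self):
        sea = np.array([1.5, 2.0, 3.1, 4.0, 4.9, 5.3, 6.0])
        out = population_level_tests(self._table(2.0 - 0.1 * sea, sea))
        sea_rows = out[out.metric == "sea_c"]
        assert np.allclose(sea_rows["rho"], -1.0)

    def test_exact_p_at_n7(self, rng):
        prod = rng.normal(1.5, 0.2, 7)
        out = population_level_tests(self._table(prod, rng.uniform(1, 6, 7)))
        assert (out["method"] == "exact").all()
        assert (out["n"] == 7).all()

    def test_needs_five_population_years(self):
        with pytest.raises(InvalidInputError):
            population_level_tests(self._table([1.2, 1.3], [1.0, 2.0]))
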