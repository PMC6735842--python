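import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from seedspan.errors import InvalidInputError
from seedspan.models import (
    DEFAULT_CANDIDATES,
    ModelSpec,
    aicc,
    akaike_weights,
    fit_candidates,
    gls_fit,
    group_summary,
    model_average,
    one_way_anova,
    pgls_fit,
    rank_models,
    tukey_hsd,
)
from seedspan.simulate import balanced_tree, gen_bm_traits
from seedspan.tree import phylo_covariance

# the ten AICc values of the study's printed non-phylogenetic candidate block
PRINTED_AICC = (20.35, 26.72, 29.20, 36.04, 40.30, 47.79, 50.09, 50.13, 52.28, 52.31)


class TestAicc:
    def test_published_row_small_model(self):
        # logLik rounded to 2 decimals in print; AICc printed 26.72
        assert aicc(-9.97, 3, 35) == pytest.approx(26.71, abs=0.015)

    def test_published_row_full_model(self):
        assert aicc(0.60, 8, 35) == pytest.approx(20.34, abs=0.015)

    def test_k_zero(self):
        assert aicc(-5.0, 0, 10) == pytest.approx(10.0)

    def test_small_n_error(self):
        with pytest.raises(InvalidInputError):
            aicc(0.0, 5, 6)


class TestAkaikeWeights:
    def test_printed_column_gives_095(self):
        delta, w = akaike_weights(PRINTED_AICC)
        assert delta[0] == 0.0
        assert w[0] == pytest.approx(0.95, abs=0.005)

    def test_single_model(self):
        _, w = akaike_weights([42.0])
        assert w[0] == 1.0

    def test_equal_models(self):
        _, w = akaike_weights([10.0, 10.0])
        assert np.allclose(w, [0.5, 0.5])

    @given(st.lists(st.floats(-50, 300), min_size=1, max_size=12))
    def test_weights_sum_to_one_and_min_wins(self, vals):
        delta, w = akaike_weights(vals)
        assert w.sum() == pytest.approx(1.0)
        assert w[np.argmin(np.asarray(vals))] == pytest.approx(w.max())


def _sim_matrix(n=200, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 2.0 + 0.5 * x + rng.normal(0, 0.1, size=n)
    return pd.DataFrame({"y": y, "x": x}, index=[f"s{i}" for i in range(n)])


class TestGlsFit:
    def test_slope_recovery(self):
        fit = gls_fit(_sim_matrix(), ModelSpec(response="y", predictors=("x",)))
        assert 0.45 <= fit.coefficients["x"][0] <= 0.55

    def test_null_model_intercept_is_mean(self):
        m = _sim_matrix(50, 3)
        fit = gls_fit(m, ModelSpec(response="y"))
        assert fit.coefficients["(Intercept)"][0] == pytest.approx(m["y"].mean())

    def test_degenerate_perfect_fit(self):
        m = _sim_matrix(50, 1)
        m["y"] = m["x"]
        with pytest.raises(InvalidInputError, match="degenerate"):
            gls_fit(m, ModelSpec(response="y", predictors=("x",)))

    def test_collinear_design(self):
        m = _sim_matrix(50, 2)
        m["x2"] = 2.0 * m["x"]
        with pytest.raises(InvalidInputError, match="rank"):
            gls_fit(m, ModelSpec(response="y", predictors=("x", "x2")))

    def test_k_counting(self):
        m = _sim_matrix(35, 4)
        assert gls_fit(m, ModelSpec(response="y")).K == 2  # intercept + variance
        assert gls_fit(m, ModelSpec(response="y", predictors=("x",))).K == 3


@pytest.fixture(scope="module")
def pgls_setup():
    tree = balanced_tree(64, 100.0)
    cov = phylo_covariance(tree)
    rng = np.random.default_rng(21)
    x = np.array(list(gen_bm_traits(cov, 1.0, 0.0, 1.0, rng).values()))
    eps_draw = gen_bm_traits(cov, 0.01, 0.0, 1.0, rng)
    eps = np.array([eps_draw[t] for t in cov.taxa])
    y = 1.0 + 0.5 * x + eps
    m = pd.DataFrame({"y": y, "x": x}, index=cov.taxa)
    return m, cov


class TestPglsFit:

    def test_lambda_zero_equals_gls(self, pgls_setup):
        m, cov = pgls_setup
        spec = ModelSpec(response="y", predictors=("x",))
        pfit = pgls_fit(m, spec, cov, lam=0.0)
        ofit = gls_fit(m, spec)
        for name in pfit.coefficients:
            assert pfit.coefficients[name][0] == pytest.approx(
                ofit.coefficients[name][0], abs=1e-8
            )

    def test_bm_residuals_recovered(self, pgls_setup):
        m, cov = pgls_setup
        fit = pgls_fit(m, ModelSpec(response="y", predictors=("x",)), cov)
        assert fit.lambda_hat > 0.8
        assert fit.coefficients["x"][0] == pytest.approx(0.5, rel=0.1)

    def test_k_includes_lambda(self, pgls_setup):
        m, cov = pgls_setup
        fit = pgls_fit(m, ModelSpec(response="y", predictors=("x",)), cov)
        assert fit.K == 4  # intercept + slope + variance + lambda


class TestModelAveraging:
    def _fits(self, matrix, cands):
        return fit_candidates(matrix, cands, response="y")

    def test_single_model_identity(self):
        m = _sim_matrix(60, 5)
        fits = self._fits(m, [("x",)])
        avg = model_average(fits)
        for name, (est, *_rest) in avg.coefficients.items():
            assert est == pytest.approx(fits[0].coefficients[name][0])

    def test_equal_weight_halving(self):
        from seedspan.models import ModelFit

        f1 = ModelFit(spec=ModelSpec(response="y", predictors=("x",)),
                      coefficients={"x": (1.0, 0.0)}, log_likelihood=0, K=2, n=10,
                      aicc=10.0, weight=0.5, delta_i=0.0)
        f2 = ModelFit(spec=ModelSpec(response="y"), coefficients={},
                      log_likelihood=0, K=1, n=10, aicc=10.0, weight=0.5, delta_i=0.0)
        avg = model_average([f1, f2])
        assert avg.coefficients["x"][0] == pytest.approx(0.5)

    def test_dominant_weight_pins_average(self):
        # weights mimicking a ~0.95-dominant candidate set
        m = _sim_matrix(120, 6)
        m["z"] = np.random.default_rng(7).normal(size=len(m))
        fits = self._fits(m, [("x",), ("z",), ()])
        avg = model_average(fits)
        best = fits[0]
        assert best.weight > 0.9
        for name, (est, *_rest) in avg.coefficients.items():
            if name in best.coefficients and abs(best.coefficients[name][0]) > 0.05:
                assert est == pytest.approx(best.coefficients[name][0], rel=0.06)

    def test_weights_must_be_ranked(self):
        m = _sim_matrix(60, 8)
        fits = [gls_fit(m, ModelSpec(response="y", predictors=("x",)))]
        with pytest.raises(InvalidInputError):
            model_average(fits)  # no weights assigned yet


class TestAnova:
    def test_fixture_endosperm_f(self, fixture_frame):
        logp = np.log10(fixture_frame["p50"].astype(float))
        res = one_way_anova(logp, fixture_frame["endosperm"])
        assert res.F == pytest.approx(20.63, abs=0.05)
        assert (res.df1, res.df2) == (1, 37)
        assert res.p < 0.001

    def test_brute_force_small_example(self):
        vals = [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]
        grp = ["a", "a", "a", "b", "b", "b"]
        res = one_way_anova(vals, grp)
        # hand SS: grand mean 2.5; SSB = 6*(0.5^2) = 1.5; SSW = 4.0
        F = (1.5 / 1) / (4.0 / 4)
        assert res.F == pytest.approx(F)

    def test_affine_invariance(self, fixture_frame):
        logp = np.log10(fixture_frame["p50"].astype(float))
        a = one_way_anova(logp, fixture_frame["endosperm"]).F
        b = one_way_anova(3.0 * logp + 11.0, fixture_frame["endosperm"]).F
        assert a == pytest.approx(b)

    def test_single_group_error(self):
        with pytest.raises(InvalidInputError):
            one_way_anova([1, 2, 3], ["a", "a", "a"])

    def test_identical_values_error(self):
        with pytest.raises(InvalidInputError):
            one_way_anova([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])


class TestTukey:
    def test_fixture_dormancy_pattern(self, fixture_frame):
        sub = fixture_frame[fixture_frame["endosperm"] == "N"]
        p = tukey_hsd(np.log10(sub["p50"].astype(float)), sub["dormancy"])
        p = {frozenset(k): v for k, v in p.items()}
        assert p[frozenset(("PY", "ND"))] < 0.001
        assert p[frozenset(("PY", "PD"))] < 0.001
        assert p[frozenset(("ND", "PD"))] > 0.05

    def test_two_groups_equal_anova(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 10)])
        grp = ["a"] * 10 + ["b"] * 10
        tk = tukey_hsd(vals, grp)
        an = one_way_anova(vals, grp)
        assert list(tk.values())[0] == pytest.approx(an.p, abs=1e-6)

    def test_identical_groups_p_one(self):
        p = tukey_hsd([1, 2, 3, 1, 2, 3], ["a", "a", "a", "b", "b", "b"])
        assert list(p.values())[0] == pytest.approx(1.0)


class TestGroupSummary:
    def test_fixture_order_means(self, fixture_frame):
        g = group_summary(fixture_frame["p50"].astype(float), fixture_frame["order"])
        assert g["Fabales"]["mean"] == pytest.approx(186.0, abs=0.05)
        assert g["Fabales"]["n"] == 6
        assert g["Gentianales"]["mean"] == pytest.approx(16.3, abs=0.05)
        assert g["Poales"]["mean"] == pytest.approx(20.9, abs=0.05)

    def test_singleton_se_zero(self, fixture_frame):
        g = group_summary(fixture_frame["p50"].astype(float), fixture_frame["order"])
        assert g["Dipsacales"] == {"mean": 18.8, "se": 0.0, "n": 1}


class TestFixtureCandidateSet:
    def test_binary_candidates_rank_sanely(self, fixture_matrix):
        cands = [c for c in DEFAULT_CANDIDATES
                 if set(c) <= {"non_endospermic", "py", "pd"}]
        fits = fit_candidates(fixture_matrix, cands)
        assert sum(f.weight for f in fits) == pytest.approx(1.0)
        assert fits[0].delta_i == 0.0
        # PY alone explains most: it must beat the null model decisively
        labels = [f.spec.label() for f in fits]
        assert labels.index("py") < labels.index("null")

    def test_pgls_full_set(self, fixture_matrix, fixture_cov):
        cands = [c for c in DEFAULT_CANDIDATES
                 if set(c) <= {"non_endospermic", "py", "pd"}]
        fits = fit_candidates(fixture_matrix, cands, cov=fixture_cov)
        avg = model_average(fits)
        assert avg.lambda_avg is not None
        assert sum(f.weight for f in fits) == pytest.approx(1.0)
        # indicator effects keep their published signs
        assert avg.coefficients["non_endospermic"][0] > 0
        assert avg.coefficients["py"][0] > 0
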