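"""Driver analyses: Akaike importance, Pearson screens, taxon
proportions, recursive path analysis."""

import numpy as np
import pandas as pd
import pytest

from chronobef.community import OtuTable
from chronobef.driver_models import (
    PathModel,
    _aicc,
    akaike_importance,
    dominant_taxon_proportions,
    fit_path_model,
    pearson_screen,
)


class TestAkaikeImportance:
    def test_overwhelming_predictor_dominates(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = 10.0 * x + rng.normal(size=n)  # slope = 10 x noise SD
        out = akaike_importance(pd.Series(y), pd.DataFrame({"x": x}))
        assert out.loc["x", "importance"] > 0.99
        assert out.loc["x", "significant"]

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_noise_predictor_scores_below_true_predictor(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        out = akaike_importance(
            pd.Series(y), pd.DataFrame({"x": x, "noise": noise})
        )
        assert out.loc["noise", "importance"] < out.loc["x", "importance"]

    def test_two_predictor_case_matches_hand_enumeration(self, rng):
        """Importance equals the sum of hand-computed normalised AICc
        weights over the four models {}, {a}, {b}, {a,b}."""
        n = 40
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = 0.8 * a + 0.3 * b + rng.normal(size=n)
        X = pd.DataFrame({"a": a, "b": b})
        out = akaike_importance(pd.Series(y), X)

        def fit_aicc(cols):
            M = np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in cols])
            coef, *_ = np.linalg.lstsq(M, y, rcond=None)
            rss = ((y - M @ coef) ** 2).sum()
            return _aicc(rss, n, M.shape[1])

        aiccs = np.array([fit_aicc(c) for c in [(), ("a",), ("b",), ("a", "b")]])
        w = np.exp(-(aiccs - aiccs.min()) / 2)
        w = w / w.sum()
        assert out.loc["a", "importance"] == pytest.approx(w[1] + w[3])
        assert out.loc["b", "importance"] == pytest.approx(w[2] + w[3])

    def test_weights_sum_to_one(self, rng):
        y = rng.normal(size=30)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        out = akaike_importance(pd.Series(y), X)
        assert sum(out.attrs["weights"].values()) == pytest.approx(1.0)
        assert out["importance"].between(0, 1).all()

    def test_collinear_pair_rejected_by_name(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="'x' and 'x2'"):
            akaike_importance(pd.Series(rng.normal(size=20)), X)

    def test_duplicate_column_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)))
        X.columns = ["x", "x"]
        with pytest.raises(ValueError, match="duplicate"):
            akaike_importance(pd.Series(rng.normal(size=20)), X)

    def test_too_many_predictors_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 13)))
        X.columns = [f"p{i}" for i in range(13)]
        with pytest.raises(ValueError, match="2\\^k"):
            akaike_importance(pd.Series(rng.normal(size=30)), X)


class TestPearsonScreen:
    def _env(self, bef, **extra):
        return pd.DataFrame({"self": bef, **extra}, index=bef.index)

    def test_identity_covariate(self, rng):
        bef = pd.Series(rng.normal(size=20), index=[f"p{i}" for i in range(20)])
        out = pearson_screen(bef, self._env(bef))
        assert out.loc["self", "r"] == pytest.approx(1.0)
        assert out.loc["self", "p"] < 0.01
        assert out.loc["self", "sig"] == "**"

    def test_negated_covariate(self, rng):
        bef = pd.Series(rng.normal(size=15), index=[f"p{i}" for i in range(15)])
        out = pearson_screen(bef, self._env(bef, neg=-bef))
        assert out.loc["neg", "r"] == pytest.approx(-1.0)

    def test_matches_brute_force_covariance_formula(self, rng):
        bef = pd.Series(rng.normal(size=25), index=[f"p{i}" for i in range(25)])
        x = pd.Series(rng.normal(size=25), index=bef.index)
        out = pearson_screen(bef, self._env(bef, x=x))
        xc, yc = x - x.mean(), bef - bef.mean()
        brute = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert out.loc["x", "r"] == pytest.approx(brute)

    def test_constant_covariate_skipped(self, rng, caplog):
        bef = pd.Series(rng.normal(size=12), index=[f"p{i}" for i in range(12)])
        with caplog.at_level("INFO"):
            out = pearson_screen(bef, self._env(bef, flat=pd.Series(1.0, index=bef.index)))
        assert "flat" not in out.index

    def test_too_few_plots_rejected(self, rng):
        bef = pd.Series(rng.normal(size=5), index=[f"p{i}" for i in range(5)])
        with pytest.raises(ValueError, match="plots"):
            pearson_screen(bef, self._env(bef))


class TestDominantTaxonProportions:
    def _table(self, arr, otus, group="bacteria"):
        df = pd.DataFrame(arr, index=otus, columns=[f"s{j}" for j in range(np.shape(arr)[1])])
        return OtuTable(counts=df, group=group, rarefaction_depth=10)

    def test_single_otu_taxon_has_proportion_one(self):
        tables = {"bacteria": self._table([[7, 3]], ["b1"])}
        tax = pd.DataFrame(dict(otu_id=["b1"], group=["bacteria"], taxon=["Actinobacteria"]))
        out = dominant_taxon_proportions(tables, tax)
        assert (out["bacteria:Actinobacteria"] == 1.0).all()

    def test_disjoint_taxa_sum_below_one(self, rng):
        arr = rng.integers(1, 20, size=(6, 4))
        otus = [f"b{i}" for i in range(6)]
        tables = {"bacteria": self._table(arr, otus)}
        tax = pd.DataFrame(
            dict(
                otu_id=otus,
                group="bacteria",
                taxon=["A", "A", "B", "B", "C", "Other"],
            )
        )
        out = dominant_taxon_proportions(tables, tax)
        assert (out.sum(axis=1) <= 1.0 + 1e-12).all()

    def test_matches_brute_force_ratio(self, rng):
        arr = rng.integers(0, 9, size=(5, 3)) + 1
        otus = [f"b{i}" for i in range(5)]
        tables = {"bacteria": self._table(arr, otus)}
        tax = pd.DataFrame(dict(otu_id=otus, group="bacteria",
                                taxon=["A", "A", "B", "B", "B"]))
        out = dominant_taxon_proportions(tables, tax)
        totals = arr.sum(axis=0)
        np.testing.assert_allclose(out["bacteria:A"], arr[:2].sum(axis=0) / totals)
        np.testing.assert_allclose(out["bacteria:B"], arr[2:].sum(axis=0) / totals)

    def test_absent_taxon_yields_zero_column_with_warning(self, caplog):
        tables = {"bacteria": self._table([[5, 5]], ["b1"])}
        tax = pd.DataFrame(dict(otu_id=["zz"], group=["bacteria"], taxon=["Ghost"]))
        with caplog.at_level("WARNING"):
            out = dominant_taxon_proportions(tables, tax)
        assert (out["bacteria:Ghost"] == 0).all()
        assert "Ghost" in caplog.text


class TestPathModel:
    def test_saturated_model_reproduces_covariance(self, rng):
        n = 300
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.4 * m + 0.2 * x + rng.normal(size=n)
        data = pd.DataFrame(dict(x=x, m=m, y=y))
        fit = fit_path_model(
            PathModel(edges=[("x", "m"), ("x", "y"), ("m", "y")]), data
        )
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 0
        assert fit.saturated

    def test_chain_indirect_effect_is_product_of_paths(self, rng):
        n = 400
        x = rng.normal(size=n)
        m = 0.7 * x + rng.normal(size=n)
        y = 0.5 * m + rng.normal(size=n)
        fit = fit_path_model(
            PathModel(edges=[("x", "m"), ("m", "y")]),
            pd.DataFrame(dict(x=x, m=m, y=y)),
        )
        a = fit.coefficients[("x", "m")]
        b = fit.coefficients[("m", "y")]
        eff = fit.effects.set_index(["source", "target"])
        assert eff.loc[("x", "y"), "indirect"] == pytest.approx(a * b)
        assert eff.loc[("x", "y"), "direct"] == 0.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_parameter_recovery_at_large_n(self, seed):
        rng = np.random.default_rng(seed)
        n = 2000
        a, b, c = 0.6, 0.5, 0.3
        x = rng.normal(size=n)
        m = a * x + rng.normal(scale=np.sqrt(1 - a**2), size=n)
        resid_y = 1 - (b**2 + c**2 + 2 * a * b * c)
        y = b * m + c * x + rng.normal(scale=np.sqrt(resid_y), size=n)
        fit = fit_path_model(
            PathModel(edges=[("x", "m"), ("m", "y"), ("x", "y")]),
            pd.DataFrame(dict(x=x, m=m, y=y)),
        )
        assert fit.coefficients[("x", "m")] == pytest.approx(a, abs=0.05)
        assert fit.coefficients[("m", "y")] == pytest.approx(b, abs=0.05)
        assert fit.coefficients[("x", "y")] == pytest.approx(c, abs=0.05)

    def test_total_equals_direct_plus_indirect(self, rng):
        n = 200
        x = rng.normal(size=n)
        w = rng.normal(size=n)
        m = 0.4 * x + 0.3 * w + rng.normal(size=n)
        y = 0.5 * m + 0.2 * x + rng.normal(size=n)
        fit = fit_path_model(
            PathModel(edges=[("x", "m"), ("w", "m"), ("m", "y"), ("x", "y")]),
            pd.DataFrame(dict(x=x, w=w, m=m, y=y)),
        )
        for _, row in fit.effects.iterrows():
            assert row["total"] == pytest.approx(row["direct"] + row["indirect"])

    def test_cyclic_spec_rejected(self, rng):
        data = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="cycle"):
            fit_path_model(PathModel(edges=[("a", "b"), ("b", "a")]), data)

    def test_missing_variable_rejected(self, rng):
        data = pd.DataFrame(rng.normal(size=(50, 1)), columns=["a"])
        with pytest.raises(ValueError, match="missing"):
            fit_path_model(PathModel(edges=[("a", "zz")]), data)

    def test_overidentified_model_reports_fit_statistics(self, rng):
        n = 500
        x = rng.normal(size=n)
        m = 0.6 * x + rng.normal(size=n)
        y = 0.5 * m + rng.normal(size=n)  # no direct x->y path: df = 1
        fit = fit_path_model(
            PathModel(edges=[("x", "m"), ("m", "y")]),
            pd.DataFrame(dict(x=x, m=m, y=y)),
        )
        assert fit.df == 1
        assert fit.chi2 >= 0
        assert 0 <= fit.rmsea
        assert 0 <= fit.p <= 1
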