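import numpy as np
import pandas as pd
import pytest

from marshweb import (FoodWeb, MinresCorePeriphery, SyntheticParasiteConfig,
                      SyntheticWebConfig, build_predictor_table,
                      centrality_suite, fit_random_forest,
                      fit_regression_tree, generality_vulnerability,
                      generate_parasites, generate_web, host_richness,
                      importance_report)
from marshweb.diversity import PREDICTORS, _bootstrap_indices


def _component_tables(web, planted, records):
    cent = centrality_suite(web).table.assign(web=web.name)
    core = pd.DataFrame({"web": web.name, "label": list(web.labels),
                         "coreness": MinresCorePeriphery().fit(web).coreness_})
    grp = pd.DataFrame({"web": web.name, "label": list(web.labels),
                        "group": planted})
    gv = generality_vulnerability(web).assign(web=web.name)
    inc = host_richness(web, records)
    return cent, core, grp, gv, inc


@pytest.fixture(scope="module")
def web_table():
    web, planted = generate_web(SyntheticWebConfig(S=60, seed=8))
    records = generate_parasites(web, SyntheticParasiteConfig(seed=9))
    table = build_predictor_table([web],
                                  *_component_tables(web, planted, records))
    return web, table


def _noise_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "web": "w", "label": [f"s{i}" for i in range(n)],
        "eigenvector": rng.random(n), "betweenness": rng.random(n),
        "closeness": rng.random(n), "degree": rng.integers(1, 20, n),
        "group": rng.integers(1, 4, n), "coreness": rng.random(n),
        "marsh_diversity": 80, "G": rng.integers(0, 10, n),
        "V": rng.integers(0, 10, n),
        "richness": rng.integers(0, 6, n),
    })


class TestPredictorTable:
    def test_row_count_and_marsh_diversity(self, web_table):
        web, table = web_table
        assert len(table) == web.n_species
        assert (table["marsh_diversity"] == web.n_species).all()
        assert set(table.columns) >= set(PREDICTORS) | {"richness"}

    def test_multi_web_marsh_diversity_values(self):
        tables = []
        webs = []
        for S, seed in ((30, 1), (40, 2)):
            web, planted = generate_web(SyntheticWebConfig(S=S, seed=seed))
            records = generate_parasites(web, SyntheticParasiteConfig(
                n_parasites=8, seed=seed))
            webs.append(web)
            tables.append(_component_tables(web, planted, records))
        merged = build_predictor_table(
            webs, *(pd.concat(parts, ignore_index=True)
                    for parts in zip(*tables)))
        assert len(merged) == 70
        assert set(merged["marsh_diversity"]) == {30, 40}
        # group levels are web-qualified: no cross-marsh aliasing
        assert merged["group"].str.contains(":").all()

    def test_missing_metric_is_hard_error(self, web_table):
        web, _ = web_table
        _, planted = generate_web(SyntheticWebConfig(S=60, seed=8))
        records = generate_parasites(web, SyntheticParasiteConfig(seed=9))
        cent, core, grp, gv, inc = _component_tables(web, planted, records)
        with pytest.raises(ValueError, match="missing a metric"):
            build_predictor_table([web], cent.iloc[:-1], core, grp, gv, inc)


class TestRegressionTree:
    def test_constant_response_is_stump(self, web_table):
        _, table = web_table
        rows = table.copy()
        rows["richness"] = 3
        fit = fit_regression_tree(rows, seed=0)
        assert fit.pseudo_r2 == 0.0 and fit.n_leaves == 1

    def test_planted_signal_recovered(self):
        rows = _noise_table(n=300, seed=4)
        rng = np.random.default_rng(5)
        rows["richness"] = np.round(
            3.0 * rows["G"] + rng.normal(0, 1, 300)).clip(0).astype(int)
        fit = fit_regression_tree(rows, seed=1)
        root_feature = fit.design.columns[fit.estimator.tree_.feature[0]]
        assert root_feature == "G"
        assert fit.importance.idxmax() == "G"
        assert fit.pseudo_r2 > 0.8

    def test_min_rule_grows_at_least_as_complex_a_tree(self, web_table):
        _, table = web_table
        one_se = fit_regression_tree(table, seed=2, rule="1se")
        cv_min = fit_regression_tree(table, seed=2, rule="min")
        assert cv_min.cp_alpha <= one_se.cp_alpha
        assert cv_min.pseudo_r2 >= one_se.pseudo_r2 - 1e-12

    def test_seed_reproducibility(self, web_table):
        _, table = web_table
        a = fit_regression_tree(table, seed=3)
        b = fit_regression_tree(table, seed=3)
        assert a.pseudo_r2 == b.pseudo_r2
        assert a.importance.equals(b.importance)

    def test_importance_covers_all_predictors(self, web_table):
        _, table = web_table
        fit = fit_regression_tree(table, seed=0)
        assert list(fit.importance.index) == list(PREDICTORS)


class TestRandomForest:
    def test_oob_reconstruction_matches_sklearn(self, web_table):
        """Our bootstrap-index reconstruction must reproduce the forest's
        own out-of-bag predictions exactly."""
        _, table = web_table
        fit = fit_random_forest(table, n_trees=120, seed=3)
        X = fit.design.matrix(table)
        n = len(table)
        preds, counts = np.zeros(n), np.zeros(n)
        for t in fit.estimator.estimators_:
            oob = np.setdiff1d(np.arange(n), _bootstrap_indices(t.random_state, n))
            preds[oob] += t.predict(X[oob])
            counts[oob] += 1
        mask = counts > 0
        np.testing.assert_allclose(preds[mask] / counts[mask],
                                   fit.estimator.oob_prediction_[mask])

    def test_pure_noise_importances_near_zero(self):
        rows = _noise_table(n=200, seed=0)
        fit = fit_random_forest(rows, n_trees=200, seed=3)
        var_y = rows["richness"].to_numpy(float).var()
        assert (fit.importance.abs() <= 0.1 * var_y).all()

    def test_planted_importance_ordering(self):
        rows = _noise_table(n=300, seed=6)
        rng = np.random.default_rng(7)
        signal = 3.0 * rows["G"] + 1.0 * 10 * rows["eigenvector"]
        rows["richness"] = np.round(
            signal + rng.normal(0, 1, 300)).clip(0).astype(int)
        fit = fit_random_forest(rows, n_trees=300, seed=8)
        imp = fit.importance
        rest = imp.drop(["G", "eigenvector"])
        assert imp["G"] >= imp["eigenvector"]
        assert imp["eigenvector"] >= rest.max()

    def test_two_importance_measures_reported(self, web_table):
        _, table = web_table
        fit = fit_random_forest(table, n_trees=100, seed=1)
        assert list(fit.importance.index) == list(PREDICTORS)
        assert list(fit.impurity_importance.index) == list(PREDICTORS)
        assert fit.impurity_importance.sum() == pytest.approx(1.0)

    def test_few_trees_warns(self, web_table):
        _, table = web_table
        with pytest.warns(UserWarning, match="50"):
            fit_random_forest(table, n_trees=20, seed=0)

    def test_seed_reproducibility(self, web_table):
        _, table = web_table
        a = fit_random_forest(table, n_trees=80, seed=5)
        b = fit_random_forest(table, n_trees=80, seed=5)
        assert a.pseudo_r2 == b.pseudo_r2
        assert a.importance.equals(b.importance)


class TestReport:
    def test_top4_and_both_flag(self, web_table):
        _, table = web_table
        models = {
            ("regression_tree", "all"): fit_regression_tree(table, seed=0),
            ("random_forest", "all"): fit_random_forest(table, n_trees=100,
                                                        seed=0),
        }
        report = importance_report(models)
        assert len(report) == 2
        for tops in report["top4_variables"]:
            names = tops.split(", ")
            assert len(names) == 4
            assert set(names) <= set(PREDICTORS)
        rt = set(report.loc[report.model_type == "regression_tree",
                            "top4_variables"].iloc[0].split(", "))
        rf = set(report.loc[report.model_type == "random_forest",
                            "top4_variables"].iloc[0].split(", "))
        flagged = set(report["important_in_both"].iloc[0].split(", "))
        assert flagged == (rt & rf)
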