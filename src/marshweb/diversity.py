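"""Topological determinants of within-host parasite diversity.

The response is a host's parasite richness; the predictors are the nine
topological descriptors of the host's position in its food web:
eigenvector centrality, betweenness, closeness, degree, group
membership, coreness, marsh diversity (the species richness of the
host's web), trophic generality G and trophic vulnerability V.

Two models are fit:

* a CART regression tree with cost-complexity pruning, the pruned size
  chosen by K-fold cross-validation (1-SE rule by default);
* a random forest (default 1000 trees, mtry = ceil(p/3)) whose fit is
  summarised by the out-of-bag pseudo-R^2 and two variable-importance
  measures — the permutation increase in out-of-bag MSE, and the mean
  decrease in node impurity.

Group membership is an unordered categorical; levels are web-qualified
(group 3 of one marsh is unrelated to group 3 of another) and one-hot
encoded for the split search, with the one-hot importances summed back
into a single "group" predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .webio import FoodWeb

__all__ = [
    "PREDICTORS",
    "build_predictor_table",
    "FittedTree",
    "FittedForest",
    "fit_regression_tree",
    "fit_random_forest",
    "importance_report",
]

PREDICTORS = ("eigenvector", "betweenness", "closeness", "degree", "group",
              "coreness", "marsh_diversity", "G", "V")
_NUMERIC = tuple(p for p in PREDICTORS if p != "group")
RESPONSE = "richness"


def build_predictor_table(webs, centrality, coreness, groups, gv, incidence
                          ) -> pd.DataFrame:
    """Join the per-species metric tables into the model design table.

    Parameters are all keyed by (web, label): ``centrality`` has columns
    eigenvector/betweenness/closeness/degree, ``coreness`` a coreness
    column, ``groups`` a group column, ``gv`` G and V, ``incidence``
    host richness (host column named ``host`` or ``label``).  ``webs``
    is the list of :class:`FoodWeb` objects, used for marsh diversity
    and completeness checks.  Any web species missing any metric is a
    hard error.
    """
    incidence = incidence.rename(columns={"host": "label"})
    parts = {"centrality": centrality, "coreness": coreness,
             "groups": groups, "gv": gv, "incidence": incidence}
    merged = None
    for name, df in parts.items():
        if "web" not in df.columns or "label" not in df.columns:
            raise ValueError(f"{name} table must be keyed by (web, label)")
        merged = df if merged is None else merged.merge(
            df, on=["web", "label"], how="inner")
    sizes = {w.name: w.n_species for w in webs}
    for w in webs:
        have = set(merged.loc[merged["web"] == w.name, "label"])
        missing = [lbl for lbl in w.labels if lbl not in have]
        if missing:
            raise ValueError(
                f"web {w.name!r}: species missing a metric: {missing[:5]}"
                + ("..." if len(missing) > 5 else ""))
    merged["marsh_diversity"] = merged["web"].map(sizes)
    # web-qualified categorical group levels
    merged["group"] = merged["web"].astype(str) + ":" + merged["group"].astype(str)
    cols = ["web", "label", *PREDICTORS, RESPONSE]
    return merged[cols].reset_index(drop=True)


# -- design matrix -----------------------------------------------------------

@dataclass(frozen=True)
class _Design:
    """Numeric design matrix with the group factor one-hot encoded."""
    columns: tuple[str, ...]
    group_levels: tuple[str, ...]
    #: map predictor name -> list of column indices in the matrix
    blocks: dict = field(default_factory=dict)

    @classmethod
    def from_table(cls, rows: pd.DataFrame) -> "_Design":
        levels = tuple(sorted(rows["group"].astype(str).unique()))
        columns = list(_NUMERIC) + [f"group={lv}" for lv in levels]
        blocks = {p: [columns.index(p)] for p in _NUMERIC}
        blocks["group"] = [columns.index(f"group={lv}") for lv in levels]
        return cls(columns=tuple(columns), group_levels=levels, blocks=blocks)

    def matrix(self, rows: pd.DataFrame) -> np.ndarray:
        X = np.zeros((len(rows), len(self.columns)))
        for j, p in enumerate(_NUMERIC):
            X[:, j] = rows[p].to_numpy(dtype=float)
        grp = rows["group"].astype(str).to_numpy()
        base = len(_NUMERIC)
        for k, lv in enumerate(self.group_levels):
            X[:, base + k] = grp == lv
        return X

    def collapse(self, per_column: np.ndarray) -> pd.Series:
        """Sum per-column scores into per-predictor scores."""
        return pd.Series(
            {p: float(per_column[idx].sum()) for p, idx in self.blocks.items()},
            name="importance")[list(PREDICTORS)]


def _check_rows(rows: pd.DataFrame, min_rows: int = 20) -> None:
    if len(rows) < min_rows:
        raise ValueError(f"need >= {min_rows} rows, got {len(rows)}")
    y = rows[RESPONSE].to_numpy()
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("response must be non-negative integer richness")
    missing = [p for p in (*PREDICTORS, RESPONSE) if p not in rows.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if rows[list(_NUMERIC)].isna().any().any():
        raise ValueError("predictor table contains missing values")


# -- regression tree ---------------------------------------------------------

@dataclass
class FittedTree:
    estimator: DecisionTreeRegressor
    design: _Design
    pseudo_r2: float
    importance: pd.Series
    cp_alpha: float
    cp_path: pd.DataFrame
    n_leaves: int
    seed: int | None

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self.design.matrix(rows))


def fit_regression_tree(rows: pd.DataFrame, cv_folds: int = 10,
                        seed: int | None = None,
                        rule: str = "1se") -> FittedTree:
    """CART with squared-error loss and cost-complexity pruning.

    The pruning strength alpha is chosen by ``cv_folds``-fold
    cross-validation: either the smallest tree within one standard
    error of the CV-minimum (``rule="1se"``, default) or the CV minimum
    itself (``rule="min"``).  ``pseudo_r2`` is the training
    ``1 - SSE/SST``; importance is each variable's summed squared-error
    reduction over all splits (normalised to sum to 1), with the group
    one-hot block reported as one predictor.
    """
    _check_rows(rows)
    if rule not in ("1se", "min"):
        raise ValueError("rule must be '1se' or 'min'")
    design = _Design.from_table(rows)
    X = design.matrix(rows)
    y = rows[RESPONSE].to_numpy(dtype=float)

    if np.allclose(y, y[0]):  # constant response: stump, R^2 = 0
        est = DecisionTreeRegressor(max_depth=1, random_state=seed).fit(X, y)
        return FittedTree(estimator=est, design=design, pseudo_r2=0.0,
                          importance=design.collapse(np.zeros(X.shape[1])),
                          cp_alpha=0.0,
                          cp_path=pd.DataFrame({"alpha": [0.0], "cv_mse": [0.0],
                                                "cv_se": [0.0]}),
                          n_leaves=1, seed=seed)

    path = DecisionTreeRegressor(random_state=seed).cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.maximum(path.ccp_alphas, 0.0))
    # evaluate at geometric midpoints so each candidate selects a distinct subtree
    cand = [0.0] + [float(np.sqrt(a * b)) if a > 0 else (a + b) / 2
                    for a, b in zip(alphas[:-1], alphas[1:])] + [float(alphas[-1])]
    cand = sorted(set(cand))

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_mse = np.zeros((cv_folds, len(cand)))
    for f, (tr, te) in enumerate(kf.split(X)):
        for a_i, alpha in enumerate(cand):
            m = DecisionTreeRegressor(ccp_alpha=alpha, random_state=seed)
            m.fit(X[tr], y[tr])
            resid = y[te] - m.predict(X[te])
            fold_mse[f, a_i] = float(resid @ resid) / len(te)
    cv_mean = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    i_min = int(np.argmin(cv_mean))
    if rule == "min":
        alpha = cand[i_min]
    else:
        thresh = cv_mean[i_min] + cv_se[i_min]
        within = [i for i in range(len(cand)) if cv_mean[i] <= thresh]
        alpha = cand[max(within)]  # largest alpha = smallest tree within 1 SE

    est = DecisionTreeRegressor(ccp_alpha=alpha, random_state=seed).fit(X, y)
    resid = y - est.predict(X)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / sst
    imp = design.collapse(est.feature_importances_)
    cp_path = pd.DataFrame({"alpha": cand, "cv_mse": cv_mean, "cv_se": cv_se})
    return FittedTree(estimator=est, design=design, pseudo_r2=r2,
                      importance=imp, cp_alpha=float(alpha), cp_path=cp_path,
                      n_leaves=int(est.get_n_leaves()), seed=seed)


# -- random forest -----------------------------------------------------------

@dataclass
class FittedForest:
    estimator: RandomForestRegressor
    design: _Design
    pseudo_r2: float
    importance: pd.Series            # permutation (OOB) measure
    impurity_importance: pd.Series   # mean decrease in node impurity
    n_trees: int
    mtry: int
    seed: int | None

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self.design.matrix(rows))


def _bootstrap_indices(tree_random_state: int, n: int) -> np.ndarray:
    # replicates sklearn's per-tree bootstrap draw (RandomState.randint);
    # validated in the test suite against forest.oob_prediction_
    rs = np.random.RandomState(tree_random_state)
    return rs.randint(0, n, n)


def fit_random_forest(rows: pd.DataFrame, n_trees: int = 1000,
                      seed: int | None = None,
                      mtry: int | None = None) -> FittedForest:
    """Bootstrap-aggregated regression trees with OOB diagnostics.

    ``pseudo_r2`` is the out-of-bag ``1 - MSE_oob / Var(y)``.  The
    primary importance is the permutation measure: for each tree, each
    predictor (the group one-hot block is permuted jointly) is shuffled
    among that tree's out-of-bag rows and the increase in OOB MSE is
    averaged over trees.  The impurity measure (mean decrease in node
    impurity) is reported alongside.
    """
    _check_rows(rows)
    if n_trees < 50:
        warnings.warn("fewer than 50 trees: importance estimates are unstable")
    design = _Design.from_table(rows)
    X = design.matrix(rows)
    y = rows[RESPONSE].to_numpy(dtype=float)
    n, p_cols = X.shape
    if mtry is None:
        mtry = int(np.ceil(len(PREDICTORS) / 3))
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry, bootstrap=True,
        oob_score=True, random_state=seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny-n OOB coverage warnings
        forest.fit(X, y)

    var_y = float(y.var())
    r2 = float(forest.oob_score_) if var_y > 0 else 0.0

    rng = np.random.default_rng(seed)
    blocks = list(design.blocks.items())
    increases = np.zeros(len(blocks))
    for tree in forest.estimators_:
        boot = _bootstrap_indices(tree.random_state, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if len(oob) < 2:
            continue
        Xo = X[oob]
        base_mse = float(np.mean((y[oob] - tree.predict(Xo)) ** 2))
        for b, (name, cols) in enumerate(blocks):
            perm = rng.permutation(len(oob))
            Xp = Xo.copy()
            Xp[:, cols] = Xo[np.ix_(perm, cols)]
            mse = float(np.mean((y[oob] - tree.predict(Xp)) ** 2))
            increases[b] += mse - base_mse
    increases /= n_trees
    perm_imp = pd.Series({name: increases[b] for b, (name, _) in
                          enumerate(blocks)})[list(PREDICTORS)]
    impurity = design.collapse(forest.feature_importances_)
    return FittedForest(estimator=forest, design=design, pseudo_r2=r2,
                        importance=perm_imp, impurity_importance=impurity,
                        n_trees=n_trees, mtry=mtry, seed=seed)


# -- reporting ---------------------------------------------------------------

def importance_report(models: dict) -> pd.DataFrame:
    """Per-model top-4 importance ranking, Table-3 style.

    ``models`` maps ``(model_type, site)`` (e.g. ``("regression_tree",
    "all")``) to a fitted model.  A variable is flagged
    ``important_in_both`` for a site when it is in the top 4 of both the
    tree and forest models of that site.
    """
    rows = []
    top4: dict = {}
    for (model_type, site), fitted in models.items():
        ranking = fitted.importance.sort_values(ascending=False)
        top = list(ranking.index[:4])
        top4[(model_type, site)] = set(top)
        rows.append({"model_type": model_type, "site": site,
                     "r2": round(100.0 * fitted.pseudo_r2, 2),
                     "top4_variables": ", ".join(top)})
    report = pd.DataFrame(rows)
    both = []
    for row in report.itertuples():
        other = {"regression_tree": "random_forest",
                 "random_forest": "regression_tree"}.get(row.model_type)
        key = (other, row.site)
        mine = top4[(row.model_type, row.site)]
        both.append(", ".join(sorted(mine & top4[key])) if key in top4 else "")
    report["important_in_both"] = both
    return report
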