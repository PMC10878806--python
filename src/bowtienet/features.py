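"""Per-page features and the fan-count-change prediction harness.

Features are computed on the early snapshot for anti- and pro- pages only
(neutral pages are excluded as rows but fully included in every sum over
neighbours): polarity, community assignment, the two reduced bow-tie
roles (within-group and across-group), the raw fan count, weighted in-
and out-degree, same-polarity and same-community recommendation-strength
proportions, weighted PageRank and weighted betweenness.

The harness mirrors a standard protocol: a class-weighted logistic
classifier for expansion vs non-expansion, support-vector and
random-forest regression of the raw fan-count change on three page
strata (all / expanding / non-expanding), and feature assessment via
Pearson correlation, averaged mutual information and sequential forward
floating selection (SFFS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import mutual_info_regression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    confusion_matrix,
    mean_absolute_error,
    mean_squared_error,
    r2_score,
)
from sklearn.model_selection import (
    GridSearchCV,
    KFold,
    StratifiedKFold,
    cross_val_predict,
)
from sklearn.compose import TransformedTargetRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import RobustScaler, StandardScaler
from sklearn.svm import SVR

from .bowtie import UNASSIGNED, NodePartition
from .network import SnapshotNetwork, WEIGHT_FLOOR

logger = logging.getLogger(__name__)

CATEGORICAL_FEATURES = ("p", "c", "w_bt", "a_bt")
NUMERIC_FEATURES = (
    "f", "k_in", "k_out", "kps_in", "kps_out",
    "kcs_in", "kcs_out", "pagerank", "betweenness",
)
ALL_FEATURES = CATEGORICAL_FEATURES + NUMERIC_FEATURES

STRATA = ("all", "expanding", "non-expanding")


@dataclass
class PredictionOutcome:
    """Cross-validated metrics for one model on one stratum."""

    target: str
    stratum: str
    model: str
    metrics: dict
    baseline: dict
    best_params: dict = field(default_factory=dict)
    n: int = 0


def label_expansion(f_early: int, f_late: int) -> int:
    """1 iff the fan count strictly increased (unchanged counts as 0)."""
    return int(f_late > f_early)


# ---------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------

def _betweenness_distances(g: nx.DiGraph) -> nx.DiGraph:
    h = g.copy()
    for u, v, w in h.edges(data="weight"):
        h.edges[u, v]["dist"] = 1.0 / max(w, WEIGHT_FLOOR)
    return h


def compute_features(
    net_early: SnapshotNetwork,
    roles_within: Mapping,
    roles_across: Mapping,
    communities: NodePartition,
    weighted_centralities: bool = True,
) -> pd.DataFrame:
    """Feature table for the anti- and pro- pages of the early snapshot.

    Proportions use edge weights, not edge counts.  A page with zero
    weighted in-degree (no recommenders, or only zero-fan ones) gets
    in-proportions 0 and its ``degenerate_in`` flag set; likewise for the
    out direction.  Nodes in UNASSIGNED communities never match anyone's
    community, including each other.
    """
    g = net_early.graph
    pols = net_early.polarity
    fans = net_early.fan_count
    comm = communities.community

    if weighted_centralities:
        pagerank = nx.pagerank(g, weight="weight")
        betweenness = nx.betweenness_centrality(
            _betweenness_distances(g), weight="dist"
        )
    else:
        pagerank = nx.pagerank(g, weight=None)
        betweenness = nx.betweenness_centrality(g, weight=None)

    def same_comm(i, j) -> bool:
        return comm[i] == comm[j] and comm[i] != UNASSIGNED

    rows = []
    for i in net_early.nodes:
        if pols[i] == "g":
            continue
        k_in = k_out = 0.0
        ps_in = ps_out = cs_in = cs_out = 0.0
        for j, _ in g.in_edges(i):
            w = g.edges[j, i]["weight"]
            k_in += w
            if pols[j] == pols[i]:
                ps_in += w
            if same_comm(i, j):
                cs_in += w
        for _, j in g.out_edges(i):
            w = g.edges[i, j]["weight"]
            k_out += w
            if pols[j] == pols[i]:
                ps_out += w
            if same_comm(i, j):
                cs_out += w
        degenerate_in = k_in == 0
        degenerate_out = k_out == 0
        rows.append(
            {
                "page": i,
                "p": pols[i],
                "c": comm[i],
                "w_bt": roles_within[i],
                "a_bt": roles_across[i],
                "f": fans[i],
                "k_in": k_in,
                "k_out": k_out,
                "kps_in": 0.0 if degenerate_in else ps_in / k_in,
                "kps_out": 0.0 if degenerate_out else ps_out / k_out,
                "kcs_in": 0.0 if degenerate_in else cs_in / k_in,
                "kcs_out": 0.0 if degenerate_out else cs_out / k_out,
                "pagerank": pagerank[i],
                "betweenness": betweenness[i],
                "degenerate_in": degenerate_in,
                "degenerate_out": degenerate_out,
            }
        )
    return pd.DataFrame(rows).set_index("page")


def feature_matrix(
    features: pd.DataFrame,
    include: Sequence[str] = ALL_FEATURES,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: one-hot categoricals, log1p fan counts.

    Returns the matrix and its column names.  The raw fan count enters as
    ``log(1 + f)`` because zero-fan pages exist.
    """
    blocks = []
    names: list[str] = []
    for feat in include:
        if feat in CATEGORICAL_FEATURES:
            d = pd.get_dummies(features[feat], prefix=feat)
            blocks.append(d.to_numpy(dtype=float))
            names.extend(d.columns)
        elif feat == "f":
            blocks.append(
                np.log1p(features["f"].to_numpy(dtype=float))[:, None]
            )
            names.append("log1p_f")
        else:
            blocks.append(features[feat].to_numpy(dtype=float)[:, None])
            names.append(feat)
    return np.hstack(blocks), names


def _stratum_mask(delta_f: np.ndarray, stratum: str) -> np.ndarray:
    if stratum == "all":
        return np.ones(len(delta_f), dtype=bool)
    if stratum == "expanding":
        return delta_f > 0
    if stratum == "non-expanding":
        return delta_f <= 0
    raise ValueError(f"unknown stratum {stratum!r}")


# ---------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------

#: grid-search space for the logistic classifier (inverse regularization)
LR_GRID = {"clf__C": [0.01, 0.1, 1.0, 10.0, 100.0]}


def classify_expansion(
    features: pd.DataFrame,
    labels: Sequence[int],
    cv_folds: int = 5,
    seed: int | None = None,
) -> PredictionOutcome:
    """Class-weighted logistic classification of expansion vs not.

    Regularization strength is grid-searched with accuracy as the
    optimized metric; sensitivity and specificity (label 1 = expanding)
    come from out-of-fold predictions at the selected strength.  The
    baseline assigns each class with equal probability.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X, _ = feature_matrix(features)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(
                class_weight="balanced", max_iter=5000
            )),
        ]
    )
    search = GridSearchCV(pipe, LR_GRID, scoring="accuracy", cv=cv)
    search.fit(X, y)
    y_hat = cross_val_predict(search.best_estimator_, X, y, cv=cv)

    def cls_metrics(y_true, y_pred) -> dict:
        tn, fp, fn, tp = confusion_matrix(
            y_true, y_pred, labels=[0, 1]
        ).ravel()
        return {
            "accuracy": (tp + tn) / len(y_true),
            "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
        }

    rng = np.random.default_rng(seed)
    y_base = rng.integers(0, 2, size=len(y))
    return PredictionOutcome(
        target="expansion",
        stratum="all",
        model="logistic",
        metrics=cls_metrics(y, y_hat),
        baseline=cls_metrics(y, y_base),
        best_params=search.best_params_,
        n=len(y),
    )


# ---------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------

SVR_GRID = {
    "regressor__model__kernel": ["linear", "rbf"],
    "regressor__model__C": [1.0, 10.0, 100.0],
    "regressor__model__epsilon": [0.001, 0.01, 0.1],
}
RFR_GRID = {
    "model__n_estimators": [100],
    "model__max_depth": [None, 10],
    "model__min_samples_leaf": [1, 5],
}


def _make_regressor(model: str, seed: int | None):
    if model == "svr":
        # iteration cap: libsvm can stall on heavy-tailed targets
        pipe = Pipeline(
            [("scale", StandardScaler()), ("model", SVR(max_iter=100_000))]
        )
        # robust target scaling keeps the C/epsilon grid meaningful
        # for heavy-tailed fan-count changes (a few mega pages dominate
        # the variance, so standard scaling would crush the bulk)
        est = TransformedTargetRegressor(
            regressor=pipe, transformer=RobustScaler()
        )
        return est, SVR_GRID
    if model == "rfr":
        pipe = Pipeline(
            [("model", RandomForestRegressor(random_state=seed))]
        )
        return pipe, RFR_GRID
    raise ValueError(f"unknown regression model {model!r}")


def regress_variation(
    features: pd.DataFrame,
    delta_f: Sequence[float],
    stratum: str = "all",
    model: str = "svr",
    cv_folds: int = 5,
    seed: int | None = None,
) -> PredictionOutcome:
    """Cross-validated regression of the raw fan-count change.

    The stratum filter is applied before fitting; mean absolute error is
    the optimized metric, with R-squared and RMSE reported alongside.
    The baseline predicts the training-fold mean.
    """
    dfv = np.asarray(delta_f, dtype=float)
    mask = _stratum_mask(dfv, stratum)
    if mask.sum() < 2 * cv_folds:
        raise ValueError(
            f"stratum {stratum!r} has {int(mask.sum())} rows, "
            f"need at least {2 * cv_folds}"
        )
    X, _ = feature_matrix(features)
    X, y = X[mask], dfv[mask]
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    est, grid = _make_regressor(model, seed)
    search = GridSearchCV(
        est, grid, scoring="neg_mean_absolute_error", cv=cv
    )
    search.fit(X, y)
    y_hat = cross_val_predict(search.best_estimator_, X, y, cv=cv)
    y_base = cross_val_predict(DummyRegressor(strategy="mean"), X, y, cv=cv)

    def reg_metrics(y_true, y_pred) -> dict:
        return {
            "mae": mean_absolute_error(y_true, y_pred),
            "r2": r2_score(y_true, y_pred),
            "rmse": float(
                np.sqrt(mean_squared_error(y_true, y_pred))
            ),
        }

    return PredictionOutcome(
        target="delta_f",
        stratum=stratum,
        model=model,
        metrics=reg_metrics(y, y_hat),
        baseline=reg_metrics(y, y_base),
        best_params=search.best_params_,
        n=int(mask.sum()),
    )


# ---------------------------------------------------------------------
# feature assessment: CC, MI, SFFS
# ---------------------------------------------------------------------

def _sffs(
    block_names: list[str],
    block_arrays: dict,
    y: np.ndarray,
    estimator_factory,
    k_target: int,
    cv: KFold,
) -> list[str]:
    """Sequential forward floating selection of ``k_target`` blocks.

    Greedy forward additions minimising cross-validated MAE, each
    followed by conditional backward removals while they strictly improve
    the score.  Categorical one-hot columns move as a single block.
    """
    from sklearn.model_selection import cross_val_score

    def score(selected: list[str]) -> float:
        X = np.hstack([block_arrays[b] for b in selected])
        vals = cross_val_score(
            estimator_factory(), X, y,
            scoring="neg_mean_absolute_error", cv=cv,
        )
        return -float(vals.mean())  # MAE, lower is better

    selected: list[str] = []
    best_scores: dict[int, float] = {}
    while len(selected) < k_target:
        candidates = [b for b in block_names if b not in selected]
        trial = [(score(selected + [b]), b) for b in candidates]
        s_add, b_add = min(trial)
        selected.append(b_add)
        best_scores[len(selected)] = s_add
        # floating backward step
        improved = True
        while improved and len(selected) > 2:
            improved = False
            for b in list(selected[:-1]):
                rest = [x for x in selected if x != b]
                s = score(rest)
                if s < best_scores.get(len(rest), np.inf):
                    selected = rest
                    best_scores[len(rest)] = s
                    improved = True
                    break
    return selected


def rank_features(
    features: pd.DataFrame,
    delta_f: Sequence[float],
    labels: Sequence[int] | None = None,
    n_runs: int = 50,
    sffs_subset: int = 10,
    seed: int | None = None,
    include_mi: bool = True,
    include_sffs: bool = True,
    sffs_cv_folds: int = 5,
) -> pd.DataFrame:
    """Per-feature assessment against the fan-count change.

    Pearson correlation (numeric features only, per stratum), mutual
    information averaged over ``n_runs`` seeded estimator runs (all
    features, per stratum), and — on the expanding stratum — SFFS
    selection frequencies out of ``n_runs`` runs for both regression
    models.  Zero-variance features get correlation 0 and a flag.
    """
    dfv = np.asarray(delta_f, dtype=float)
    rows = {
        feat: {"feature": feat, "zero_variance": False}
        for feat in ALL_FEATURES
    }

    for stratum in STRATA:
        mask = _stratum_mask(dfv, stratum)
        y = dfv[mask]
        sub = features.iloc[mask]
        if len(y) < 5:
            logger.warning(
                "stratum %s has %d rows; skipped", stratum, len(y)
            )
            for feat in ALL_FEATURES:
                rows[feat][f"cc_{stratum}"] = np.nan
                rows[feat][f"mi_{stratum}"] = np.nan
            continue
        for feat in NUMERIC_FEATURES:
            x = sub[feat].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows[feat][f"cc_{stratum}"] = 0.0
                rows[feat]["zero_variance"] = True
            else:
                rows[feat][f"cc_{stratum}"] = float(
                    stats.pearsonr(x, y).statistic
                )

        if include_mi:
            X_num = np.column_stack(
                [sub[f].to_numpy(dtype=float) for f in NUMERIC_FEATURES]
            )
            X_cat = np.column_stack(
                [
                    sub[f].astype("category").cat.codes.to_numpy()
                    for f in CATEGORICAL_FEATURES
                ]
            )
            X_mi = np.hstack([X_num, X_cat])
            discrete = np.array(
                [False] * len(NUMERIC_FEATURES)
                + [True] * len(CATEGORICAL_FEATURES)
            )
            mi_acc = np.zeros(X_mi.shape[1])
            for run in range(n_runs):
                mi_acc += mutual_info_regression(
                    X_mi, y, discrete_features=discrete,
                    random_state=None if seed is None else seed + run,
                )
            mi_mean = mi_acc / n_runs
            order = list(NUMERIC_FEATURES) + list(CATEGORICAL_FEATURES)
            for feat, v in zip(order, mi_mean):
                rows[feat][f"mi_{stratum}"] = float(v)

    if include_sffs:
        mask = _stratum_mask(dfv, "expanding")
        y = dfv[mask]
        sub = features.iloc[mask]
        block_arrays: dict = {}
        for feat in ALL_FEATURES:
            arr, _ = feature_matrix(sub, include=[feat])
            block_arrays[feat] = arr
        factories = {
            "svr": lambda: TransformedTargetRegressor(
                regressor=Pipeline(
                    [("scale", StandardScaler()),
                     ("model", SVR(max_iter=20_000))]
                ),
                transformer=RobustScaler(),
            ),
            "rfr": lambda: RandomForestRegressor(
                n_estimators=50, random_state=0, n_jobs=1
            ),
        }
        for model, factory in factories.items():
            freq = {feat: 0 for feat in ALL_FEATURES}
            for run in range(n_runs):
                cv = KFold(
                    n_splits=sffs_cv_folds, shuffle=True,
                    random_state=None if seed is None else seed + 1000 + run,
                )
                chosen = _sffs(
                    list(ALL_FEATURES), block_arrays, y, factory,
                    min(sffs_subset, len(ALL_FEATURES)), cv,
                )
                for feat in chosen:
                    freq[feat] += 1
            for feat in ALL_FEATURES:
                rows[feat][f"sffs_{model}"] = freq[feat]

    out = pd.DataFrame(list(rows.values())).set_index("feature")
    return out
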