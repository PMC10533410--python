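"""Multivariate response prediction and variable importance.

Workflow: drop near-constant features (≤ 6 unique values), collapse
groups of highly correlated features (Spearman ρ > 0.95, Louvain
communities on the correlation graph, one random representative each),
then

* **repeated_split_auc** — L1-regularized logistic regression with the
  shrinkage strength chosen by internal cross-validation, evaluated on
  100 random stratified 75/25 train/test splits; reports the per-repeat
  test AUCs, their mean and a 2.5/97.5-percentile 95% CI.
* **shadow_feature_importance** — Boruta-style selection: every predictor
  is duplicated as a randomly permuted "shadow"; a random forest is fit
  to the doubled matrix, feature importance is the out-of-bag permutation
  increase in misclassification averaged over trees and scaled by its
  standard error; a real feature scores a hit when it beats the best
  shadow. Hits over many runs are tested against Binomial(n_runs, 0.5),
  one-sided, with Bonferroni correction (P < 0.01 default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

#: features must show more unique values than this to be retained
MIN_UNIQUE_VALUES = 6

CORRELATION_THRESHOLD = 0.95


def filter_low_variability(
    features: pd.DataFrame, min_unique: int = MIN_UNIQUE_VALUES
) -> pd.DataFrame:
    """Keep only columns with more than ``min_unique`` distinct values."""
    nuniq = features.nunique(dropna=True)
    keep = nuniq[nuniq > min_unique].index
    if len(keep) == 0:
        raise ValueError("no feature shows enough distinct values")
    return features[list(keep)]


def prune_correlated(
    features: pd.DataFrame,
    threshold: float = CORRELATION_THRESHOLD,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Collapse groups of near-duplicate features.

    Builds a graph joining features with Spearman ρ strictly above the
    threshold (edges weighted by ρ), partitions it with Louvain community
    detection, and keeps one seeded-random representative per community.
    Features with no strong correlation are always retained. Returns the
    reduced table and a representative → community-members map.
    """
    if features.shape[1] < 2:
        return features, {c: [c] for c in features.columns}
    rho = features.corr(method="spearman")
    cols = list(features.columns)
    G = nx.Graph()
    G.add_nodes_from(cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = rho.loc[a, b]
            if np.isfinite(r) and r > threshold:
                G.add_edge(a, b, weight=float(r))
    communities = nx.community.louvain_communities(G, weight="weight", seed=seed)
    rng = np.random.default_rng(seed)
    cluster_map: dict[str, list[str]] = {}
    kept = []
    for comm in sorted(communities, key=lambda c: sorted(c)[0]):
        members = sorted(comm)
        rep = members[int(rng.integers(len(members)))]
        kept.append(rep)
        cluster_map[rep] = members
    kept = [c for c in cols if c in set(kept)]  # preserve column order
    return features[kept], cluster_map


@dataclass
class PredictionRun:
    arm: str
    timepoints: tuple[str, ...]
    n_repeats: int
    train_frac: float
    aucs: np.ndarray
    retained_features: list[str]
    cluster_map: dict[str, list[str]]
    seed: int
    n_samples: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.aucs, 2.5)),
            float(np.percentile(self.aucs, 97.5)),
        )


def repeated_split_auc(
    features: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    n_repeats: int = 100,
    train_frac: float = 0.75,
    seed: int = 0,
    arm: str = "",
    timepoints: tuple[str, ...] = (),
    cv_folds: int = 5,
    Cs: int = 15,
) -> PredictionRun:
    """Repeated stratified-split lasso-logistic test AUC.

    Each repeat draws a stratified 75/25 split (responder proportion
    approximately balanced), standardizes on the training fold, fits an
    L1 logistic regression with the shrinkage factor minimizing
    cross-validated deviance, and scores the held-out quarter by ROC AUC.
    Tumours with any missing feature are dropped (complete case, logged).
    Deterministic for a given (seed, data).
    """
    y = np.asarray(outcome, dtype=int)
    X = features.to_numpy(dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    if (~complete).sum():
        logger.info("dropping %d tumours with missing features", int((~complete).sum()))
    X, y = X[complete], y[complete]
    if min((y == 0).sum(), (y == 1).sum()) < 10:
        raise ValueError("need at least 10 samples per outcome class")
    aucs = np.empty(n_repeats)
    for rep in range(n_repeats):
        sub = seed + 1000 * rep
        for attempt in range(10):
            Xtr, Xte, ytr, yte = train_test_split(
                X,
                y,
                train_size=train_frac,
                stratify=y,
                random_state=(sub + attempt) % (2**32),
            )
            if len(np.unique(yte)) == 2 and len(np.unique(ytr)) == 2:
                break
            logger.info("repeat %d: single-class split, redrawing", rep)
        scaler = StandardScaler().fit(Xtr)
        model = LogisticRegressionCV(
            Cs=Cs,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            cv=StratifiedKFold(cv_folds, shuffle=True, random_state=sub % (2**32)),
            max_iter=2000,
            random_state=0,
        ).fit(scaler.transform(Xtr), ytr)
        prob = model.predict_proba(scaler.transform(Xte))[:, 1]
        aucs[rep] = roc_auc_score(yte, prob)
    return PredictionRun(
        arm=arm,
        timepoints=tuple(timepoints),
        n_repeats=n_repeats,
        train_frac=train_frac,
        aucs=aucs,
        retained_features=list(features.columns),
        cluster_map={},
        seed=seed,
        n_samples=int(len(y)),
    )


def _oob_permutation_importance(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_trees: int,
    max_features: str | int = "sqrt",
) -> np.ndarray:
    """Breiman-style scaled permutation importance from a bagged forest.

    Fits ``n_trees`` bootstrap decision trees; for each tree, each
    feature is permuted within the tree's out-of-bag samples and the
    increase in misclassification rate recorded. The importance of a
    feature is its mean increase over trees divided by the standard error
    over trees (0 when the spread is exactly zero).
    """
    n, m = X.shape
    deltas = np.zeros((n_trees, m))
    for b in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) < 2 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_features, random_state=int(rng.integers(2**31))
        ).fit(X[boot], y[boot])
        base_err = np.mean(tree.predict(X[oob]) != y[oob])
        # one stacked predict per tree: all single-feature permutations
        k = len(oob)
        stacked = np.repeat(X[oob][None, :, :], m, axis=0)  # (m, k, m)
        for j in range(m):
            stacked[j, :, j] = X[oob][rng.permutation(k), j]
        preds = tree.predict(stacked.reshape(m * k, m)).reshape(m, k)
        deltas[b] = (preds != y[oob]).mean(axis=1) - base_err
    mean = deltas.mean(axis=0)
    se = deltas.std(axis=0, ddof=1) / np.sqrt(n_trees)
    out = np.zeros(m)
    nz = se > 0
    out[nz] = mean[nz] / se[nz]
    return out


@dataclass
class ImportanceResult:
    feature: str
    hits: int
    n_runs: int
    p_binomial: float
    p_bonferroni: float
    selected: bool
    importance_mean: float
    importance_median: float
    importance_q25: float
    importance_q75: float


def shadow_feature_importance(
    features: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    n_runs: int = 1000,
    n_trees: int = 500,
    seed: int = 0,
    alpha: float = 0.01,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Shadow-feature (Boruta-style) variable importance selection.

    Per run: append a freshly permuted copy of every feature (doubling
    the predictor set), fit a bagged random forest, compute scaled OOB
    permutation importance for every column, and score a *hit* for each
    real feature whose importance exceeds the maximum among all shadows.
    Hit counts over ``n_runs`` are tested one-sided against
    Binomial(n_runs, 0.5); features below ``alpha`` (Bonferroni-corrected
    across features by default) are selected and ranked by their
    importance distribution across runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be ≥ 1")
    y = np.asarray(outcome, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if len(y) < 20:
        raise ValueError("need at least 20 samples")
    X = features.to_numpy(dtype=float)
    n, m = X.shape
    rng = np.random.default_rng(seed)
    hits = np.zeros(m, dtype=int)
    imp_runs = np.empty((n_runs, m))
    for run in range(n_runs):
        shadows = np.column_stack([X[rng.permutation(n), j] for j in range(m)])
        doubled = np.hstack([X, shadows])
        imp = _oob_permutation_importance(doubled, y, rng, n_trees=n_trees)
        real, shadow = imp[:m], imp[m:]
        hits += real > shadow.max()
        imp_runs[run] = real
    p = stats.binom.sf(hits - 1, n_runs, 0.5)
    p_bonf = np.minimum(p * m, 1.0)
    thr = p_bonf if bonferroni else p
    rows = []
    for j, name in enumerate(features.columns):
        rows.append(
            ImportanceResult(
                feature=name,
                hits=int(hits[j]),
                n_runs=n_runs,
                p_binomial=float(p[j]),
                p_bonferroni=float(p_bonf[j]),
                selected=bool(thr[j] < alpha),
                importance_mean=float(imp_runs[:, j].mean()),
                importance_median=float(np.median(imp_runs[:, j])),
                importance_q25=float(np.percentile(imp_runs[:, j], 25)),
                importance_q75=float(np.percentile(imp_runs[:, j], 75)),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values("importance_median", ascending=False).reset_index(drop=True)


def prepare_feature_matrix(
    feature_table: pd.DataFrame,
    min_unique: int = MIN_UNIQUE_VALUES,
    threshold: float = CORRELATION_THRESHOLD,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Variability filter + correlation pruning, in the standard order."""
    filtered = filter_low_variability(feature_table, min_unique=min_unique)
    return prune_correlated(filtered, threshold=threshold, seed=seed)
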