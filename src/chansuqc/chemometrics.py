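"""Origin-discriminating chemometrics for venom content/peak-area matrices.

Implements the multivariate toolbox the QC workflow applies to the
samples x features matrix: per-feature Kruskal-Wallis origin testing
(chi-square approximation, with an exact permutation mode for small N),
PCA, OPLS-DA with cross-validated R2Y/Q2, and Euclidean/average-linkage
(UPGMA) hierarchical clustering with a leaf-ordered heatmap matrix.

OPLS-DA follows the orthogonal-signal-correction formulation: components
orthogonal to the one-hot class response are stripped from X, then a
standard PLS2 regression on the filtered matrix provides the predictive
scores.  Q2 = 1 - PRESS/SS is estimated by venetian-blind cross-validation
(every k-th sample per fold), the de facto convention of chemometrics
software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "scale_matrix",
    "KWResult",
    "kruskal_wallis",
    "PCAModel",
    "pca",
    "OPLSDAModel",
    "oplsda",
    "ClusterResult",
    "hclust_heatmap",
]


def scale_matrix(X: np.ndarray, scaling: str = "autoscale") -> np.ndarray:
    """Column scaling: none, center, or autoscale (unit variance)."""
    X = np.asarray(X, float)
    if scaling == "none":
        return X.copy()
    Xc = X - X.mean(axis=0)
    if scaling == "center":
        return Xc
    if scaling == "autoscale":
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return Xc / sd
    raise ValueError(f"unknown scaling {scaling!r}")


# ---------------------------------------------------------------------------
# Kruskal-Wallis


@dataclass
class KWResult:
    h: float
    df: int
    p_value: float
    method: str
    n: int


def _tie_correction(values: np.ndarray) -> float:
    n = len(values)
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - float((counts**3 - counts).sum()) / (n**3 - n)


def _h_from_rank_sums(rank_sums: Sequence[float], sizes: Sequence[int], n: int, tie: float) -> float:
    """Tie-corrected H from per-group rank sums."""
    h = 12.0 / (n * (n + 1)) * sum(r * r / s for r, s in zip(rank_sums, sizes))
    h -= 3 * (n + 1)
    return h / tie if tie else 0.0


def kruskal_wallis(
    values: Sequence[float],
    groups: Sequence,
    method: str = "chi2",
) -> KWResult:
    """Kruskal-Wallis H test of a feature across origin groups.

    ``method='chi2'`` uses the tie-corrected chi-square approximation
    (delegated to scipy); ``method='permutation'`` enumerates every
    distinct assignment of the observations to the group layout (exact,
    guarded to N <= 12) and reports the tail probability of H.
    """
    values = np.asarray(values, float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[labels == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    n = len(values)
    if np.all(values == values[0]):
        return KWResult(0.0, len(uniq) - 1, 1.0, method, n)
    if method == "chi2":
        h, p = stats.kruskal(*samples)
        return KWResult(float(h), len(uniq) - 1, float(p), "chi2", n)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n > 12:
        raise ValueError("exact permutation mode is limited to N <= 12")
    sizes = [len(s) for s in samples]
    ranks = [float(r) for r in stats.rankdata(values)]
    tie = _tie_correction(values)
    obs_sums = [sum(ranks[i] for i in np.flatnonzero(labels == g)) for g in uniq]
    observed = _h_from_rank_sums(obs_sums, sizes, n, tie)
    # enumerate every distinct assignment of observations to the labelled
    # group layout; the rank multiset is fixed, so only rank sums matter
    count_ge = 0
    total = 0

    def _partitions(pool: tuple[int, ...], sizes_left: list[int], sums: list[float]):
        nonlocal count_ge, total
        if not sizes_left:
            total += 1
            if _h_from_rank_sums(sums, sizes, n, tie) >= observed - 1e-12:
                count_ge += 1
            return
        k = sizes_left[0]
        for combo in combinations(pool, k):
            rest = tuple(i for i in pool if i not in combo)
            sums.append(sum(ranks[i] for i in combo))
            _partitions(rest, sizes_left[1:], sums)
            sums.pop()

    _partitions(tuple(range(n)), sizes, [])
    return KWResult(observed, len(uniq) - 1, count_ge / total, "permutation", n)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    scaling: str


def pca(X: np.ndarray, n_components: int = 2, scaling: str = "autoscale") -> PCAModel:
    """PCA of the scaled matrix via eigendecomposition of its covariance."""
    Xs = scale_matrix(X, scaling)
    if n_components > min(Xs.shape[0] - 1, Xs.shape[1]):
        raise ValueError("n_components too large for the matrix")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(Xs)
    return PCAModel(
        scores=scores,
        loadings=model.components_.T,
        explained_variance=model.explained_variance_,
        explained_variance_ratio=model.explained_variance_ratio_,
        scaling=scaling,
    )


# ---------------------------------------------------------------------------
# OPLS-DA


def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    Y = (labels[:, None] == classes[None, :]).astype(float)
    return Y, classes


def _osc_filter(X: np.ndarray, Y: np.ndarray, n_orthogonal: int):
    """Strip Y-orthogonal components from X (O-PLS filtering).

    Returns the filtered matrix and the orthogonal weight/loading pairs
    needed to filter new samples.
    """
    Xf = X.copy()
    W_ortho, P_ortho = [], []
    for _ in range(n_orthogonal):
        # orthonormal basis of the predictive weight subspace span(X'Y)
        u, s, _ = np.linalg.svd(Xf.T @ Y, full_matrices=False)
        W = u[:, s > s[0] * 1e-10]
        w = W[:, 0]
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - W @ (W.T @ p)
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        W_ortho.append(w_o)
        P_ortho.append(p_o)
    return Xf, W_ortho, P_ortho


def _apply_filter(X: np.ndarray, W_ortho, P_ortho) -> np.ndarray:
    Xf = X.copy()
    for w_o, p_o in zip(W_ortho, P_ortho):
        t_o = Xf @ w_o
        Xf = Xf - np.outer(t_o, p_o)
    return Xf


@dataclass
class OPLSDAModel:
    r2y: float
    q2: float
    predictive_scores: np.ndarray
    orthogonal_scores: Optional[np.ndarray]
    classes: np.ndarray
    n_predictive: int
    n_orthogonal: int
    cv_folds: int
    scaling: str
    predicted_class: np.ndarray = field(default=None)  # type: ignore[assignment]


def oplsda(
    X: np.ndarray,
    labels: Sequence,
    n_orthogonal: int = 1,
    cv_folds: int = 7,
    scaling: str = "autoscale",
    n_predictive: Optional[int] = None,
) -> OPLSDAModel:
    """OPLS-DA of a feature matrix against class labels.

    R2Y is the explained fraction of the centered one-hot response on the
    full fit; Q2 = 1 - PRESS/SS from venetian-blind cross-validation in
    which the orthogonal filter and PLS fit are re-estimated per fold.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    Yfull, classes = _one_hot(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n = len(X)
    if cv_folds > n:
        raise ValueError("more CV folds than samples")
    if n_predictive is None:
        n_predictive = max(1, len(classes) - 1)

    def _fit(Xtr, Ytr):
        Xs = scale_matrix(Xtr, scaling)
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        Yc = Ytr - Ytr.mean(axis=0)
        Xf, Wo, Po = _osc_filter(Xs, Yc, n_orthogonal)
        pls = PLSRegression(n_components=n_predictive, scale=False)
        pls.fit(Xf, Yc)
        return (mu, sd, Wo, Po, pls, Ytr.mean(axis=0))

    def _predict(model, Xte):
        mu, sd, Wo, Po, pls, ymean = model
        Xs = (Xte - mu) / sd if scaling == "autoscale" else (
            Xte - mu if scaling == "center" else Xte
        )
        Xf = _apply_filter(Xs, Wo, Po)
        return pls.predict(Xf) + ymean

    full = _fit(X, Yfull)
    Yhat = _predict(full, X)
    Yc = Yfull - Yfull.mean(axis=0)
    ss = float((Yc**2).sum())
    r2y = 1.0 - float(((Yfull - Yhat) ** 2).sum()) / ss

    # venetian blinds: sample i -> fold i % cv_folds
    press = 0.0
    fold_of = np.arange(n) % cv_folds
    for f in range(cv_folds):
        test = fold_of == f
        if not test.any():
            continue
        if len(np.unique(labels[~test])) < len(classes):
            raise ValueError("a CV fold removes an entire class; reduce folds")
        m = _fit(X[~test], Yfull[~test])
        press += float(((Yfull[test] - _predict(m, X[test])) ** 2).sum())
    q2 = 1.0 - press / ss

    mu, sd, Wo, Po, pls, _ = full
    Xs = scale_matrix(X, scaling)
    Xf = _apply_filter(Xs, Wo, Po)
    t_pred = pls.transform(Xf)
    t_orth = np.column_stack([Xs @ w for w in Wo]) if Wo else None
    pred_class = classes[np.argmax(Yhat, axis=1)]
    return OPLSDAModel(
        r2y=r2y,
        q2=q2,
        predictive_scores=t_pred,
        orthogonal_scores=t_orth,
        classes=classes,
        n_predictive=n_predictive,
        n_orthogonal=len(Wo),
        cv_folds=cv_folds,
        scaling=scaling,
        predicted_class=pred_class,
    )


# ---------------------------------------------------------------------------
# hierarchical clustering heatmap


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    heatmap: pd.DataFrame  # leaf-ordered, per-feature min-max scaled
    newick: str

    def cut(self, k: int) -> pd.Series:
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self._sample_ids)

    _sample_ids: list[str] = field(default_factory=list)


def _to_newick(node, names) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _to_newick(node.get_left(), names)
    right = _to_newick(node.get_right(), names)
    return f"({left},{right}):{node.dist:.6g}"


def hclust_heatmap(
    X: pd.DataFrame, scaling_for_distance: str = "none"
) -> ClusterResult:
    """UPGMA (average linkage, Euclidean) clustering with heatmap export.

    The heatmap matrix is the sample-leaf-ordered data with each feature
    min-max scaled to [0, 1] (the dark-blue-to-red convention maps 0 to
    the minimum and 1 to the maximum of the feature).
    """
    if len(X) < 2:
        raise ValueError("need at least 2 samples")
    vals = scale_matrix(X.values, scaling_for_distance)
    Z = linkage(pdist(vals, metric="euclidean"), method="average")
    order = leaves_list(Z)
    ids = [str(i) for i in X.index]
    ordered = X.iloc[order]
    rng = ordered.max(axis=0) - ordered.min(axis=0)
    rng = rng.replace(0, 1.0)
    heat = (ordered - ordered.min(axis=0)) / rng
    tree = to_tree(Z)
    result = ClusterResult(
        linkage_matrix=Z,
        leaf_order=[ids[i] for i in order],
        heatmap=heat,
        newick=_to_newick(tree, ids) + ";",
    )
    result._sample_ids = ids
    return result
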