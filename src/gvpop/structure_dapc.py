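"""Discriminant analysis of principal components (DAPC), from scratch.

The genotype matrix (samples x biallelic SNPs, 0/1 alt-allele indicators,
missing calls mean-imputed per site) is column-centred and decomposed by SVD.
Cluster number is chosen by scoring seeded k-means solutions for K = 1..40
with the k-means BIC

    BIC(K) = n * ln(WSS_K / n) + K * ln(n),

where WSS_K is the total within-cluster sum of squares; the best K minimizes
BIC. The number of retained principal components is chosen by stratified
cross-validation of assignment error (lowest root mean squared error; ties go
to fewer components). The discriminant step maximizes the between/within
group variance ratio on the retained PCs, and assignment probabilities come
from per-group Gaussian densities with pooled covariance in discriminant
space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold

from .variant_filtering import MISSING, VariantMatrix

__all__ = [
    "DapcResult",
    "genotype_matrix",
    "genotype_pca",
    "kmeans_bic",
    "find_clusters",
    "select_n_pca",
    "fit_dapc",
    "dapc_pipeline",
]


@dataclass
class DapcResult:
    n_pca: int
    n_da: int
    scores: np.ndarray  # samples x discriminant axes
    assignment_probs: np.ndarray  # samples x groups
    correct_assignment_rate: float
    group_labels: np.ndarray
    groups: np.ndarray  # distinct group values, column order of assignment_probs
    bic_curve: dict[int, float] = field(default_factory=dict)
    best_k: int | None = None
    loadings: np.ndarray | None = None
    group_means: np.ndarray | None = None
    _pooled_cov_inv: np.ndarray | None = None


def genotype_matrix(matrix: VariantMatrix) -> np.ndarray:
    """Samples x sites 0/1 alt indicator with per-site mean imputation."""
    g = matrix.genotypes.T.astype(float)  # samples x sites
    g[g > 1] = 1.0  # any alt allele counts as alternative
    miss = matrix.genotypes.T == MISSING
    if miss.any():
        col_mean = np.where(
            (~miss).sum(axis=0) > 0,
            np.nansum(np.where(miss, np.nan, g), axis=0)
            / np.maximum((~miss).sum(axis=0), 1),
            0.0,
        )
        g[miss] = np.broadcast_to(col_mean, g.shape)[miss]
    return g


def genotype_pca(matrix: VariantMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-centred PCA of the genotype matrix.

    Returns (scores, eigenvalues); eigenvalues sum to the total (ddof=1)
    variance of the centred matrix, and ``scores @ Vt`` reconstructs it when
    all components are retained.
    """
    X = genotype_matrix(matrix) if isinstance(matrix, VariantMatrix) else np.asarray(matrix, float)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 samples and >= 1 site")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("zero-variance genotype matrix")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    eigenvalues = s**2 / (X.shape[0] - 1)
    return scores, eigenvalues


def kmeans_bic(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """k-means BIC: n * ln(WSS/n) + K * ln(n)."""
    n = X.shape[0]
    K = centers.shape[0]
    wss = float(np.sum((X - centers[labels]) ** 2))
    wss = max(wss, 1e-12)  # duplicate-point degenerate fit
    return n * np.log(wss / n) + K * np.log(n)


def find_clusters(
    scores: np.ndarray,
    k_range: range | list[int] = range(1, 41),
    n_pca: int | None = None,
    restarts: int = 20,
    seed: int = 0,
) -> tuple[dict[int, float], int, np.ndarray]:
    """Score seeded k-means solutions over candidate K by BIC.

    For each K the best of ``restarts`` seeded initializations is kept;
    ``best_k`` minimizes the BIC (ties -> smaller K). K beyond the sample
    count is skipped with a warning.
    """
    X = scores[:, :n_pca] if n_pca is not None else scores
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    bic_curve: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for K in k_range:
        if K > n:
            warnings.warn(f"K={K} exceeds sample count {n}; skipped", stacklevel=2)
            continue
        if K == 1:
            centers = X.mean(axis=0, keepdims=True)
            labels = np.zeros(n, dtype=int)
        else:
            with warnings.catch_warnings():
                # bottlenecked cohorts contain duplicate genotypes; k-means
                # then finds fewer distinct clusters than requested
                from sklearn.exceptions import ConvergenceWarning

                warnings.simplefilter("ignore", ConvergenceWarning)
                km = KMeans(
                    n_clusters=K,
                    n_init=restarts,
                    random_state=int(rng.integers(2**31 - 1)),
                ).fit(X)
            centers, labels = km.cluster_centers_, km.labels_
        bic_curve[K] = kmeans_bic(X, labels, centers)
        labels_by_k[K] = labels
    if not bic_curve:
        raise ValueError("no usable K in k_range")
    best_k = min(bic_curve, key=lambda k: (round(bic_curve[k], 12), k))
    return bic_curve, best_k, labels_by_k[best_k]


def _lda_axes(
    X: np.ndarray, labels: np.ndarray, groups: np.ndarray, n_da: int
) -> np.ndarray:
    """Discriminant axes: generalized eigenvectors of (between, within) scatter."""
    d = X.shape[1]
    overall = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for g in groups:
        Xg = X[labels == g]
        mg = Xg.mean(axis=0)
        Sw += (Xg - mg).T @ (Xg - mg)
        Sb += len(Xg) * np.outer(mg - overall, mg - overall)
    ridge = 1e-8 * max(np.trace(Sw) / d, 1e-12)
    Sw += ridge * np.eye(d)
    evals, evecs = linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    return evecs[:, order[:n_da]]


def fit_dapc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_pca: int,
    n_da: int | None = None,
) -> DapcResult:
    """Fit the discriminant step on retained PCs and score group assignment.

    Assignment probabilities are per-group Gaussian densities with pooled
    covariance (equal priors) in discriminant space; the correct-assignment
    rate is the fraction of samples whose highest-probability group matches
    their a priori label.
    """
    labels = np.asarray(labels)
    groups, group_idx = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("fit_dapc needs >= 2 groups")
    for g in groups:
        if np.sum(labels == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if n_pca < 1:
        raise ValueError("n_pca must be >= 1")
    X = scores[:, :n_pca]
    n_da = min(len(groups) - 1, n_pca) if n_da is None else min(n_da, len(groups) - 1, n_pca)
    W = _lda_axes(X, labels, groups, n_da)
    Z = X @ W
    means = np.vstack([Z[labels == g].mean(axis=0) for g in groups])
    resid = Z - means[group_idx]
    pooled = resid.T @ resid / max(len(Z) - len(groups), 1)
    pooled += 1e-10 * np.eye(n_da)
    inv = np.linalg.inv(pooled)
    d2 = _mahalanobis_sq(Z, means, inv)
    logp = -0.5 * d2
    logp -= logp.max(axis=1, keepdims=True)
    probs = np.exp(logp)
    probs /= probs.sum(axis=1, keepdims=True)
    assigned = probs.argmax(axis=1)
    rate = float(np.mean(assigned == group_idx))
    return DapcResult(
        n_pca=n_pca,
        n_da=n_da,
        scores=Z,
        assignment_probs=probs,
        correct_assignment_rate=rate,
        group_labels=labels,
        groups=groups,
        loadings=W,
        group_means=means,
        _pooled_cov_inv=inv,
    )


def _mahalanobis_sq(Z: np.ndarray, means: np.ndarray, inv: np.ndarray) -> np.ndarray:
    diff = Z[:, None, :] - means[None, :, :]  # n x k x d
    return np.einsum("nkd,de,nke->nk", diff, inv, diff)


def _predict(result: DapcResult, scores_test: np.ndarray) -> np.ndarray:
    Z = scores_test[:, : result.n_pca] @ result.loadings
    d2 = _mahalanobis_sq(Z, result.group_means, result._pooled_cov_inv)
    return result.groups[d2.argmin(axis=1)]


def select_n_pca(
    matrix: VariantMatrix | np.ndarray,
    labels: np.ndarray,
    candidates: list[int] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Choose the retained-PC count by stratified cross-validated RMSE.

    Per candidate, the per-fold misassignment fraction is aggregated as a
    root mean squared error; the candidate with the lowest RMSE wins (ties ->
    fewer components). PCA is refit on each training fold and the held-out
    samples are projected onto the training loadings. Groups with a single
    sample are excluded with a warning.
    """
    X = genotype_matrix(matrix) if isinstance(matrix, VariantMatrix) else np.asarray(matrix, float)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    small = groups[counts < 2]
    if small.size:
        warnings.warn(f"groups with one sample excluded from folds: {small}", stacklevel=2)
        keep = ~np.isin(labels, small)
        X, labels = X[keep], labels[keep]
    n = X.shape[0]
    min_group = int(np.unique(labels, return_counts=True)[1].min())
    folds = max(2, min(folds, min_group))
    max_pc = min(n - max(2, n // folds) - 1, X.shape[1])
    if candidates is None:
        candidates = sorted({c for c in (2, 5, 10, 20, 40, 60, 80, 100) if c <= max_pc} or {max(1, max_pc)})
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors: dict[int, float] = {}
    for c in candidates:
        fold_err = []
        for train, test in skf.split(X, labels):
            Xtr = X[train]
            mean = Xtr.mean(axis=0)
            U, s, Vt = np.linalg.svd(Xtr - mean, full_matrices=False)
            n_pc = min(c, len(s))
            tr_scores = (U * s)[:, :n_pc]
            te_scores = (X[test] - mean) @ Vt[:n_pc].T
            try:
                res = fit_dapc(tr_scores, labels[train], n_pca=n_pc)
            except ValueError:
                continue
            pred = _predict(res, te_scores)
            fold_err.append(float(np.mean(pred != labels[test])))
        if fold_err:
            errors[c] = float(np.sqrt(np.mean(np.square(fold_err))))
    if not errors:
        raise ValueError("cross-validation produced no usable folds")
    best = min(errors, key=lambda c: (round(errors[c], 12), c))
    return best, errors


def dapc_pipeline(
    matrix: VariantMatrix,
    labels: np.ndarray,
    n_pca: int | None = None,
    k_range: range = range(1, 41),
    restarts: int = 20,
    seed: int = 0,
) -> DapcResult:
    """Full pipeline: PCA -> BIC cluster scan -> a priori DAPC fit."""
    scores, _ = genotype_pca(matrix)
    if n_pca is None:
        n_pca, _ = select_n_pca(matrix, labels, seed=seed)
    k_range = range(k_range.start, min(k_range.stop, scores.shape[0]))
    # the cluster scan runs on the full score matrix (all PCs), as the
    # original find.clusters workflow does; n_pca governs the discriminant fit
    bic_curve, best_k, _ = find_clusters(
        scores, k_range=k_range, n_pca=None, restarts=restarts, seed=seed
    )
    result = fit_dapc(scores, labels, n_pca=n_pca)
    result.bic_curve = bic_curve
    result.best_k = best_k
    return result
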