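"""Ordination and classification of shape variables.

PCA establishes overall morphological affinities, the broken-stick rule
decides how many components carry interpretable variance, canonical
variates analysis (CVA) separates a-priori groups (taxonomic family or
locomotor category) with jackknifed classification rates and Mahalanobis
distances, and Ward clustering summarises affinities as a dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.linalg

__all__ = [
    "PcaResult",
    "CvaResult",
    "pca",
    "broken_stick",
    "broken_stick_proportions",
    "cva_fit",
    "cva_classify",
    "ward_cluster",
    "linkage_to_newick",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    eigenvalues: np.ndarray       # non-increasing, >= 0
    proportions: np.ndarray
    scores: np.ndarray            # (n, n_components), zero column means
    loadings: np.ndarray          # (p, n_components), orthonormal columns
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.loadings

    def reconstruct(self, scores: np.ndarray | None = None) -> np.ndarray:
        s = self.scores if scores is None else scores
        return s @ self.loadings.T + self.mean


def pca(X: np.ndarray, scale: bool = False) -> PcaResult:
    """Principal component analysis of the covariance (or correlation) matrix.

    With ``scale=True`` columns are standardized first, i.e. the PCA is of
    the correlation matrix — the convention used for locomotor-mode
    percentage data.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs >= 2 observations")
    mean = X.mean(axis=0)
    Xc = X - mean
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column cannot be scaled to unit variance")
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    keep = min(n - 1, p)
    eig = eig[:keep]
    scores = (U[:, :keep] * s[:keep])
    loadings = Vt[:keep].T
    res = PcaResult(
        eigenvalues=eig,
        proportions=eig / eig.sum() if eig.sum() > 0 else eig,
        scores=scores,
        loadings=loadings,
        mean=mean,
    )
    if scale:
        # fold the scaling into the reported mean/loadings-free transform
        res._sd = sd
        res.transform = lambda Y: ((np.asarray(Y, float) - mean) / sd) @ loadings
    return res


def broken_stick_proportions(p: int) -> np.ndarray:
    """Expected eigenvalue proportions under the broken-stick null.

    ``b_k = (1/p) * sum_{i=k..p} 1/i`` for ``k = 1..p``.
    """
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick(eigenvalues: np.ndarray) -> int:
    """Number of leading PCs whose variance proportion beats the broken stick.

    Returns the length of the initial run of components whose observed
    proportion exceeds the broken-stick expectation; may be 0.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size == 0:
        raise ValueError("need at least one eigenvalue")
    props = eig / eig.sum()
    expected = broken_stick_proportions(len(eig))
    k = 0
    for obs, exp in zip(props, expected):
        if obs > exp:
            k += 1
        else:
            break
    return k


# ---------------------------------------------------------------------------
# CVA
# ---------------------------------------------------------------------------

@dataclass
class CvaResult:
    groups: list[str]
    coefficients: np.ndarray          # (p_reduced, n_axes) canonical coefficients
    scores: np.ndarray                # (n, n_axes) canonical scores
    group_means: np.ndarray           # (g, n_axes) in canonical space
    mahalanobis: np.ndarray           # (g, g) distances between group means
    perm_p: np.ndarray | None         # (g, g) permutation p-values
    confusion: np.ndarray             # (g, g) jackknife confusion matrix
    percent_correct: float
    # internals needed to classify new specimens
    _mean: np.ndarray = None
    _proj: np.ndarray = None          # maps raw variables -> canonical space

    @property
    def n_axes(self) -> int:
        return self.coefficients.shape[1]


def _pc_reduce(X: np.ndarray, variance: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project onto leading PCs capturing ``variance`` of total variance."""
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    nz = var > 1e-12 * var[0] if var.size else var > 0
    var = var[nz]
    keep = int(np.searchsorted(np.cumsum(var) / var.sum(), variance) + 1)
    keep = min(keep, nz.sum())
    return Xc @ Vt[:keep].T, mean, Vt[:keep].T


def _cva_axes(Z: np.ndarray, labels: np.ndarray, groups: list[str]):
    """Canonical axes from the within/between generalized eigenproblem."""
    n, p = Z.shape
    g = len(groups)
    means = np.stack([Z[labels == lab].mean(axis=0) for lab in groups])
    grand = Z.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for gi, lab in enumerate(groups):
        sub = Z[labels == lab] - means[gi]
        W += sub.T @ sub
        ng = (labels == lab).sum()
        d = (means[gi] - grand)[:, None]
        B += ng * (d @ d.T)
    W /= (n - g)
    evals, evecs = scipy.linalg.eigh(B, W)  # ascending; vecs: v' W v = I
    order = np.argsort(evals)[::-1]
    n_axes = min(g - 1, p)
    A = evecs[:, order[:n_axes]]
    return A, W, means


def cva_fit(X: np.ndarray, groups: np.ndarray, n_perm: int = 10_000,
            seed: int | None = 0, pc_variance: float = 0.95,
            jackknife: bool = True) -> CvaResult:
    """Canonical variates analysis with jackknifed classification.

    Variables are first reduced to the PCs holding ``pc_variance`` of the
    variance so the pooled within-group covariance stays invertible.
    Canonical axes maximize the between/within variance ratio; group
    separation is summarized by Mahalanobis distances between group means
    with permutation p-values, and classification accuracy by a
    leave-one-out (jackknife) refit.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(groups)
    group_names = sorted(set(labels.tolist()))
    if len(group_names) < 2:
        raise ValueError("CVA needs >= 2 groups")
    for lab in group_names:
        if (labels == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 specimens")
    Z, mean, P = _pc_reduce(X, pc_variance)
    A, W, means_Z = _cva_axes(Z, labels, group_names)
    scores = Z @ A
    gmeans = means_Z @ A

    Wi = np.linalg.inv(W)

    def mdist(means_Z_):
        g = len(means_Z_)
        D = np.zeros((g, g))
        for i in range(g):
            for j in range(i + 1, g):
                d = means_Z_[i] - means_Z_[j]
                D[i, j] = D[j, i] = np.sqrt(d @ Wi @ d)
        return D

    D = mdist(means_Z)
    perm_p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros_like(D)
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            pm = np.stack([Z[perm == lab].mean(axis=0) for lab in group_names])
            exceed += mdist(pm) >= D
        perm_p = (exceed + 1) / (n_perm + 1)
        np.fill_diagonal(perm_p, 1.0)

    g = len(group_names)
    confusion = np.zeros((g, g), dtype=int)
    if jackknife:
        idx_by_name = {lab: gi for gi, lab in enumerate(group_names)}
        for i in range(len(Z)):
            keep = np.ones(len(Z), dtype=bool)
            keep[i] = False
            sub_labels = labels[keep]
            if min((sub_labels == lab).sum() for lab in group_names) < 2:
                continue
            Ai, Wsub, mi = _cva_axes(Z[keep], sub_labels, group_names)
            zi = Z[i] @ Ai
            d2 = ((mi @ Ai - zi) ** 2).sum(axis=1)
            pred = int(np.argmin(d2))
            confusion[idx_by_name[labels[i]], pred] += 1
    total = confusion.sum()
    pct = 100.0 * np.trace(confusion) / total if total else float("nan")
    return CvaResult(
        groups=group_names, coefficients=A, scores=scores, group_means=gmeans,
        mahalanobis=D, perm_p=perm_p, confusion=confusion, percent_correct=pct,
        _mean=mean, _proj=P @ A,
    )


def cva_classify(fit: CvaResult, X_new: np.ndarray):
    """Classify new specimens from canonical-space Mahalanobis distances.

    Equal priors: the posterior for group *g* is proportional to
    ``exp(-d_g^2 / 2)`` with ``d_g`` the Euclidean distance to the group
    mean in canonical space (where the within-group covariance is the
    identity).  Ties are broken by lexicographic group name.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    z = (X_new - fit._mean) @ fit._proj
    d2 = ((z[:, None, :] - fit.group_means[None, :, :]) ** 2).sum(axis=2)
    # subtract the row minimum for numerical stability
    logp = -0.5 * (d2 - d2.min(axis=1, keepdims=True))
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    labels = [fit.groups[int(np.argmax(row))] for row in post]
    return labels, post


# ---------------------------------------------------------------------------
# Phylomorphospace
# ---------------------------------------------------------------------------

def phylomorphospace(means: np.ndarray, tree, labels: list[str],
                     n_axes: int = 2):
    """Species-mean PCA with ancestral nodes projected into the same space.

    Ancestral states come from the Brownian squared-change-parsimony
    estimator; internal nodes are mapped through the identical PCA
    transform as the tips, so tip coordinates equal the plain PCA scores.
    Returns ``(PcaResult, tip_scores, node_scores, node_ids)``.
    """
    from .comparative import ancestral_bm

    res = pca(means)
    anc = ancestral_bm(means, tree, labels)
    node_scores = res.transform(anc.states)
    return res, res.scores[:, :n_axes], node_scores[:, :n_axes], anc.node_ids


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def ward_cluster(X: np.ndarray, labels: list[str] | None = None) -> np.ndarray:
    """Agglomerative hierarchical clustering, Ward linkage on Euclidean
    distances (Ward.D2: heights on the distance scale).

    Returns a SciPy linkage matrix; merge heights are non-decreasing.
    """
    X = np.asarray(X, dtype=float)
    if len(X) < 2:
        raise ValueError("clustering needs >= 2 rows")
    return sch.linkage(X, method="ward", metric="euclidean")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick string."""
    n = len(labels)

    def render(node: int) -> tuple[str, float]:
        if node < n:
            return labels[node].replace(" ", "_"), 0.0
        row = Z[node - n]
        h = row[2]
        parts = []
        for child in (int(row[0]), int(row[1])):
            txt, ch = render(child)
            parts.append(f"{txt}:{(h - ch) / 2:.10g}")
        return f"({','.join(parts)})", h

    txt, _ = render(2 * n - 2)
    return txt + ";"
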