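"""Multivariate evolutionary-model fitting on a phylogeny.

Fits Brownian motion (BM), early burst (EB) and single/multi-regime
Ornstein-Uhlenbeck (OU) models to species-by-trait matrices, compares them
with the finite-sample Akaike criterion (AICc) using an effective sample
size of species x traits, and paints adaptive regimes onto tree edges by
parsimony from tip categories.

Model conventions
-----------------
* BM/EB: GLS root state, rate matrix ``R`` (p x p, symmetric PD); EB adds
  the exponent ``a <= 0`` scaling the rate by ``exp(a t)``.
* OU: symmetric PD attraction matrix ``alpha`` shared across regimes, a
  per-regime optimum vector ``theta``, and the process started at the root
  regime's optimum (no separate root parameter), so the OU likelihood
  tends to the BM likelihood as ``alpha -> 0``.
* Parameter counts: BM ``p(p+1)/2 + p``; EB one more; OU with m regimes
  ``p(p+1) + p m``.
* ``AICc = -2 logL + 2k + 2k(k+1)/(n_eff - k - 1)`` with
  ``n_eff = n_species * p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .comparative import gls_mean, phylo_transform
from .dataio import PhyloTree

__all__ = [
    "RegimePainting",
    "EvoModelFit",
    "paint_regimes",
    "clade_painting",
    "fit_bm",
    "fit_eb",
    "fit_ou",
    "model_table",
    "aicc",
    "akaike_weights",
    "param_count",
    "bm_covariance",
    "eb_branch_transform",
    "ou_mean_and_cov",
]


# ---------------------------------------------------------------------------
# Regime paintings
# ---------------------------------------------------------------------------

@dataclass
class RegimePainting:
    """Per-edge adaptive-regime labels (edges keyed by child node index)."""

    edge_regime: dict[int, str]
    root_regime: str
    regimes: list[str]

    def __post_init__(self) -> None:
        if self.root_regime not in self.regimes:
            raise ValueError("root regime not in regime list")

    @property
    def n_regimes(self) -> int:
        return len(self.regimes)

    def n_shifts(self) -> int:
        """Number of edges whose regime differs from the parent edge's."""
        count = 0
        for child, reg in self.edge_regime.items():
            parent = self._parent_regime(child)
            if reg != parent:
                count += 1
        return count

    def _parent_regime(self, child: int) -> str:
        return self._parents.get(child, self.root_regime)

    _parents: dict[int, str] = field(default_factory=dict, repr=False)

    def attach_parents(self, tree: PhyloTree) -> "RegimePainting":
        self._parents = {
            c: (self.edge_regime[int(tree.parent[c])]
                if tree.parent[c] != tree.root else self.root_regime)
            for c in self.edge_regime
        }
        return self


def paint_regimes(tree: PhyloTree, tip_states: dict[str, str],
                  method: str = "parsimony") -> RegimePainting:
    """Paint edges from tip categories by Fitch parsimony (ACCTRAN-style).

    Bottom-up Fitch state sets followed by a deterministic top-down pass:
    a node keeps its parent's state when possible, otherwise the
    lexicographically smallest member of its own set.  Each edge takes its
    child node's state, so reciprocally monophyletic categories shift
    exactly on their stem edges.
    """
    if method != "parsimony":
        raise ValueError(f"unknown painting method {method!r}")
    missing = [t for t in tree.tip_labels if t not in tip_states]
    if missing:
        raise ValueError(f"unlabeled tips: {missing}")
    sets: dict[int, frozenset[str]] = {}
    for nd in tree.postorder():
        nd = int(nd)
        if tree.is_tip[nd]:
            sets[nd] = frozenset([tip_states[tree.node_labels[nd]]])
        else:
            child_sets = [sets[c] for c in tree.children[nd]]
            inter = frozenset.intersection(*child_sets)
            sets[nd] = inter if inter else frozenset.union(*child_sets)
    state: dict[int, str] = {}
    for nd in range(tree.n_nodes):
        if nd == tree.root:
            state[nd] = min(sets[nd])
        else:
            p_state = state[int(tree.parent[nd])]
            state[nd] = p_state if p_state in sets[nd] else min(sets[nd])
    edge_regime = {c: state[c] for c in range(1, tree.n_nodes)}
    regimes = sorted(set(tip_states.values()))
    return RegimePainting(edge_regime, state[tree.root], regimes).attach_parents(tree)


def clade_painting(tree: PhyloTree, clades: dict[str, list[str]],
                   background: str = "root") -> RegimePainting:
    """Paint named clades (crown plus stem edge) over a background regime.

    ``clades`` maps a regime name to the tip labels of a monophyletic
    group; the regime covers the group's MRCA subtree and its stem edge.
    """
    edge_regime = {c: background for c in range(1, tree.n_nodes)}
    for name, tips in clades.items():
        tip_nodes = [int(tree.tip_ids[tree.tip_labels.index(t)]) for t in tips]
        paths = [set(tree.lineage(t)) for t in tip_nodes]
        shared = set.intersection(*paths)
        mrca = max(shared, key=lambda nd: tree.heights[nd])
        stack = [mrca]
        while stack:
            nd = stack.pop()
            if nd != tree.root:
                edge_regime[nd] = name
            stack.extend(tree.children[nd])
    regimes = sorted(set(edge_regime.values()) | {background})
    return RegimePainting(edge_regime, background, regimes).attach_parents(tree)


def single_regime(tree: PhyloTree, name: str = "global") -> RegimePainting:
    edge_regime = {c: name for c in range(1, tree.n_nodes)}
    return RegimePainting(edge_regime, name, [name]).attach_parents(tree)


def parsimony_score(tree: PhyloTree, tip_states: dict[str, str]) -> int:
    """Minimum number of state changes (Fitch count)."""
    score = 0
    sets: dict[int, frozenset[str]] = {}
    for nd in tree.postorder():
        nd = int(nd)
        if tree.is_tip[nd]:
            sets[nd] = frozenset([tip_states[tree.node_labels[nd]]])
        else:
            child_sets = [sets[c] for c in tree.children[nd]]
            inter = frozenset.intersection(*child_sets)
            if inter:
                sets[nd] = inter
            else:
                sets[nd] = frozenset.union(*child_sets)
                score += 1
    return score


# ---------------------------------------------------------------------------
# Information criteria
# ---------------------------------------------------------------------------

def param_count(model: str, p: int, m: int = 1) -> int:
    half = p * (p + 1) // 2
    if model == "BM":
        return half + p
    if model == "EB":
        return half + p + 1
    if model in ("OU", "OU1", "OUM"):
        return 2 * half + p * m
    raise ValueError(f"unknown model {model!r}")


def aicc(logL: float, k: int, n_eff: int) -> float:
    if n_eff - k - 1 <= 0:
        raise ValueError("AICc undefined: n_eff <= k + 1")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n_eff - k - 1)


def akaike_weights(aicc_values: np.ndarray) -> np.ndarray:
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

@dataclass
class EvoModelFit:
    model: str                      # BM | EB | OU1 | OUM
    logL: float
    k: int
    n_eff: int
    R: np.ndarray                   # rate / diffusion matrix (p x p)
    alpha: np.ndarray | None = None
    theta: dict[str, np.ndarray] | None = None
    a: float | None = None          # EB exponent
    root_state: np.ndarray | None = None
    aicc: float = None
    delta_aicc: float | None = None
    weight: float | None = None
    converged: bool = True
    n_restarts: int = 0
    name: str | None = None

    def __post_init__(self) -> None:
        if self.aicc is None:
            self.aicc = aicc(self.logL, self.k, self.n_eff)
        if self.name is None:
            self.name = self.model


def _check_tree(tree: PhyloTree, need_ultrametric: bool = False) -> None:
    if not tree.is_binary():
        raise ValueError("model fitting requires a fully binary tree; "
                         "resolve polytomies externally")
    if need_ultrametric and not tree.is_ultrametric():
        raise ValueError("OU fitting requires an ultrametric tree")


def _mvn_loglik_gls(Y: np.ndarray, C: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """ML log-likelihood of a matrix-normal BM-type model with covariance
    ``C (x) R``, profiling the root (GLS mean) and the rate matrix R."""
    n, p = Y.shape
    Cinv = np.linalg.inv(C)
    root = gls_mean(Y, Cinv)
    E = Y - root
    R = E.T @ Cinv @ E / n
    sign, logdet_R = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("degenerate rate matrix (traits collinear?)")
    _, logdet_C = np.linalg.slogdet(C)
    logL = -0.5 * (n * p * np.log(2 * np.pi) + p * logdet_C + n * logdet_R + n * p)
    return float(logL), R, root


def fit_bm(Y: np.ndarray, tree: PhyloTree,
           labels: list[str] | None = None) -> EvoModelFit:
    """Multivariate Brownian motion by maximum likelihood (closed form)."""
    from .comparative import _match

    Y, labels = _match(Y, tree, labels)
    _check_tree(tree)
    n, p = Y.shape
    C, _ = phylo_transform(tree, labels)
    logL, R, root = _mvn_loglik_gls(Y, C)
    return EvoModelFit("BM", logL, param_count("BM", p), n * p, R,
                       root_state=root)


def eb_branch_transform(C: np.ndarray, a: float) -> np.ndarray:
    """Brownian covariance under an exponentially decaying rate.

    Shared variance accumulated to time ``t`` is ``(exp(a t) - 1) / a``
    (elementwise on the shared-path matrix); ``a = 0`` recovers BM.
    """
    if abs(a) < 1e-12:
        return C.copy()
    return np.expm1(a * C) / a


def fit_eb(Y: np.ndarray, tree: PhyloTree, labels: list[str] | None = None,
           bounds: tuple[float, float] | None = None) -> EvoModelFit:
    """Early burst: BM with rate ``exp(a t)``, ``a <= 0``, profiled over a."""
    from .comparative import _match

    Y, labels = _match(Y, tree, labels)
    _check_tree(tree)
    n, p = Y.shape
    C, _ = phylo_transform(tree, labels)
    T = tree.tree_height
    lo, hi = bounds if bounds is not None else (-10.0 / T, 0.0)

    def nll(a: float) -> float:
        try:
            logL, _, _ = _mvn_loglik_gls(Y, eb_branch_transform(C, a))
        except (ValueError, np.linalg.LinAlgError):
            return np.inf
        return -logL

    res = scipy.optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                         options={"xatol": 1e-10})
    a_hat = float(res.x)
    if nll(0.0) <= res.fun:  # boundary check: BM at least as good
        a_hat = 0.0
    logL, R, root = _mvn_loglik_gls(Y, eb_branch_transform(C, a_hat))
    return EvoModelFit("EB", logL, param_count("EB", p), n * p, R,
                       a=a_hat, root_state=root)


# ---------------------------------------------------------------------------
# Multivariate OU
# ---------------------------------------------------------------------------

def _tip_segments(tree: PhyloTree, painting: RegimePainting):
    """Per tip: list of (t0, t1, regime_index) from root to tip."""
    reg_index = {r: i for i, r in enumerate(painting.regimes)}
    segs = []
    for t in tree.tip_ids:
        path = tree.lineage(int(t))
        out = []
        for child in path[1:]:
            t0 = tree.heights[tree.parent[child]]
            t1 = tree.heights[child]
            out.append((t0, t1, reg_index[painting.edge_regime[child]]))
        segs.append(out)
    return segs, reg_index


def ou_mean_and_cov(tree: PhyloTree, labels: list[str],
                    painting: RegimePainting, alpha: np.ndarray,
                    sigma: np.ndarray,
                    theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tip mean vector and covariance of the multivariate OU process.

    ``theta`` is (m, p) with rows ordered as ``painting.regimes``.  The
    process starts at the root regime's optimum.  Layout is species-major:
    entry ``i*p + a`` is trait ``a`` of species ``labels[i]``.
    """
    D, V, _ = _ou_design_cov(tree, labels, painting, alpha, sigma)
    mean = D @ theta.reshape(-1)
    return mean, V


def _ou_design_cov(tree: PhyloTree, labels: list[str],
                   painting: RegimePainting, alpha: np.ndarray,
                   sigma: np.ndarray):
    """Mean design matrix (np x mp) and tip covariance (np x np)."""
    p = alpha.shape[0]
    lam, Q = np.linalg.eigh(alpha)
    if lam.min() <= 0:
        raise ValueError("alpha must be positive definite")
    segs, reg_index = _tip_segments(tree, painting)
    m = len(painting.regimes)
    order = [tree.tip_labels.index(s) for s in labels]
    n = len(order)
    T = tree.tree_height
    S = Q.T @ sigma @ Q
    qsum = lam[:, None] + lam[None, :]

    # mean design: regime weights in the eigenbasis
    root_reg = reg_index[painting.root_regime]
    D = np.zeros((n * p, m * p))
    for row, tip_pos in enumerate(order):
        w = np.zeros((m, p))
        w[root_reg] += np.exp(-lam * T)
        for (t0, t1, r) in segs[tip_pos]:
            w[r] += np.exp(-lam * (T - t1)) - np.exp(-lam * (T - t0))
        for r in range(m):
            block = (Q * w[r]) @ Q.T
            D[row * p:(row + 1) * p, r * p:(r + 1) * p] = block

    # covariance from MRCA depths, vectorized over tip pairs: in the
    # eigenbasis the (k, l) entry of the (i, j) block is
    # S_kl * exp(-(lam_k+lam_l)(T - s_ij)) * (1 - exp(-(lam_k+lam_l) s_ij))
    #      / (lam_k + lam_l)
    Cbm = tree.vcv()[np.ix_(order, order)]
    q = qsum[..., None, None]                                # (p, p, 1, 1)
    with np.errstate(over="ignore"):
        F = (S[..., None, None] * np.exp(-q * (T - Cbm))
             * (-np.expm1(-q * Cbm)) / q)                    # (p, p, n, n)
    V = np.einsum("ak,bl,klij->iajb", Q, Q, F, optimize=True)
    V = V.reshape(n * p, n * p)
    return D, V, reg_index


def _chol_from_params(x: np.ndarray, p: int) -> np.ndarray:
    """Lower-triangular Cholesky factor from a packed parameter vector
    (diagonal entries stored on log scale)."""
    L = np.zeros((p, p))
    idx = 0
    for i in range(p):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(x[idx])
            else:
                L[i, j] = x[idx]
            idx += 1
    return L


def _ou_negloglik(x: np.ndarray, Yv: np.ndarray, tree: PhyloTree,
                  labels: list[str], painting: RegimePainting, p: int,
                  fixed_alpha: np.ndarray | None):
    half = p * (p + 1) // 2
    if fixed_alpha is None:
        A = _chol_from_params(x[:half], p)
        alpha = A @ A.T
        xs = x[half:]
    else:
        alpha = fixed_alpha
        xs = x
    Ls = _chol_from_params(xs, p)
    sigma = Ls @ Ls.T
    try:
        D, V, _ = _ou_design_cov(tree, labels, painting, alpha, sigma)
        cf = scipy.linalg.cho_factor(V, lower=True)
    except (ValueError, np.linalg.LinAlgError):
        return np.inf, None
    ViD = scipy.linalg.cho_solve(cf, D)
    Viy = scipy.linalg.cho_solve(cf, Yv)
    M = D.T @ ViD
    try:
        theta = np.linalg.solve(M, D.T @ Viy)
    except np.linalg.LinAlgError:
        theta, *_ = np.linalg.lstsq(M, D.T @ Viy, rcond=None)
    r = Yv - D @ theta
    Vir = scipy.linalg.cho_solve(cf, r)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    npn = len(Yv)
    logL = -0.5 * (npn * np.log(2 * np.pi) + logdet + r @ Vir)
    return -logL, theta


def fit_ou(Y: np.ndarray, tree: PhyloTree, painting: RegimePainting,
           labels: list[str] | None = None, n_restarts: int = 5,
           seed: int = 0, fix_alpha: np.ndarray | None = None,
           maxiter: int = 300) -> EvoModelFit:
    """Multivariate OU with shared attraction matrix and per-regime optima.

    ``alpha`` and the rate matrix are parameterized by Cholesky factors
    (log-scale diagonals); the optima are profiled out by GLS at every
    likelihood evaluation.  A bounded quasi-Newton search is run from
    ``n_restarts`` seeded random restarts and the best likelihood kept.
    With ``fix_alpha`` the attraction matrix is held fixed and only the
    rate matrix (and optima) are estimated — used for nesting checks.
    """
    from .comparative import _match

    Y, labels = _match(Y, tree, labels)
    _check_tree(tree, need_ultrametric=True)
    n, p = Y.shape
    m = painting.n_regimes
    Yv = Y.reshape(-1)
    T = tree.tree_height
    half = p * (p + 1) // 2

    # moment-based starting values
    Vs = np.cov(Y.T).reshape(p, p) + 1e-8 * np.eye(p)
    alpha0 = (np.log(2.0) / (0.5 * T)) * np.eye(p)
    sigma0 = alpha0 @ Vs + Vs @ alpha0

    def pack(Mat):
        L = np.linalg.cholesky(Mat)
        out = []
        for i in range(p):
            for j in range(i + 1):
                out.append(np.log(L[i, j]) if i == j else L[i, j])
        return np.array(out)

    x0_parts = []
    if fix_alpha is None:
        x0_parts.append(pack(alpha0))
    x0_parts.append(pack(sigma0))
    x0 = np.concatenate(x0_parts)

    rng = np.random.default_rng(seed)
    best = None
    n_free = len(x0)
    bounds = [(-12.0, 12.0)] * n_free
    converged = False
    for attempt in range(n_restarts):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.75, n_free)
        res = scipy.optimize.minimize(
            lambda x: _ou_negloglik(x, Yv, tree, labels, painting, p, fix_alpha)[0],
            start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    nll, theta = _ou_negloglik(best.x, Yv, tree, labels, painting, p, fix_alpha)
    if fix_alpha is None:
        A = _chol_from_params(best.x[:half], p)
        alpha_hat = A @ A.T
        xs = best.x[half:]
    else:
        alpha_hat = fix_alpha
        xs = best.x
    Ls = _chol_from_params(xs, p)
    sigma_hat = Ls @ Ls.T
    theta_mat = theta.reshape(m, p)
    theta_dict = {r: theta_mat[i] for i, r in enumerate(painting.regimes)}
    model = "OU1" if m == 1 else "OUM"
    return EvoModelFit(
        model, float(-nll), param_count("OU", p, m), n * p, sigma_hat,
        alpha=alpha_hat, theta=theta_dict, converged=converged,
        n_restarts=n_restarts,
    )


def bm_covariance(C: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Dense tip covariance ``C (x) R`` (species-major layout)."""
    return np.kron(C, R)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def model_table(fits, n_species: int | None = None, p: int | None = None):
    """AICc comparison table with deltas and Akaike weights.

    ``fits`` is a list of :class:`EvoModelFit` (their stored ``n_eff`` is
    used) or of ``(name, logL, k)`` tuples, in which case ``n_species``
    and ``p`` supply ``n_eff = n_species * p``.
    """
    import pandas as pd

    rows = []
    for f in fits:
        if isinstance(f, EvoModelFit):
            rows.append((f.name, f.logL, f.k, f.aicc))
        else:
            name, logL, k = f
            rows.append((name, logL, k, aicc(logL, k, n_species * p)))
    df = pd.DataFrame(rows, columns=["model", "logL", "k", "AICc"])
    df["delta_AICc"] = df["AICc"] - df["AICc"].min()
    df["weight"] = akaike_weights(df["AICc"].to_numpy())
    for f, (_, row) in zip(fits, df.iterrows()):
        if isinstance(f, EvoModelFit):
            f.delta_aicc = float(row["delta_AICc"])
            f.weight = float(row["weight"])
    return df
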