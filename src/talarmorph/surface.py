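"""Stepwise adaptive-peak search (SURFACE-style) with convergence detection.

Traits are fitted independently with scalar-parameter OU models sharing a
single shift configuration; the summed AICc over traits scores a model.
The forward phase greedily adds the peak shift that most improves the
summed AICc (acceptance threshold 2 units by default), the backward phase
collapses regime pairs toward shared peaks while the score improves, and
regimes reached by two or more phylogenetically independent shifts are
reported as convergent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .dataio import PhyloTree
from .evomodels import RegimePainting, aicc

__all__ = [
    "SurfaceModel",
    "TraitFit",
    "hansen_fit",
    "surface_forward",
    "surface_backward",
    "run_surface",
    "painting_from_shifts",
]


@dataclass
class TraitFit:
    alpha: float
    sigma2: float
    theta: np.ndarray       # one optimum per regime
    logL: float
    k: int
    aicc: float


@dataclass
class SurfaceModel:
    """A shift configuration with its per-trait scalar OU fits."""

    shifts: dict[int, str]            # edge (child node) -> regime created there
    edge_regime: dict[int, str]       # full painting derived from shifts
    root_regime: str
    regimes: list[str]
    trait_fits: list[TraitFit]
    aicc: float                       # summed over traits
    history: list[dict] = field(default_factory=list)
    regime_sources: dict[str, list[int | None]] = field(default_factory=dict)

    def convergent_groups(self) -> list[str]:
        """Regimes reached by >= 2 independent origins (shift or root)."""
        return sorted(r for r, src in self.regime_sources.items() if len(src) >= 2)

    def to_painting(self, tree: PhyloTree) -> RegimePainting:
        return RegimePainting(
            dict(self.edge_regime), self.root_regime, sorted(self.regimes)
        ).attach_parents(tree)


def painting_from_shifts(tree: PhyloTree, shifts: dict[int, str],
                         root_regime: str = "R1") -> dict[int, str]:
    """Whole-edge painting implied by shifts at branch origins.

    A shift on an edge assigns its regime to that edge and all descendant
    edges up to any downstream shift; everything else inherits from above.
    """
    painting: dict[int, str] = {}
    # preorder traversal: node index order is already preorder
    current = {tree.root: root_regime}
    for child in range(1, tree.n_nodes):
        reg = shifts.get(child, current[int(tree.parent[child])])
        painting[child] = reg
        current[child] = reg
    return painting


# ---------------------------------------------------------------------------
# Scalar OU fit with fixed shifts
# ---------------------------------------------------------------------------

class _ScalarOuWorkspace:
    """Precomputed tree quantities reused across many candidate fits."""

    def __init__(self, tree: PhyloTree, labels: list[str]):
        order = [tree.tip_labels.index(s) for s in labels]
        self.order = order
        self.C = tree.vcv()[np.ix_(order, order)]
        self.T = tree.tree_height
        self.n = len(order)
        self.tree = tree
        # root-to-tip segments (t0, t1, child-edge) per tip, in label order
        self.segments = []
        for pos in order:
            t = int(tree.tip_ids[pos])
            path = tree.lineage(t)
            self.segments.append([
                (tree.heights[tree.parent[c]], tree.heights[c], c)
                for c in path[1:]
            ])

    def design(self, edge_regime: dict[int, str], root_regime: str,
               regimes: list[str], alpha: float) -> np.ndarray:
        m = len(regimes)
        reg_index = {r: i for i, r in enumerate(regimes)}
        W = np.zeros((self.n, m))
        T = self.T
        for i, segs in enumerate(self.segments):
            W[i, reg_index[root_regime]] += np.exp(-alpha * T)
            for (t0, t1, child) in segs:
                r = reg_index[edge_regime[child]]
                W[i, r] += np.exp(-alpha * (T - t1)) - np.exp(-alpha * (T - t0))
        return W

    def corr(self, alpha: float) -> np.ndarray:
        # OU tip correlation structure (unit sigma2), process started at root
        q = 2.0 * alpha
        s = self.C
        with np.errstate(over="ignore"):
            return np.exp(-q * (self.T - s)) * (-np.expm1(-q * s)) / q


def _scalar_ou_profile(y: np.ndarray, W: np.ndarray, V0: np.ndarray):
    """Profile theta (GLS) and sigma2 for a scalar OU with unit-rate
    correlation matrix ``V0``; returns (logL, theta, sigma2)."""
    n = len(y)
    cf = scipy.linalg.cho_factor(V0, lower=True)
    ViW = scipy.linalg.cho_solve(cf, W)
    Viy = scipy.linalg.cho_solve(cf, y)
    M = W.T @ ViW
    try:
        theta = np.linalg.solve(M, W.T @ Viy)
    except np.linalg.LinAlgError:
        theta, *_ = np.linalg.lstsq(M, W.T @ Viy, rcond=None)
    r = y - W @ theta
    quad = float(r @ scipy.linalg.cho_solve(cf, r))
    sigma2 = quad / n
    if sigma2 <= 0:
        return -np.inf, theta, 0.0
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    logL = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return logL, theta, sigma2


def hansen_fit(Y: np.ndarray, tree: PhyloTree, shifts: dict[int, str],
               labels: list[str] | None = None, root_regime: str = "R1",
               workspace: _ScalarOuWorkspace | None = None,
               edge_regime: dict[int, str] | None = None):
    """Fit every trait with a scalar-alpha, scalar-sigma2 OU sharing one
    shift configuration; returns (list of TraitFit, summed AICc).

    Per trait ``k = 2 + m`` (alpha, sigma2 and one optimum per regime);
    each trait's alpha is optimized on a log scale by bounded search.
    """
    if not tree.is_ultrametric():
        raise ValueError("SURFACE fitting requires an ultrametric tree")
    if not tree.is_binary():
        raise ValueError("SURFACE fitting requires a binary tree")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if labels is None:
        labels = tree.tip_labels
    ws = workspace or _ScalarOuWorkspace(tree, labels)
    if edge_regime is None:
        edge_regime = painting_from_shifts(tree, shifts, root_regime)
    regimes = sorted(set(edge_regime.values()) | {root_regime})
    m = len(regimes)
    n = ws.n
    T = ws.T
    fits: list[TraitFit] = []
    log_lo, log_hi = np.log(1e-4 / T), np.log(50.0 / T)

    for j in range(Y.shape[1]):
        y = Y[:, j]

        def nll(log_a: float) -> float:
            a = np.exp(log_a)
            try:
                logL, _, _ = _scalar_ou_profile(
                    y, ws.design(edge_regime, root_regime, regimes, a), ws.corr(a))
            except (ValueError, np.linalg.LinAlgError):
                return np.inf
            return -logL

        res = scipy.optimize.minimize_scalar(
            nll, bounds=(log_lo, log_hi), method="bounded",
            options={"xatol": 1e-6})
        a_hat = float(np.exp(res.x))
        logL, theta, s2 = _scalar_ou_profile(
            y, ws.design(edge_regime, root_regime, regimes, a_hat), ws.corr(a_hat))
        k = 2 + m
        fits.append(TraitFit(a_hat, s2, theta, logL, k, aicc(logL, k, n)))
    total = float(sum(f.aicc for f in fits))
    return fits, total


# ---------------------------------------------------------------------------
# Forward phase
# ---------------------------------------------------------------------------

def _model_from(tree, Y, labels, ws, shifts, root_regime="R1"):
    edge_regime = painting_from_shifts(tree, shifts, root_regime)
    fits, total = hansen_fit(Y, tree, shifts, labels, root_regime,
                             workspace=ws, edge_regime=edge_regime)
    sources: dict[str, list[int | None]] = {root_regime: [None]}
    for e, r in shifts.items():
        sources.setdefault(r, []).append(e)
    return SurfaceModel(
        shifts=dict(shifts), edge_regime=edge_regime, root_regime=root_regime,
        regimes=sorted(set(edge_regime.values()) | {root_regime}),
        trait_fits=fits, aicc=total, regime_sources=sources,
    )


def surface_forward(Y: np.ndarray, tree: PhyloTree,
                    labels: list[str] | None = None,
                    delta_aicc_stop: float = 2.0,
                    max_shifts: int | None = None) -> SurfaceModel:
    """Greedy forward phase: add the best peak shift while the summed AICc
    improves by at least ``delta_aicc_stop``.

    Candidate shifts sit at branch origins of every edge without one; the
    search is deterministic given the data (ties broken by edge index).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if labels is None:
        labels = tree.tip_labels
    ws = _ScalarOuWorkspace(tree, labels)
    shifts: dict[int, str] = {}
    model = _model_from(tree, Y, labels, ws, shifts)
    model.history.append({"step": 0, "action": "start", "aicc": model.aicc})
    step = 0
    limit = max_shifts if max_shifts is not None else tree.n_nodes
    while len(shifts) < limit:
        best_edge, best_model = None, None
        next_name = f"R{len(shifts) + 2}"
        for edge in range(1, tree.n_nodes):
            if edge in shifts:
                continue
            cand = dict(shifts)
            cand[edge] = next_name
            trial = _model_from(tree, Y, labels, ws, cand)
            if best_model is None or trial.aicc < best_model.aicc:
                best_edge, best_model = edge, trial
        if best_model is None or model.aicc - best_model.aicc < delta_aicc_stop:
            break
        step += 1
        shifts[best_edge] = next_name
        best_model.history = model.history + [{
            "step": step, "action": f"shift@edge{best_edge}",
            "aicc_before": model.aicc, "aicc": best_model.aicc,
        }]
        model = best_model
    return model


# ---------------------------------------------------------------------------
# Backward phase
# ---------------------------------------------------------------------------

def surface_backward(model: SurfaceModel, Y: np.ndarray, tree: PhyloTree,
                     labels: list[str] | None = None,
                     min_improvement: float = 0.0) -> SurfaceModel:
    """Collapse regime pairs toward shared adaptive peaks.

    Each round evaluates every unordered regime pair relabeled to a single
    regime; the merge improving the summed AICc the most is accepted and
    the loop repeats until no merge improves it by more than
    ``min_improvement``.  Regimes with two or more independent origins
    after merging are flagged convergent.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if labels is None:
        labels = tree.tip_labels
    ws = _ScalarOuWorkspace(tree, labels)
    current = model
    step = len(current.history)
    while True:
        regimes = current.regimes
        if len(regimes) < 2:
            break
        best = None
        for i in range(len(regimes)):
            for j in range(i + 1, len(regimes)):
                keep, drop = regimes[i], regimes[j]
                if drop == current.root_regime:
                    keep, drop = drop, keep
                shifts = {
                    e: (keep if r == drop else r)
                    for e, r in current.shifts.items()
                }
                # a shift relabeled to its parent regime is no longer a shift
                trial = _merged_model(tree, Y, labels, ws, shifts,
                                      current.root_regime, current, keep, drop)
                if best is None or trial.aicc < best.aicc:
                    best = trial
        if best is None or current.aicc - best.aicc <= min_improvement:
            break
        step += 1
        best.history = current.history + [{
            "step": step, "action": best.history[-1]["action"],
            "aicc_before": current.aicc, "aicc": best.aicc,
        }]
        current = best
    return current


def _merged_model(tree, Y, labels, ws, shifts, root_regime, parent_model,
                  keep, drop):
    model = _model_from(tree, Y, labels, ws, shifts, root_regime)
    # carry over merged origin bookkeeping
    sources = {r: list(s) for r, s in parent_model.regime_sources.items()}
    merged = sources.pop(drop, []) + sources.get(keep, [])
    sources[keep] = merged
    model.regime_sources = {r: s for r, s in sources.items() if r in model.regimes
                            or r == keep}
    model.regime_sources.setdefault(keep, merged)
    model.history = [{"action": f"merge {drop}->{keep}"}]
    return model


def run_surface(Y: np.ndarray, tree: PhyloTree,
                labels: list[str] | None = None,
                delta_aicc_stop: float = 2.0) -> SurfaceModel:
    """Full SURFACE search: forward shift addition then backward collapse."""
    fwd = surface_forward(Y, tree, labels, delta_aicc_stop=delta_aicc_stop)
    return surface_backward(fwd, Y, tree, labels)
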