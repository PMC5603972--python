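"""Seeded synthetic-data generators with the structure the analyses assume.

The default dimensions mirror the empirical design the pipeline targets:
about 40 species with ~5 specimens each, 30 three-dimensional landmarks,
five locomotor-mode-percentage (LMP) categories and four articular
facets.  Species mean shapes evolve on the tree (Brownian motion by
default, optionally OU or early burst), specimens scatter around their
species mean with independent digitizing noise, LMP compositions are a
softmax-linear readout of the latent shape factors, and mass-area data
follow a log-log line with normal scatter.  Every generator takes an
explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import LandmarkConfiguration, PhyloTree
from .evomodels import RegimePainting, eb_branch_transform, ou_mean_and_cov

__all__ = [
    "SimulationSpec",
    "sim_tree",
    "sim_traits",
    "sim_landmarks",
    "sim_lmp",
    "sim_mass_area",
    "default_template",
]


@dataclass
class SimulationSpec:
    """Bundle of generator settings for an end-to-end synthetic dataset."""

    seed: int
    n_species: int = 40
    n_specimens_per_species: int = 5
    n_landmarks: int = 30
    model: str = "BM"                      # BM | OU | EB
    evo_rate: float = 1.0                  # scalar Brownian rate scale
    a: float = 0.0                         # EB exponent
    within_noise_sd: float = 0.02
    landmark_missing_rate: float = 0.0
    birth_rate: float = 1.0
    lmp_link_strength: float = 1.0
    mass_slope: float = 1.25
    mass_intercept: float = 3.0
    mass_see: float = 0.10
    regimes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def sim_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Ultrametric pure-birth (Yule) tree with ``n_tips`` labeled tips.

    With k extant lineages the waiting time to the next split is
    exponential with rate ``k * birth_rate``; after the (n-1)th split one
    more exponential waiting time runs to the present, so all tips end at
    the same height.
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    t = 0.0
    root = {"h": 0.0, "kids": []}
    active = []
    for _ in range(2):
        child = {"h": None, "kids": [], "parent": root, "birth": 0.0}
        root["kids"].append(child)
        active.append(child)
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = rng.integers(0, k)
        node = active.pop(int(idx))
        node["h"] = t
        for _ in range(2):
            child = {"h": None, "kids": [], "parent": node, "birth": t}
            node["kids"].append(child)
            active.append(child)
        k += 1
    t += rng.exponential(1.0 / (birth_rate * k))
    labels = iter(f"sp{i + 1:03d}" for i in range(n_tips))

    def render(node, parent_h: float) -> str:
        if not node["kids"]:
            return f"{next(labels)}:{t - parent_h:.12f}"
        inner = ",".join(render(c, node["h"]) for c in node["kids"])
        if parent_h is None:
            return f"({inner});"
        return f"({inner}):{node['h'] - parent_h:.12f}"

    newick = f"({render(root['kids'][0], 0.0)},{render(root['kids'][1], 0.0)});"
    return PhyloTree.from_newick(newick)


# ---------------------------------------------------------------------------
# Species-level traits
# ---------------------------------------------------------------------------

def sim_traits(tree: PhyloTree, R: np.ndarray, model: str = "BM",
               seed: int = 0, root: np.ndarray | None = None,
               a: float = 0.0, alpha: np.ndarray | None = None,
               theta: np.ndarray | None = None,
               painting: RegimePainting | None = None) -> np.ndarray:
    """Exact multivariate-normal draw of tip traits under BM, EB or OU.

    Rows follow ``tree.tip_labels``.  The mean and covariance are the
    same matrices the corresponding likelihoods integrate over, so
    fitted-model recovery tests draw from the model exactly.
    """
    rng = np.random.default_rng(seed)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    p = R.shape[0]
    n = tree.n_tips
    labels = tree.tip_labels
    if model in ("BM", "EB"):
        C = tree.vcv()
        if model == "EB":
            C = eb_branch_transform(C, a)
        mu = np.zeros(p) if root is None else np.asarray(root, float)
        Lc = np.linalg.cholesky(C + 1e-12 * np.trace(C) / n * np.eye(n))
        Lr = np.linalg.cholesky(R)
        return mu + Lc @ rng.standard_normal((n, p)) @ Lr.T
    if model == "OU":
        if alpha is None or theta is None or painting is None:
            raise ValueError("OU simulation needs alpha, theta and a painting")
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        mean, V = ou_mean_and_cov(tree, labels, painting,
                                  np.atleast_2d(alpha), R, theta)
        L = np.linalg.cholesky(V + 1e-12 * np.trace(V) / len(V) * np.eye(len(V)))
        y = mean + L @ rng.standard_normal(len(V))
        return y.reshape(n, p)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Landmark datasets
# ---------------------------------------------------------------------------

def default_template(n_landmarks: int = 30, seed: int = 12345,
                     scale: float = 10.0) -> np.ndarray:
    """A fixed, reproducible 3D landmark template (roughly ellipsoidal)."""
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_landmarks, 3)) * np.array([1.6, 1.0, 0.7])
    pts -= pts.mean(axis=0)
    return pts * scale


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, Rm = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(Rm)))
    if np.linalg.det(Q) < 0:
        Q[:, 2] = -Q[:, 2]
    return Q


def sim_landmarks(tree: PhyloTree, template: np.ndarray | None = None,
                  n_specimens: int = 5, evo_sd: float = 0.03,
                  noise_sd: float = 0.01, seed: int = 0,
                  random_pose: bool = True, left_fraction: float = 0.0,
                  missing_rate: float = 0.0,
                  allometry: float = 0.0) -> list[LandmarkConfiguration]:
    """Specimen landmark configurations for every species on the tree.

    Species mean shapes are the template plus Brownian deviations in
    tangent (coordinate) space with per-coordinate rate ``evo_sd**2``;
    specimens add iid digitizing noise, an optional random rigid pose
    (rotation/translation/scale), optional left-side mirroring, and
    optional missing-landmark masking.  ``allometry`` adds a size factor
    that covaries with the first latent shape axis.
    """
    rng = np.random.default_rng(seed)
    if template is None:
        template = default_template()
    template = np.asarray(template, dtype=float)
    k = template.shape[0]
    n_sp = tree.n_tips
    scale0 = float(np.sqrt(((template - template.mean(0)) ** 2).sum()))
    # Brownian deviations per coordinate, drawn jointly across species
    C = tree.vcv()
    Lc = np.linalg.cholesky(C + 1e-12 * np.trace(C) / n_sp * np.eye(n_sp))
    species_dev = (evo_sd * scale0) * (
        Lc @ rng.standard_normal((n_sp, 3 * k))
    )
    configs: list[LandmarkConfiguration] = []
    for si, sp in enumerate(tree.tip_labels):
        mean_shape = template + species_dev[si].reshape(k, 3)
        size_factor = np.exp(allometry * species_dev[si, 0] / (evo_sd * scale0 + 1e-12))
        for r in range(n_specimens):
            coords = mean_shape + rng.normal(0.0, noise_sd * scale0, (k, 3))
            coords = coords * size_factor
            side = "right"
            if rng.random() < left_fraction:
                coords = coords.copy()
                coords[:, 0] = -coords[:, 0]
                side = "left"
            if random_pose:
                coords = coords @ _random_rotation(rng).T
                coords = coords * np.exp(rng.normal(0, 0.1))
                coords = coords + rng.normal(0, 5.0, 3)
            missing = rng.random(k) < missing_rate
            if missing.sum() > k - 4:
                missing[:] = False
            coords = coords.copy()
            coords[missing] = np.nan
            configs.append(LandmarkConfiguration(
                f"{sp}_{r + 1}", sp, side, coords, missing))
    return configs


# ---------------------------------------------------------------------------
# Locomotor-mode percentages
# ---------------------------------------------------------------------------

def sim_lmp(shape_factors: np.ndarray, link: np.ndarray | float = 1.0,
            seed: int = 0, n_categories: int = 5,
            noise_sd: float = 0.3) -> np.ndarray:
    """Five-part compositions covarying with latent shape factors.

    A linear map of the factors plus noise goes through a softmax and is
    scaled to percentages, so every row sums to exactly 100.
    ``link`` may be a scalar strength (a fixed random map is drawn) or an
    explicit (n_factors, n_categories) matrix; zero gives compositions
    independent of shape.
    """
    rng = np.random.default_rng(seed)
    F = np.atleast_2d(np.asarray(shape_factors, dtype=float))
    n, q = F.shape
    if np.isscalar(link):
        B = rng.standard_normal((q, n_categories)) * float(link)
    else:
        B = np.asarray(link, dtype=float)
    eta = F @ B + rng.normal(0.0, noise_sd, (n, B.shape[1]))
    eta -= eta.max(axis=1, keepdims=True)
    w = np.exp(eta)
    comp = w / w.sum(axis=1, keepdims=True)
    return 100.0 * comp


# ---------------------------------------------------------------------------
# Mass-area calibration data
# ---------------------------------------------------------------------------

def sim_mass_area(n: int, m: float = 1.25, b: float = 3.0, see: float = 0.10,
                  seed: int = 0,
                  log_area_range: tuple[float, float] = (-0.5, 1.5)):
    """Log-log mass-area pairs: ``log10(mass) = m log10(area) + b + N(0, SEE^2)``.

    Areas are log-uniform over ``log_area_range`` (log10 units).  Returns
    ``(areas, masses)``.
    """
    rng = np.random.default_rng(seed)
    log_area = rng.uniform(*log_area_range, n)
    log_mass = m * log_area + b + rng.normal(0.0, see, n)
    return 10.0 ** log_area, 10.0 ** log_mass
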