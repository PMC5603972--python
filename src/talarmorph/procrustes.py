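"""Generalized Procrustes analysis of 3D landmark configurations.

Removes translation, scale and rotation from landmark data to produce
shape variables and centroid sizes.  Reflection is only ever applied as an
explicit, recorded preprocessing step (specimens are mirrored to a
uniformly right-sided dataset before analysis); the rotation solver is
restricted to proper rotations.  Incomplete specimens are first aligned to
the complete-data consensus on their available landmarks, their missing
landmarks are filled by a per-landmark linear regression fitted on the
aligned complete specimens, and the full superimposition is then re-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import LandmarkConfiguration

__all__ = [
    "ShapeDataset",
    "reflect",
    "centroid",
    "centroid_size",
    "optimal_rotation",
    "procrustes_distance",
    "gpa",
    "impute_missing",
]


def reflect(config: LandmarkConfiguration, axis: str = "x") -> LandmarkConfiguration:
    """Mirror a configuration across the plane normal to ``axis``.

    Negates the chosen coordinate for every landmark and flips the side
    flag.  Applying the same reflection twice restores the original.
    """
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    out = config.copy()
    out.coords[:, ax] = -out.coords[:, ax]
    out.side = "left" if config.side == "right" else "right"
    return out


def centroid(coords: np.ndarray, missing: np.ndarray | None = None) -> np.ndarray:
    if missing is not None:
        coords = coords[~missing]
    return coords.mean(axis=0)


def centroid_size(config) -> float:
    """Square root of summed squared landmark distances from their centroid.

    Computed over non-missing landmarks only; requires at least two.
    """
    if isinstance(config, LandmarkConfiguration):
        coords, missing = config.coords, config.missing
    else:
        coords = np.asarray(config, dtype=float)
        missing = np.isnan(coords).any(axis=1)
    pts = coords[~missing]
    if len(pts) == 0:
        raise ValueError("all landmarks missing")
    if len(pts) < 2:
        raise ValueError("centroid size requires >= 2 non-missing landmarks")
    c = pts.mean(axis=0)
    return float(np.sqrt(((pts - c) ** 2).sum()))


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation ``R`` minimizing ``||A @ R.T - B||``.

    Both configurations must be centered and share the same landmark set.
    Reflections are excluded: the determinant of the result is always +1,
    so a mirrored configuration keeps a positive residual.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("configurations must have identical shape")
    H = A.T @ B
    U, s, Vt = np.linalg.svd(H)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (rank < 2) configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _center_scale(coords: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Center on the non-missing centroid and scale to unit centroid size."""
    out = coords - centroid(coords, missing)
    cs = np.sqrt((out[~missing] ** 2).sum())
    if cs == 0:
        raise ValueError("zero centroid size")
    return out / cs


def procrustes_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Full-fit Procrustes distance between two complete configurations."""
    za = np.zeros(len(A), dtype=bool)
    a = _center_scale(np.asarray(A, float), za)
    b = _center_scale(np.asarray(B, float), za)
    R = optimal_rotation(b, a)
    return float(np.linalg.norm(b @ R.T - a))


@dataclass
class ShapeDataset:
    """Procrustes-aligned configurations with sizes and a consensus shape."""

    specimen_ids: list[str]
    species_labels: list[str]
    aligned: np.ndarray            # (n, k, 3), unit centroid size each
    centroid_sizes: np.ndarray     # (n,), original sizes in mm
    consensus: np.ndarray          # (k, 3)
    reflected: np.ndarray = None   # (n,) bool
    imputed: np.ndarray = None     # (n, k) bool
    n_iterations: int = 0
    residual_history: list = None  # summed squared residuals per iteration

    def __post_init__(self) -> None:
        n, k, _ = self.aligned.shape
        if self.reflected is None:
            self.reflected = np.zeros(n, dtype=bool)
        if self.imputed is None:
            self.imputed = np.zeros((n, k), dtype=bool)

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flat(self) -> np.ndarray:
        """Shape variables: aligned coordinates flattened to (n, 3k)."""
        return self.aligned.reshape(self.n_specimens, -1)

    def species_means(self) -> tuple[list[str], np.ndarray]:
        """Per-species mean shape variables, species sorted alphabetically."""
        flat = self.flat()
        species = sorted(set(self.species_labels))
        lab = np.asarray(self.species_labels)
        means = np.stack([flat[lab == s].mean(axis=0) for s in species])
        return species, means

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, sid in enumerate(self.specimen_ids):
            for j in range(self.n_landmarks):
                rows.append((sid, self.species_labels[i], j + 1,
                             *self.aligned[i, j], bool(self.imputed[i, j])))
        return pd.DataFrame(
            rows, columns=["specimen", "species", "landmark", "x", "y", "z", "imputed"]
        )


def _masked_fit_to(coords: np.ndarray, missing: np.ndarray,
                   reference: np.ndarray) -> np.ndarray:
    """Superimpose one (possibly incomplete) configuration on a reference.

    Centering, scaling and rotation use only the specimen's available
    landmarks matched against the same subset of the reference; missing
    rows come out as NaN.
    """
    avail = ~missing
    if avail.sum() < 4:
        raise ValueError("need >= 4 non-missing landmarks to superimpose")
    ref_sub = reference[avail] - reference[avail].mean(axis=0)
    sub = coords[avail] - coords[avail].mean(axis=0)
    cs = np.sqrt((sub ** 2).sum())
    if cs == 0:
        raise ValueError("zero centroid size")
    # match the scale of the reference subset so filled-in landmarks live on
    # the consensus scale
    sub = sub / cs * np.sqrt((ref_sub ** 2).sum())
    R = optimal_rotation(sub, ref_sub)
    out = np.full_like(coords, np.nan)
    out[avail] = sub @ R.T
    return out


def gpa(configs: list[LandmarkConfiguration], tol: float = 1e-8,
        max_iter: int = 100) -> ShapeDataset:
    """Generalized Procrustes superimposition (full Procrustes, unit size).

    Iteratively centers, scales and rotates every configuration to an
    evolving consensus until the consensus stops moving (change below
    ``tol``).  Incomplete configurations participate through their
    available landmarks; the consensus is the per-landmark mean over the
    specimens observing that landmark.
    """
    if not configs:
        raise ValueError("empty dataset")
    k = configs[0].n_landmarks
    for c in configs:
        if c.n_landmarks != k:
            raise ValueError(f"specimen {c.specimen_id}: landmark count mismatch")
    n = len(configs)
    sizes = np.array([centroid_size(c) for c in configs])
    masks = np.stack([c.missing for c in configs])
    if masks.all(axis=0).any():
        bad = np.flatnonzero(masks.all(axis=0)) + 1
        raise ValueError(f"landmark(s) {bad.tolist()} missing in every specimen")
    work = np.stack([
        _pad_center_scale(c.coords, c.missing) for c in configs
    ])

    complete = ~masks.any(axis=1)
    ref_idx = int(np.flatnonzero(complete)[0]) if complete.any() else 0
    consensus = np.nan_to_num(work[ref_idx])
    consensus = _center_scale(consensus, np.zeros(k, dtype=bool))
    n_it = 0
    residuals: list[float] = []
    for n_it in range(1, max_iter + 1):
        for i in range(n):
            work[i] = _masked_fit_to(work[i], masks[i], consensus)
        with np.errstate(invalid="ignore"):
            new_consensus = np.nanmean(work, axis=0)
        new_consensus = _center_scale(new_consensus, np.zeros(k, dtype=bool))
        # orient the consensus consistently so convergence is well defined
        R = optimal_rotation(new_consensus, consensus)
        new_consensus = new_consensus @ R.T
        delta = np.linalg.norm(new_consensus - consensus)
        consensus = new_consensus
        residuals.append(float(np.nansum((work - consensus) ** 2)))
        if delta < tol:
            break
    else:
        raise RuntimeError(f"GPA did not converge in {max_iter} iterations")
    # canonical orientation: principal axes of the consensus define the
    # coordinate frame, making the result invariant to specimen input order
    V = _canonical_axes(consensus)
    consensus = consensus @ V
    for i in range(n):
        work[i] = _masked_fit_to(work[i], masks[i], consensus)
        # re-normalize to exact unit centroid size on available landmarks
        avail = ~masks[i]
        work[i] = work[i] - np.nanmean(work[i][avail], axis=0)
        work[i] /= np.sqrt(np.nansum(work[i][avail] ** 2))
    # the reported consensus is the arithmetic mean of the final aligned
    # configurations (not re-scaled)
    with np.errstate(invalid="ignore"):
        consensus = np.nanmean(work, axis=0)
    return ShapeDataset(
        specimen_ids=[c.specimen_id for c in configs],
        species_labels=[c.species for c in configs],
        aligned=work,
        centroid_sizes=sizes,
        consensus=consensus,
        imputed=masks.copy() & False,
        n_iterations=n_it,
        residual_history=residuals,
    )


def _canonical_axes(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation aligning the consensus with its principal axes.

    Signs are fixed by making the largest-magnitude coordinate of each axis
    positive; the third axis is flipped if needed to keep determinant +1.
    """
    _, _, Vt = np.linalg.svd(consensus - consensus.mean(axis=0), full_matrices=False)
    V = Vt.T
    for j in range(3):
        col = consensus @ V[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            V[:, j] = -V[:, j]
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    return V


def _pad_center_scale(coords: np.ndarray, missing: np.ndarray) -> np.ndarray:
    out = np.full_like(np.asarray(coords, float), np.nan)
    avail = ~missing
    sub = coords[avail] - coords[avail].mean(axis=0)
    cs = np.sqrt((sub ** 2).sum())
    if cs == 0:
        raise ValueError("zero centroid size")
    out[avail] = sub / cs
    return out


def impute_missing(configs: list[LandmarkConfiguration], tol: float = 1e-8,
                   max_iter: int = 100, pc_variance: float = 0.99) -> ShapeDataset:
    """Fill missing landmarks by regression on the complete specimens.

    The complete specimens are superimposed first and each landmark's
    coordinates are regressed on all other landmark coordinates across that
    aligned reference set.  To keep the design well posed when specimens
    are fewer than predictor coordinates, predictors are reduced to the
    principal components explaining ``pc_variance`` of their variance
    before the regression.  Each incomplete specimen is aligned to the
    complete-data consensus on its available landmarks, its gaps are
    predicted, and a fresh superimposition over all specimens (imputed
    included) produces the returned dataset.
    """
    masks = np.stack([c.missing for c in configs])
    incomplete = masks.any(axis=1)
    for c in configs:
        if c.missing.all():
            raise ValueError(f"specimen {c.specimen_id}: all landmarks missing")
        if (~c.missing).sum() < 4:
            raise ValueError(f"specimen {c.specimen_id}: fewer than 4 landmarks present")
    if not incomplete.any():
        return gpa(configs, tol=tol, max_iter=max_iter)
    complete_configs = [c for c in configs if c.is_complete]
    if len(complete_configs) < 2:
        raise ValueError("need >= 2 complete specimens as an imputation reference")
    ref = gpa(complete_configs, tol=tol, max_iter=max_iter)
    ref_flat = ref.flat()                      # (nc, 3k)
    k = configs[0].n_landmarks

    filled: list[LandmarkConfiguration] = []
    for c in configs:
        if c.is_complete:
            filled.append(c.copy())
            continue
        aligned = _masked_fit_to(c.coords, c.missing, ref.consensus)
        avail_cols = np.repeat(~c.missing, 3)
        X = ref_flat[:, avail_cols]
        Xc = X - X.mean(axis=0)
        # PCA-reduce predictors
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        if s.sum() > 0:
            var = s ** 2
            keep = int(np.searchsorted(np.cumsum(var) / var.sum(), pc_variance) + 1)
        else:
            keep = 1
        Z = U[:, :keep] * s[:keep]             # scores
        out = c.copy()
        new_coords = aligned.copy()
        for j in np.flatnonzero(c.missing):
            Yj = ref_flat[:, 3 * j:3 * j + 3]
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(len(Z)), Z]), Yj, rcond=None
            )
            x_new = aligned[~c.missing].reshape(1, -1) - X.mean(axis=0)
            z_new = x_new @ (Vt[:keep].T)
            new_coords[j] = np.concatenate([[1.0], z_new.ravel()]) @ beta
        out.coords = new_coords
        out.missing = np.zeros(k, dtype=bool)
        filled.append(out)

    result = gpa(filled, tol=tol, max_iter=max_iter)
    result.imputed = masks.copy()
    # centroid sizes of imputed specimens are reported on their original
    # (mm) scale from the landmarks actually observed
    result.centroid_sizes = np.array([centroid_size(c) for c in configs])
    return result
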