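"""Posture correction: align and straighten each animal's point cloud.

The correction removes the four nuisance components of worm placement so
that nucleus positions become comparable across animals:

1. **PCA alignment** — the first principal component of the cloud defines
   the anterior–posterior (AP) axis; the cloud is centred and rotated into
   the PC frame.
2. **Quadratic straightening** — body bend is modelled as independent
   quadratic curves of the PC2 and PC3 coordinates as functions of PC1
   (least squares); each cell is shifted by the curve offset at its own AP
   coordinate, so cross-sections are moved rigidly and the DV–LR plane is
   not deformed.
3. **Roll and origin** — the sparsest angular direction of the cloud in the
   DV–LR plane defines dorsal (rotated to +y); the densest position of the
   1-D cell density along AP defines the origin; anterior is oriented
   toward negative x.
4. **Fine alignment** (optional) — a similarity transform fitted on named
   landmark cells (e.g. dye-stained neurons) against reference positions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from ._geom import SimilarityTransform, fit_similarity
from .model import WormSample

logger = logging.getLogger(__name__)

__all__ = [
    "PostureTransform",
    "pca_align",
    "fit_quadratic",
    "straighten",
    "orient_and_origin",
    "fine_align",
    "correct_posture",
]


@dataclass
class PostureTransform:
    """Record of the fitted posture-correction parameters for one animal."""

    pc_axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quad_coeffs: np.ndarray = field(default_factory=lambda: np.zeros((2, 3)))
    roll_angle: float = 0.0
    ap_origin: float = 0.0
    anterior_flipped: bool = False
    fine_alignment: SimilarityTransform | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.pc_axes, dtype=float)
        if np.linalg.norm(R @ R.T - np.eye(3)) > 1e-8:
            raise ValueError("pc_axes must be orthonormal")


def pca_align(sample: WormSample) -> tuple[WormSample, PostureTransform]:
    """Centre the cloud and rotate it into its principal-component frame.

    PC1 (largest variance) becomes x, PC2 becomes y, PC3 becomes z.  Axis
    signs are fixed deterministically (largest-magnitude component positive,
    right-handed frame).  Degenerate clouds (collinear or coplanar) raise.
    """
    X = sample.positions
    if sample.n_cells < 4:
        raise ValueError(f"animal {sample.animal_id!r}: need >= 4 cells for PCA")
    centroid = X.mean(axis=0)
    Xc = X - centroid
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    if svals[2] <= 1e-9 * max(svals[0], 1e-12):
        raise ValueError(
            f"animal {sample.animal_id!r}: degenerate (collinear/coplanar) cloud"
        )
    axes = Vt.copy()
    # deterministic signs: largest-|component| of each axis positive
    for k in range(3):
        j = int(np.argmax(np.abs(axes[k])))
        if axes[k, j] < 0:
            axes[k] *= -1.0
    if np.linalg.det(axes) < 0:  # keep a right-handed frame
        axes[2] *= -1.0
    aligned = Xc @ axes.T
    tf = PostureTransform(pc_axes=axes, centroid=centroid)
    return sample.with_positions(aligned), tf


def fit_quadratic(sample: WormSample) -> np.ndarray:
    """Least-squares quadratics of PC2 and PC3 versus PC1.

    Returns a (2, 3) array of coefficients (a, b, c) for
    y(x) = a x^2 + b x + c fitted independently for the y and z components.
    """
    X = sample.positions
    if X.shape[0] < 3:
        raise ValueError("fit_quadratic: need >= 3 cells")
    x = X[:, 0]
    coeffs = np.vstack([np.polyfit(x, X[:, k], 2) for k in (1, 2)])
    return coeffs


def straighten(sample: WormSample, quad_coeffs: np.ndarray) -> WormSample:
    """Remove the fitted body bend by subtracting the curve offset per cell.

    Each cell is shifted in the DV–LR plane by the curve value at its own AP
    coordinate; cross-sections move rigidly, so the cloud is not rescaled or
    deformed within the DV–LR plane.
    """
    quad_coeffs = np.asarray(quad_coeffs, dtype=float).reshape(2, 3)
    X = sample.positions.copy()
    for k in (1, 2):
        X[:, k] -= np.polyval(quad_coeffs[k - 1], X[:, 0])
    return sample.with_positions(X)


def _von_mises_density(theta: np.ndarray, grid: np.ndarray, kappa: float) -> np.ndarray:
    return np.exp(kappa * np.cos(grid[:, None] - theta[None, :])).sum(axis=1)


def orient_and_origin(
    sample: WormSample,
    kde_bandwidth: float = 5.0,
    roll_kappa: float = 100.0,
    n_grid: int = 512,
    flat_tol: float = 1e-3,
) -> tuple[WormSample, float, float]:
    """Fix roll (dorsal to +y), AP origin (density mode to x=0) and anterior.

    Dorsal is the sparsest angular direction of the cells projected to the
    DV–LR plane: a von Mises kernel density over cell angles (cells below
    the median radius excluded, to drop the uninformative dense core) is
    minimized on a grid and refined by bounded scalar optimization.  The AP
    origin is the mode of a Gaussian kernel density (bandwidth
    ``kde_bandwidth`` μm) along x, similarly refined.  Anterior is chosen as
    the side holding more cells within ±40 μm of the density mode; a flip
    negates x and z together so chirality is preserved.

    Returns the transformed sample, the roll angle applied (radians) and the
    AP origin (μm, in the input frame).
    """
    X = sample.positions.copy()
    yz = X[:, 1:3]
    radius = np.linalg.norm(yz, axis=1)
    theta = np.arctan2(yz[:, 1], yz[:, 0])  # angle from +y toward +z

    med_r = np.median(radius)
    keep = radius >= med_r - 1e-9 * max(med_r, 1.0)
    if keep.sum() < 8:
        keep = np.ones_like(keep)
    th = theta[keep]

    grid = np.linspace(0.0, 2 * np.pi, n_grid, endpoint=False)
    dens = _von_mises_density(th, grid, roll_kappa)
    rel_relief = (dens.max() - dens.min()) / max(dens.mean(), 1e-300)
    if rel_relief < flat_tol:
        warnings.warn(
            f"animal {sample.animal_id!r}: angular density nearly uniform; "
            "keeping default roll",
            stacklevel=2,
        )
        roll = 0.0
    else:
        k0 = int(np.argmin(dens))
        step = 2 * np.pi / n_grid
        f = lambda a: np.exp(roll_kappa * np.cos(a - th)).sum()  # noqa: E731
        res = minimize_scalar(
            f,
            bounds=(grid[k0] - step, grid[k0] + step),
            method="bounded",
            options={"xatol": 1e-12},
        )
        roll = float(res.x) % (2 * np.pi)

    c, s = np.cos(roll), np.sin(roll)
    y_new = c * X[:, 1] + s * X[:, 2]
    z_new = -s * X[:, 1] + c * X[:, 2]
    X[:, 1] = y_new
    X[:, 2] = z_new

    # AP origin: mode of the 1-D Gaussian KDE along x
    x = X[:, 0]
    h = kde_bandwidth
    xgrid = np.linspace(x.min() - h, x.max() + h, n_grid)
    dx = xgrid[1] - xgrid[0]
    kde = np.exp(-0.5 * ((xgrid[:, None] - x[None, :]) / h) ** 2).sum(axis=1)
    j0 = int(np.argmax(kde))
    g = lambda a: -np.exp(-0.5 * ((a - x) / h) ** 2).sum()  # noqa: E731
    res = minimize_scalar(
        g,
        bounds=(xgrid[j0] - dx, xgrid[j0] + dx),
        method="bounded",
        options={"xatol": 1e-12},
    )
    ap_origin = float(res.x)
    X[:, 0] = x - ap_origin

    # anterior toward negative x: larger cell count at x < 0 near the mode
    near = np.abs(X[:, 0]) <= 40.0
    n_neg = int(np.sum(X[near, 0] < 0))
    n_pos = int(np.sum(X[near, 0] > 0))
    if n_pos > n_neg:
        X[:, 0] *= -1.0
        X[:, 2] *= -1.0  # proper rotation, not a mirror
    elif n_pos == n_neg:
        warnings.warn(
            f"animal {sample.animal_id!r}: ambiguous anterior direction; "
            "keeping default orientation",
            stacklevel=2,
        )
    return sample.with_positions(X), roll, ap_origin


def fine_align(
    sample: WormSample, landmarks: dict[str, np.ndarray]
) -> tuple[WormSample, SimilarityTransform | None]:
    """Similarity-align the sample onto reference landmark positions.

    Fits a 7-parameter similarity (rotation + translation + isotropic scale)
    on named cells shared with ``landmarks`` and applies it to all cells.
    With fewer than 3 shared landmarks the sample is returned unchanged with
    a warning.
    """
    named = sample.named_cells(include_excluded=True)
    shared = sorted(set(named) & set(landmarks))
    if len(shared) < 3:
        warnings.warn(
            f"animal {sample.animal_id!r}: only {len(shared)} shared landmarks; "
            "fine alignment skipped",
            stacklevel=2,
        )
        return sample, None
    src = np.array([named[n] for n in shared])
    dst = np.array([np.asarray(landmarks[n], dtype=float) for n in shared])
    tf = fit_similarity(src, dst)
    resid = float(np.sqrt(((tf.apply(src) - dst) ** 2).sum(axis=1).mean()))
    logger.info(
        "animal %r: fine alignment on %d landmarks, rms residual %.3f um",
        sample.animal_id,
        len(shared),
        resid,
    )
    return sample.with_positions(tf.apply(sample.positions)), tf


def correct_posture(
    sample: WormSample,
    landmarks: dict[str, np.ndarray] | None = None,
    kde_bandwidth: float = 5.0,
) -> tuple[WormSample, PostureTransform]:
    """Full posture-correction pipeline for one animal.

    PCA alignment, quadratic straightening, roll/origin orientation, and
    optional landmark-based fine alignment.  The returned sample is in the
    canonical frame (x: AP, anterior negative; y: DV, dorsal positive;
    z: LR) with ``posture_state == "corrected"``.
    """
    aligned, tf = pca_align(sample)
    quad = fit_quadratic(aligned)
    flat = straighten(aligned, quad)
    oriented, roll, origin = orient_and_origin(flat, kde_bandwidth=kde_bandwidth)
    tf.quad_coeffs = quad
    tf.roll_angle = roll
    tf.ap_origin = origin
    out = oriented
    if landmarks is not None:
        out, fine_tf = fine_align(out, landmarks)
        tf.fine_alignment = fine_tf
    out = out.with_positions(out.positions, posture_state="corrected")
    return out, tf
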