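"""Small geometry helpers: similarity (Procrustes) fitting."""

from __future__ import annotations

import numpy as np

__all__ = ["SimilarityTransform", "fit_similarity"]


class SimilarityTransform:
    """x -> scale * rotation @ x + translation."""

    def __init__(self, rotation: np.ndarray, translation: np.ndarray, scale: float):
        self.rotation = np.asarray(rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(translation, dtype=float).reshape(3)
        self.scale = float(scale)
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation


def fit_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``src`` onto ``dst``.

    Umeyama's closed form: minimizes sum ||s R x_i + t - y_i||^2 over
    rotation R (det +1), isotropic scale s > 0 and translation t.
    Requires >= 3 non-degenerate point pairs.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[0] < 3:
        raise ValueError("fit_similarity needs matching (n>=3, 3) arrays")
    n = src.shape[0]
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    cov = dc.T @ sc / n
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    var_s = (sc**2).sum() / n
    if var_s <= 0:
        raise ValueError("degenerate source points")
    s = float(np.trace(np.diag(D) @ S) / var_s)
    t = mu_d - s * R @ mu_s
    return SimilarityTransform(rotation=R, translation=t, scale=s)
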