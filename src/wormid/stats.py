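"""Per-cell positional distributions and relative-position variation.

Across posture-corrected animals, each named cell's positions are modelled
as a trivariate Gaussian (mean and sample covariance).  The variation of the
relative position of a cell pair (X, Y) is

    V(X, Y) = det(cov(X - Y)),

the determinant of the 3x3 covariance of the per-animal difference vectors
— the squared volume scale of the relative-position ellipsoid.  A pair is
"less varying" than chance if the observed V is no larger than V computed
under every permutation of the animals of X (permutation test; exhaustive
for n <= 10 co-observations, randomly sampled otherwise).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model import CellDistribution, WormSample

__all__ = [
    "PairVariation",
    "estimate_distributions",
    "naive_assign",
    "neighbor_stats",
    "relative_variation",
    "permutation_test",
    "pair_variation_table",
]


@dataclass
class PairVariation:
    """Relative-position variation of one cell pair."""

    name_x: str
    name_y: str
    v: float
    n: int
    is_less_varying: bool | None = None
    n_permutations_used: int = 0


def estimate_distributions(samples: list[WormSample]) -> list[CellDistribution]:
    """Per-name position mean and sample covariance across animals.

    Covariance uses denominator n−1 and is ``None`` for names observed only
    once; names observed ≤ 3 times carry ``covariance_unreliable``.
    Raises if no sample has any named cell.
    """
    by_name: dict[str, list[np.ndarray]] = {}
    for s in samples:
        for name, pos in s.named_cells().items():
            by_name.setdefault(name, []).append(pos)
    if not by_name:
        raise ValueError("estimate_distributions: no named cells in any sample")
    out = []
    for name in sorted(by_name):
        P = np.array(by_name[name])
        cov = np.cov(P, rowvar=False, ddof=1) if P.shape[0] >= 2 else None
        out.append(
            CellDistribution(name=name, mean=P.mean(axis=0), covariance=cov, count=P.shape[0])
        )
    return out


def _component_logpdfs(
    positions: np.ndarray, distributions: list[CellDistribution], reg: float
) -> tuple[np.ndarray, list[str]]:
    comps = sorted(
        (d for d in distributions if d.covariance is not None), key=lambda d: d.name
    )
    if not comps:
        raise ValueError("naive_assign: no distributions with a valid covariance")
    logp = np.empty((positions.shape[0], len(comps)))
    for j, d in enumerate(comps):
        cov = d.covariance
        if np.linalg.eigvalsh(cov).min() < 1e-12:
            warnings.warn(
                f"{d.name}: singular covariance regularized by +{reg} I", stacklevel=3
            )
            cov = cov + reg * np.eye(3)
        diff = positions - d.mean
        L = np.linalg.cholesky(cov)
        sol = np.linalg.solve(L, diff.T)
        maha = (sol**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        logp[:, j] = -0.5 * (maha + logdet + 3 * np.log(2 * np.pi))
    return logp, [d.name for d in comps]


def naive_assign(
    sample: WormSample,
    distributions: list[CellDistribution],
    reg: float = 1e-6,
) -> dict[str, str]:
    """Maximum-density assignment under an equal-prior Gaussian mixture.

    Each cell independently receives the name of the component with the
    highest density at its position; duplicates are allowed.  Exact ties
    resolve to the lexicographically smaller name.  Singular covariances are
    regularized by ``+reg I`` with a warning.
    """
    logp, names = _component_logpdfs(sample.positions, distributions, reg)
    out: dict[str, str] = {}
    for i, cell in enumerate(sample.cells):
        row = logp[i]
        best = row.max()
        tied = [names[j] for j in np.flatnonzero(row >= best - 1e-12)]
        out[cell.cell_id] = min(tied)
    return out


def neighbor_stats(distributions: list[CellDistribution]) -> pd.DataFrame:
    """Nearest-centre distance and shortest ellipsoid axis per cell name.

    The shortest axis equals twice the square root of the smallest
    covariance eigenvalue (two standard deviations along the narrowest
    direction).  Only names with a covariance are included.
    """
    comps = [d for d in distributions if d.covariance is not None]
    if len(comps) < 2:
        raise ValueError("neighbor_stats: need >= 2 distributions with covariance")
    means = np.array([d.mean for d in comps])
    D = cdist(means, means)
    np.fill_diagonal(D, np.inf)
    rows = []
    for i, d in enumerate(comps):
        rows.append(
            {
                "name": d.name,
                "min_center_distance": float(D[i].min()),
                "shortest_axis": 2.0 * math.sqrt(max(np.linalg.eigvalsh(d.covariance)[0], 0.0)),
                "count": d.count,
            }
        )
    return pd.DataFrame(rows).set_index("name")


def _pair_observations(
    samples: list[WormSample], name_x: str, name_y: str
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for s in samples:
        named = s.named_cells()
        if name_x in named and name_y in named:
            xs.append(named[name_x])
            ys.append(named[name_y])
    return np.array(xs, dtype=float), np.array(ys, dtype=float)


def _det_cov(diffs: np.ndarray) -> float:
    # clamp: a covariance determinant is >= 0, roundoff can dip below
    return max(float(np.linalg.det(np.cov(diffs, rowvar=False, ddof=1))), 0.0)


def relative_variation(
    samples: list[WormSample], name_x: str, name_y: str
) -> PairVariation | None:
    """V(X, Y) = det(cov(X − Y)) over co-observing animals.

    Pairs co-observed in three or fewer animals are skipped (the covariance
    determinant is not meaningful there) and reported as ``None``.
    """
    X, Y = _pair_observations(samples, name_x, name_y)
    n = X.shape[0]
    if n <= 3:
        return None
    return PairVariation(name_x=name_x, name_y=name_y, v=_det_cov(X - Y), n=n)


def permutation_test(
    samples: list[WormSample],
    name_x: str,
    name_y: str,
    max_random: int = 10_000_000,
    seed: int | None = None,
    batch_size: int = 50_000,
) -> PairVariation | None:
    """Permutation test for a less-varying cell pair.

    The pair is flagged less-varying iff the observed V(X, Y) is <= V for
    every evaluated permutation of the animal order of X.  All n!
    permutations (identity included) are enumerated for n <= 10; for larger
    n, ``max_random`` permutations are drawn uniformly with replacement from
    the symmetric group using ``seed``.
    """
    X, Y = _pair_observations(samples, name_x, name_y)
    n = X.shape[0]
    if n <= 3:
        return None
    v_obs = _det_cov(X - Y)

    def batches():
        if n <= 10:
            it = itertools.permutations(range(n))
            while True:
                chunk = list(itertools.islice(it, batch_size))
                if not chunk:
                    return
                yield np.array(chunk, dtype=np.intp)
        else:
            rng = np.random.default_rng(seed)
            remaining = max_random
            while remaining > 0:
                b = min(batch_size, remaining)
                perms = rng.permuted(
                    np.tile(np.arange(n, dtype=np.intp), (b, 1)), axis=1
                )
                remaining -= b
                yield perms

    min_v = np.inf
    n_used = 0
    for perms in batches():
        D = X[perms] - Y[None, :, :]
        Dc = D - D.mean(axis=1, keepdims=True)
        covs = np.einsum("bni,bnj->bij", Dc, Dc) / (n - 1)
        dets = np.maximum(np.linalg.det(covs), 0.0)
        min_v = min(min_v, float(dets.min()))
        n_used += perms.shape[0]

    flag = v_obs <= min_v + 1e-12 * max(1.0, abs(v_obs))
    return PairVariation(
        name_x=name_x,
        name_y=name_y,
        v=v_obs,
        n=n,
        is_less_varying=bool(flag),
        n_permutations_used=n_used,
    )


def pair_variation_table(
    samples: list[WormSample],
    pairs: list[tuple[str, str]] | None = None,
    truncate: float = 5.0,
) -> pd.DataFrame:
    """V(X, Y) for many pairs, normalized by the median V for display.

    ``v_normalized`` is V divided by the median over all computed pairs,
    truncated at ``truncate`` (display convention); pairs with n <= 3 are
    omitted.
    """
    if pairs is None:
        names = sorted({n for s in samples for n in s.named_cells()})
        pairs = list(itertools.combinations(names, 2))
    rows = []
    for nx, ny in pairs:
        pv = relative_variation(samples, nx, ny)
        if pv is not None:
            rows.append({"name_x": nx, "name_y": ny, "v": pv.v, "n": pv.n})
    df = pd.DataFrame(rows, columns=["name_x", "name_y", "v", "n"])
    if not df.empty:
        med = df["v"].median()
        df["v_normalized"] = np.minimum(df["v"] / med if med > 0 else df["v"], truncate)
    return df
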