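"""Synthetic-atlas generation via displacement-flow alignment.

A fully annotated atlas is assembled from many partially annotated animals.
The first animal of a random order seeds the atlas with its named cells
(positions unchanged).  Each later animal is registered to the growing
atlas through a displacement flow interpolated from the cells they share:

    d(x) = sum_i N(x | x_i^src, Sigma) d_i / sum_i N(x | x_i^src, Sigma),

with d_i the displacement of shared cell i and Sigma = diag(sigma1^2, ...)
controlling smoothness (default 9.6 μm per axis).  Names new to the atlas
are carried through the flow; animals sharing fewer than half of their
annotated cells with the atlas are deferred and retried on later passes.
Orders whose seed animal has fewer than 60 annotated cells are rejected and
resampled.  Repeating over random orders yields a population of atlases
whose spread mirrors the inter-animal positional variation.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geom import fit_similarity
from .model import ReferenceAtlas, WormSample
from .stats import estimate_distributions, relative_variation

logger = logging.getLogger(__name__)

__all__ = [
    "DisplacementFlowParams",
    "SyntheticAtlas",
    "AtlasRejected",
    "displacement_flow",
    "assemble_atlas",
    "generate_atlases",
    "validate_atlases",
    "tune_sigma",
]

_LOG_UNDERFLOW = np.log(1e-300)


class AtlasRejected(Exception):
    """Raised when an assembly order fails the seed-animal rule."""


@dataclass
class DisplacementFlowParams:
    """Diagonal Gaussian kernel widths (μm) of the displacement flow."""

    sigma_diag: np.ndarray = field(default_factory=lambda: np.array([9.6, 9.6, 9.6]))

    def __post_init__(self) -> None:
        self.sigma_diag = np.asarray(self.sigma_diag, dtype=float).reshape(3)
        if np.any(self.sigma_diag <= 0):
            raise ValueError("all sigma must be positive")


@dataclass
class SyntheticAtlas:
    """One fully annotated atlas and its assembly provenance."""

    entries: dict[str, np.ndarray]
    provenance: list[str] = field(default_factory=list)
    filled_from_reference: set[str] = field(default_factory=set)
    channels: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.entries = {
            str(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.entries.items()
        }

    @property
    def names(self) -> list[str]:
        return sorted(self.entries)

    def positions(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.names
        return np.array([self.entries[n] for n in names])

    def __len__(self) -> int:
        return len(self.entries)


def displacement_flow(
    x: np.ndarray,
    shared_src: np.ndarray,
    shared_dst: np.ndarray,
    params: DisplacementFlowParams | None = None,
) -> np.ndarray:
    """Evaluate the Gaussian-kernel displacement flow at point(s) ``x``.

    Weights are Gaussian densities centred at the source positions; with a
    diagonal kernel the normalization constant cancels in the weighted
    average, so weights are computed in log space and always sum to one.  If
    every kernel underflows at an evaluation point (total weight below
    1e-300), the nearest shared cell's displacement is used with a warning.
    """
    params = params or DisplacementFlowParams()
    src = np.asarray(shared_src, dtype=float).reshape(-1, 3)
    dst = np.asarray(shared_dst, dtype=float).reshape(-1, 3)
    if src.shape != dst.shape or src.shape[0] < 1:
        raise ValueError("need >= 1 shared cell and equal-length lists")
    disp = dst - src
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = x.reshape(-1, 3)
    z = (pts[:, None, :] - src[None, :, :]) / params.sigma_diag
    logw = -0.5 * (z**2).sum(axis=2)  # (m, C), up to a common constant
    out = np.empty_like(pts)
    shift = logw.max(axis=1, keepdims=True)
    w = np.exp(logw - shift)
    w /= w.sum(axis=1, keepdims=True)
    out = w @ disp
    under = logw.max(axis=1) < _LOG_UNDERFLOW
    if np.any(under):
        warnings.warn(
            "displacement flow underflow at some points; "
            "falling back to nearest shared cell",
            stacklevel=2,
        )
        d2 = ((pts[under, None, :] - src[None, :, :]) ** 2).sum(axis=2)
        out[under] = disp[np.argmin(d2, axis=1)]
    return out[0] if single else out


def _annotated(sample: WormSample) -> dict[str, np.ndarray]:
    return sample.named_cells()


def assemble_atlas(
    ordered_samples: list[WormSample],
    reference: ReferenceAtlas | None = None,
    params: DisplacementFlowParams | None = None,
    min_first_annotated: int = 60,
    min_shared_fraction: float = 0.5,
) -> SyntheticAtlas:
    """Assemble one atlas from an ordered sequence of corrected animals.

    The seed animal's named cells enter unchanged; every later animal
    contributes its not-yet-present names mapped through the flow computed
    from the names it shares with the current atlas.  Animals sharing fewer
    than ``min_shared_fraction`` of their annotated cells are deferred and
    retried in later passes until a pass makes no progress; animals that
    never merge are dropped with a warning.  Names still missing afterwards
    are optionally filled from ``reference`` after a similarity alignment on
    shared names (recorded in ``filled_from_reference``).

    Raises :class:`AtlasRejected` when the seed animal has fewer than
    ``min_first_annotated`` annotated cells.
    """
    if not ordered_samples:
        raise ValueError("assemble_atlas: no samples")
    params = params or DisplacementFlowParams()
    seed_named = _annotated(ordered_samples[0])
    if len(seed_named) < min_first_annotated:
        raise AtlasRejected(
            f"seed animal {ordered_samples[0].animal_id!r} has "
            f"{len(seed_named)} < {min_first_annotated} annotated cells"
        )
    entries = {n: p.copy() for n, p in seed_named.items()}
    provenance = [ordered_samples[0].animal_id]
    pending = list(ordered_samples[1:])
    progress = True
    while pending and progress:
        progress = False
        deferred = []
        for s in pending:
            ann = _annotated(s)
            shared = [n for n in ann if n in entries]
            if not shared or len(shared) < min_shared_fraction * len(ann):
                deferred.append(s)
                continue
            new_names = [n for n in ann if n not in entries]
            if new_names:
                src = np.array([ann[n] for n in shared])
                dst = np.array([entries[n] for n in shared])
                pts = np.array([ann[n] for n in new_names])
                flows = displacement_flow(pts, src, dst, params)
                for n, p, d in zip(new_names, pts, flows):
                    entries[n] = p + d
            provenance.append(s.animal_id)
            progress = True
        pending = deferred
    if pending:
        warnings.warn(
            f"{len(pending)} animals never shared enough annotated cells "
            "with the atlas and were dropped",
            stacklevel=2,
        )
    filled: set[str] = set()
    if reference is not None:
        missing = [n for n in reference.entries if n not in entries]
        shared_ref = sorted(set(reference.entries) & set(entries))
        if missing:
            if len(shared_ref) >= 3:
                tf = fit_similarity(
                    np.array([reference.entries[n] for n in shared_ref]),
                    np.array([entries[n] for n in shared_ref]),
                )
                for n in missing:
                    entries[n] = tf.apply(reference.entries[n])[0]
                    filled.add(n)
            else:
                warnings.warn(
                    "reference fill-in skipped: fewer than 3 shared names",
                    stacklevel=2,
                )
    return SyntheticAtlas(
        entries=entries, provenance=provenance, filled_from_reference=filled
    )


def generate_atlases(
    samples: list[WormSample],
    n_atlases: int = 3000,
    params: DisplacementFlowParams | None = None,
    seed: int | None = None,
    reference: ReferenceAtlas | None = None,
    min_first_annotated: int = 60,
    min_shared_fraction: float = 0.5,
    max_reject_factor: int = 50,
) -> list[SyntheticAtlas]:
    """Generate ``n_atlases`` accepted atlases from seeded random orders.

    Rejected orders (seed animal under the annotation floor) are resampled
    and not counted.  Raises when no sample can ever satisfy the seed rule.
    """
    if len(samples) < 2:
        raise ValueError("generate_atlases: need >= 2 samples")
    if not any(len(_annotated(s)) >= min_first_annotated for s in samples):
        raise ValueError(
            "no animal satisfies the seed-annotation rule "
            f"(>= {min_first_annotated} annotated cells)"
        )
    rng = np.random.default_rng(seed)
    atlases: list[SyntheticAtlas] = []
    rejects = 0
    while len(atlases) < n_atlases:
        order = rng.permutation(len(samples))
        try:
            atlases.append(
                assemble_atlas(
                    [samples[i] for i in order],
                    reference=reference,
                    params=params,
                    min_first_annotated=min_first_annotated,
                    min_shared_fraction=min_shared_fraction,
                )
            )
        except AtlasRejected:
            rejects += 1
            if rejects > max_reject_factor * max(n_atlases, 1) + 100:
                raise RuntimeError("excessive rejected assembly orders")
    logger.info("generated %d atlases (%d rejected orders)", len(atlases), rejects)
    return atlases


def _atlas_population_samples(atlases: list[SyntheticAtlas]) -> list[WormSample]:
    from .model import CellRecord  # local import to avoid cycle at module load

    out = []
    for i, a in enumerate(atlases):
        cells = [
            CellRecord(cell_id=n, position=p, name=n) for n, p in a.entries.items()
        ]
        out.append(WormSample(animal_id=f"atlas{i:05d}", cells=cells, posture_state="corrected"))
    return out


def validate_atlases(
    atlases: list[SyntheticAtlas],
    samples: list[WormSample],
    pairs: list[tuple[str, str]] | None = None,
    max_pairs: int = 300,
    pair_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare the atlas population against the source data population.

    Per name present in both populations (with >= 2 observations each):
    distance between mean positions and the ellipsoid-volume ratio
    sqrt(det cov_atlas / det cov_data).  Per cell pair: the ratio of
    relative-position variations V_atlas / V_data, flagged low-n when the
    pair is co-observed fewer than 10 times in the data.  When ``pairs`` is
    not given, up to ``max_pairs`` random pairs are drawn (seeded).
    """
    if not atlases:
        raise ValueError("validate_atlases: no atlases")
    atlas_samples = _atlas_population_samples(atlases)
    dist_a = {d.name: d for d in estimate_distributions(atlas_samples)}
    dist_d = {d.name: d for d in estimate_distributions(samples)}
    rows = []
    for name in sorted(set(dist_a) & set(dist_d)):
        da, dd = dist_a[name], dist_d[name]
        row = {
            "name": name,
            "mean_distance": float(np.linalg.norm(da.mean - dd.mean)),
            "n_data": dd.count,
            "volume_ratio": np.nan,
        }
        if da.covariance is not None and dd.covariance is not None:
            det_a = max(np.linalg.det(da.covariance), 0.0)
            det_d = np.linalg.det(dd.covariance)
            if det_d > 0:
                row["volume_ratio"] = float(np.sqrt(det_a / det_d))
        rows.append(row)
    per_name = pd.DataFrame(rows, columns=["name", "mean_distance", "n_data", "volume_ratio"])
    if not per_name.empty:
        per_name = per_name.set_index("name")

    common = sorted(set(dist_a) & set(dist_d))
    if pairs is None:
        all_pairs = list(itertools.combinations(common, 2))
        if len(all_pairs) > max_pairs:
            rng = np.random.default_rng(pair_seed)
            idx = rng.choice(len(all_pairs), size=max_pairs, replace=False)
            all_pairs = [all_pairs[i] for i in sorted(idx)]
        pairs = all_pairs
    prows = []
    for nx, ny in pairs:
        pv_d = relative_variation(samples, nx, ny)
        pv_a = relative_variation(atlas_samples, nx, ny)
        if pv_d is None or pv_a is None or pv_d.v <= 0:
            continue
        prows.append(
            {
                "name_x": nx,
                "name_y": ny,
                "variation_ratio": pv_a.v / pv_d.v,
                "n_data": pv_d.n,
                "low_n": pv_d.n < 10,
            }
        )
    per_pair = pd.DataFrame(
        prows, columns=["name_x", "name_y", "variation_ratio", "n_data", "low_n"]
    )
    return per_name, per_pair


def tune_sigma(
    samples: list[WormSample],
    sigma_grid,
    n_atlases: int = 20,
    seed: int | None = 0,
    reference: ReferenceAtlas | None = None,
    min_first_annotated: int = 60,
    min_shared_fraction: float = 0.5,
) -> np.ndarray:
    """Grid search for the flow kernel width.

    Surrogate objective (the smoothness parameter is otherwise an empirical
    choice): mean per-name distance between atlas and data mean positions
    plus mean |log ellipsoid-volume ratio| from :func:`validate_atlases`.
    Ties (including a flat objective) resolve to the smallest sigma; grid
    points are evaluated in ascending order of their kernel volume.
    """
    grid = [np.broadcast_to(np.atleast_1d(np.asarray(g, dtype=float)), (3,)).copy()
            for g in sigma_grid]
    if not grid:
        raise ValueError("empty sigma grid")
    grid.sort(key=lambda s: tuple(s))
    best_sigma, best_obj = None, np.inf
    for sig in grid:
        atlases = generate_atlases(
            samples,
            n_atlases=n_atlases,
            params=DisplacementFlowParams(sigma_diag=sig),
            seed=seed,
            reference=reference,
            min_first_annotated=min_first_annotated,
            min_shared_fraction=min_shared_fraction,
        )
        per_name, _ = validate_atlases(atlases, samples, pairs=[])
        dist_term = float(per_name["mean_distance"].mean()) if len(per_name) else np.inf
        vr = per_name["volume_ratio"].dropna()
        vr = vr[vr > 0]  # singular atlas covariances carry no volume signal
        vol_term = float(np.abs(np.log(vr)).mean()) if len(vr) else 0.0
        obj = dist_term + vol_term
        logger.info("tune_sigma: sigma=%s objective=%.4f", sig, obj)
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_sigma = sig
    if best_sigma is None:  # flat/non-informative objective: smallest sigma
        best_sigma = grid[0]
    return best_sigma
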