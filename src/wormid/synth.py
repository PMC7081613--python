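"""Synthetic worm generator with known ground truth.

Emulates the statistical structure of a head-neuron position dataset so
every pipeline stage is testable without real data:

* a ground-truth cell map of ~200 named cells packed (>= 1.5 μm apart) in a
  head-shaped ellipsoidal volume of about 60 x 30 x 30 μm, densest around
  the mid-head (lateral-ganglion-like cluster) with an anterior-skewed tail
  and a dorsal angular gap (so the posture-correction heuristics for
  anterior and dorsal are well posed);
* per-animal Gaussian positional jitter (default sd 1.35 μm per axis, set
  from the scale of the measured shortest ellipsoid axes), optional
  correlated pairs sharing a common displacement, and random cell dropout;
* partial annotation: each animal carries one cell-specific promoter whose
  cells are named with the promoter's positive ratio, plus an always-named
  dye-like subset;
* binary landmark channels from a ground-truth bit per cell, with optional
  flip noise;
* a raw view of each animal with quadratic body bend and random rigid
  placement applied, for exercising posture correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .model import CellRecord, WormSample

__all__ = [
    "GroundTruthMap",
    "VariationModel",
    "Cohort",
    "make_ground_truth",
    "sample_worm",
    "make_cohort",
    "default_promoters",
]


@dataclass
class GroundTruthMap:
    """The true cell map: names, base positions and landmark-bit truth."""

    names: list[str]
    base_positions: dict[str, np.ndarray]
    channel_truth: dict[str, np.ndarray]
    half_axes: tuple[float, float, float] = (30.0, 15.0, 15.0)

    @property
    def n_channels(self) -> int:
        first = next(iter(self.channel_truth.values()))
        return int(np.asarray(first).size)

    def positions(self) -> np.ndarray:
        return np.array([self.base_positions[n] for n in self.names])


@dataclass
class VariationModel:
    """Inter-animal variation and annotation model for the generator."""

    iid_sd: np.ndarray = field(default_factory=lambda: np.array([1.35, 1.35, 1.35]))
    correlated_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    detection_rate: float = 0.97
    dye_fraction: float = 0.18
    bend_coeff_range: float = 0.005
    translation_range: float = 50.0
    channel_flip: float = 0.0

    def __post_init__(self) -> None:
        self.iid_sd = np.broadcast_to(
            np.atleast_1d(np.asarray(self.iid_sd, dtype=float)), (3,)
        ).copy()
        if np.any(self.iid_sd < 0):
            raise ValueError("iid_sd must be >= 0")
        for p in (self.detection_rate, self.dye_fraction, self.channel_flip):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def make_ground_truth(
    n_cells: int = 200,
    seed: int | None = None,
    n_channels: int = 2,
    half_axes: tuple[float, float, float] = (30.0, 15.0, 15.0),
    min_spacing: float = 1.5,
    dorsal_gap_deg: float = 50.0,
    max_attempts_per_cell: int = 2000,
) -> GroundTruthMap:
    """Reproducible packed ground-truth map inside the head volume.

    Cells are rejection-sampled with a minimum centre spacing; the AP
    profile mixes a mid-head Gaussian cluster with a uniform anterior tail,
    and a dorsal wedge of ``dorsal_gap_deg`` degrees is kept empty.  Raises
    when the packing cannot be achieved.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    rng = np.random.default_rng(seed)
    a, b, c = half_axes
    gap_half = np.deg2rad(dorsal_gap_deg) / 2.0
    accepted: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_cell * n_cells
    while len(accepted) < n_cells:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"packing infeasible: placed {len(accepted)}/{n_cells} cells"
            )
        if rng.random() < 0.6:
            x = rng.normal(0.25 * a, 0.2 * a)  # mid-head cluster
        else:
            x = rng.uniform(-a, 0.25 * a)  # anterior tail
        if not -a < x < a:
            continue
        shrink = np.sqrt(max(1.0 - (x / a) ** 2, 0.0))
        y = rng.uniform(-b, b) * shrink
        z = rng.uniform(-c, c) * shrink
        if (y / (b * shrink + 1e-12)) ** 2 + (z / (c * shrink + 1e-12)) ** 2 > 1.0:
            continue
        if abs(np.arctan2(z, y)) < gap_half:  # dorsal wedge kept sparse
            continue
        p = np.array([x, y, z])
        if accepted and cdist(p[None], np.array(accepted)).min() < min_spacing:
            continue
        accepted.append(p)
    names = [f"N{i:03d}" for i in range(n_cells)]
    positions = {n: accepted[i] for i, n in enumerate(names)}
    bits = rng.random((n_cells, n_channels)) < 0.35
    channel_truth = {n: bits[i].astype(np.uint8) for i, n in enumerate(names)}
    return GroundTruthMap(
        names=names,
        base_positions=positions,
        channel_truth=channel_truth,
        half_axes=half_axes,
    )


def _bend_and_place(
    positions: np.ndarray, model: VariationModel, rng: np.random.Generator
) -> np.ndarray:
    X = positions.copy()
    a_y, a_z = rng.uniform(-model.bend_coeff_range, model.bend_coeff_range, size=2)
    X[:, 1] += a_y * X[:, 0] ** 2
    X[:, 2] += a_z * X[:, 0] ** 2
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-model.translation_range, model.translation_range, size=3)
    return X @ R.T + t


def sample_worm(
    truth: GroundTruthMap,
    model: VariationModel,
    animal_id: str,
    seed: int | None = None,
    promoter: str | None = None,
    promoter_names: set[str] | None = None,
    promoter_positive_ratio: float = 1.0,
    dye_names: set[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[WormSample, WormSample, dict[str, str]]:
    """Draw one animal: (raw, ideal-corrected, full truth-name map).

    The ideal sample lives in the canonical corrected frame (truth + jitter
    + shared displacements); the raw sample additionally carries quadratic
    bend and a random rigid placement.  Only the animal's promoter subset
    (each name kept with the promoter's positive ratio) plus the dye-like
    subset are annotated; the returned map carries the truth for every
    detected cell.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    names = truth.names
    P = truth.positions()
    P = P + rng.normal(0.0, 1.0, size=P.shape) * model.iid_sd
    idx_of = {n: i for i, n in enumerate(names)}
    for n1, n2, sd in model.correlated_pairs:
        shared = rng.normal(0.0, sd, size=3)
        P[idx_of[n1]] += shared
        P[idx_of[n2]] += shared

    detected = rng.random(len(names)) < model.detection_rate
    if detected.sum() < 4:
        detected[:4] = True

    annotated: set[str] = set(dye_names or set())
    if promoter_names:
        for n in promoter_names:
            if rng.random() < promoter_positive_ratio:
                annotated.add(n)

    ideal_cells, raw_positions, truth_names = [], [], {}
    det_idx = np.flatnonzero(detected)
    for k, i in enumerate(det_idx):
        name = names[i]
        cid = f"c{k:03d}"
        truth_names[cid] = name
        bits = truth.channel_truth[name].copy()
        if model.channel_flip > 0:
            flip = rng.random(bits.shape) < model.channel_flip
            bits = np.where(flip, 1 - bits, bits).astype(np.uint8)
        ideal_cells.append(
            CellRecord(
                cell_id=cid,
                position=P[i],
                name=name if name in annotated else None,
                channels=bits,
            )
        )
    ideal = WormSample(
        animal_id=animal_id,
        cells=ideal_cells,
        posture_state="corrected",
        promoter_id=promoter,
    )
    raw_positions = _bend_and_place(ideal.positions, model, rng)
    raw = ideal.with_positions(raw_positions, posture_state="raw")
    raw = WormSample(
        animal_id=animal_id,
        cells=raw.cells,
        posture_state="raw",
        promoter_id=promoter,
    )
    return raw, ideal, truth_names


def default_promoters(
    truth: GroundTruthMap,
    n_promoters: int = 6,
    expressed_fraction: float = 0.3,
    positive_ratio: float = 0.9,
    seed: int | None = None,
) -> list[tuple[str, set[str], float]]:
    """Invent a promoter list: each labels a random ~30% subset of cells."""
    rng = np.random.default_rng(seed)
    out = []
    n_expr = max(2, int(round(expressed_fraction * len(truth.names))))
    for j in range(n_promoters):
        subset = set(rng.choice(truth.names, size=n_expr, replace=False))
        out.append((f"prom{j:02d}", subset, positive_ratio))
    return out


@dataclass
class Cohort:
    """A generated cohort and the tables the pipeline stages consume."""

    raw: list[WormSample]
    ideal: list[WormSample]
    truth_names: dict[str, dict[str, str]]
    expression_counts: pd.DataFrame
    tested_animals: pd.Series
    promoters: list[tuple[str, set[str], float]]
    dye_names: set[str]
    truth: GroundTruthMap


def make_cohort(
    truth: GroundTruthMap,
    model: VariationModel,
    n_animals: int,
    seed: int | None = None,
    promoters: list[tuple[str, set[str], float]] | None = None,
) -> Cohort:
    """Generate a cohort with per-animal promoter assignment cycling.

    Each animal carries one promoter (cycling through the list, mimicking a
    multi-strain design); an expression-count table (positive animals per
    promoter and cell) is accumulated for the panel-optimization stage.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    rng = np.random.default_rng(seed)
    if promoters is None:
        promoters = default_promoters(truth, seed=int(rng.integers(2**31 - 1)))
    n_dye = max(3, int(round(model.dye_fraction * len(truth.names))))
    dye_names = set(rng.choice(truth.names, size=n_dye, replace=False))

    counts = pd.DataFrame(
        0, index=[p for p, _, _ in promoters], columns=list(truth.names), dtype=int
    )
    tested = pd.Series(0, index=counts.index, dtype=int)
    raws, ideals, truth_maps = [], [], {}
    for i in range(n_animals):
        prom_id, subset, ratio = promoters[i % len(promoters)]
        raw, ideal, tmap = sample_worm(
            truth,
            model,
            animal_id=f"w{i:03d}",
            promoter=prom_id,
            promoter_names=subset,
            promoter_positive_ratio=ratio,
            dye_names=dye_names,
            rng=rng,
        )
        tested[prom_id] += 1
        positive = {c.name for c in ideal.cells if c.name is not None} & subset
        for name in positive:
            counts.at[prom_id, name] += 1
        raws.append(raw)
        ideals.append(ideal)
        truth_maps[ideal.animal_id] = tmap
    tested = tested.clip(lower=1)
    return Cohort(
        raw=raws,
        ideal=ideals,
        truth_names=truth_maps,
        expression_counts=counts,
        tested_animals=tested,
        promoters=promoters,
        dye_names=dye_names,
        truth=truth,
    )
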