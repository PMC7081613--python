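"""Promoter expression scoring and landmark-panel optimization.

A fluorescent landmark panel assigns cell-specific promoters to color
channels.  A good panel colors neighbouring cells differently (a
"checkerboard" pattern), which is captured by the metric

    M = 1/2 * sum_X sum_Y I(L_X, L_Y) * w(X, Y),

where I is 1 when the two cells' channel-label vectors differ and
w(X, Y) = N(X | Y, sigma) is an isotropic trivariate Gaussian density of the
inter-cell distance (sigma = 9.6 μm per axis by default).  Panels of up to
three promoters over two distinguishable channels are enumerated
exhaustively and ranked by M.

Expression statistics: the positive ratio p_X of a promoter for a cell is
the fraction of tested animals in which the cell expresses the landmark;
stability s is the mean of p_X over cells with p_X > 0; sparseness of a
single promoter is M with binary expressed/not-expressed labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ExpressionTable",
    "PanelAssignment",
    "positive_ratio",
    "stability",
    "checkerboard_metric",
    "sparseness",
    "enumerate_panels",
    "expected_labels",
    "rank_panels",
]


@dataclass
class ExpressionTable:
    """Per-promoter positive ratios p_X and tested-animal counts m.

    ``ratios`` is a DataFrame with promoters as rows, cell names as columns
    and values in [0, 1] (0 = never observed positive).  ``m`` gives the
    number of tested animals per promoter.
    """

    ratios: pd.DataFrame
    m: pd.Series

    def __post_init__(self) -> None:
        vals = self.ratios.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("positive ratios must lie in [0, 1]")
        if np.any(self.m.to_numpy() < 1):
            raise ValueError("tested-animal counts must be >= 1")

    @property
    def promoters(self) -> list[str]:
        return list(self.ratios.index)


def positive_ratio(counts: pd.DataFrame, m: pd.Series | int) -> ExpressionTable:
    """p_X = n_X / m from positive-animal counts.

    ``counts`` holds n_X per (promoter, cell name); ``m`` is the tested
    animal count, per promoter or a single integer.  Counts exceeding m
    raise.
    """
    if isinstance(m, int):
        m = pd.Series(m, index=counts.index)
    m = m.reindex(counts.index)
    if m.isna().any():
        raise ValueError("missing tested-animal count for some promoter")
    vals = counts.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > m.to_numpy()[:, None]):
        raise ValueError("counts must satisfy 0 <= n_X <= m")
    return ExpressionTable(ratios=counts.div(m, axis=0), m=m.astype(int))


def stability(table: ExpressionTable, promoter: str) -> float | None:
    """Mean positive ratio over cells the promoter labels at least once.

    ``None`` when the promoter has no positive cell at all.
    """
    row = table.ratios.loc[promoter]
    pos = row[row > 0]
    if pos.empty:
        return None
    return float(pos.mean())


def _label_matrix(names: list[str], labels: dict) -> np.ndarray:
    return np.array([np.atleast_1d(np.asarray(labels[n])) for n in names])


def checkerboard_metric(
    positions: dict[str, np.ndarray],
    labels: dict[str, tuple | np.ndarray],
    sigma: float = 9.6,
) -> float:
    """Gaussian-weighted count of differently-labelled neighbouring pairs.

    Every cell in ``positions`` must appear in ``labels``.  Pairs with
    identical label vectors contribute nothing; the double sum is halved so
    each unordered pair counts once.  The Gaussian density keeps its
    normalization constant (a global scale that leaves rankings unchanged).
    """
    names = sorted(positions)
    if not names:
        return 0.0
    P = np.array([np.asarray(positions[n], dtype=float) for n in names])
    L = _label_matrix(names, labels)
    d2 = squareform(pdist(P, metric="sqeuclidean"))
    W = (2 * np.pi * sigma**2) ** -1.5 * np.exp(-d2 / (2 * sigma**2))
    diff = (L[:, None, :] != L[None, :, :]).any(axis=2)
    return float(0.5 * W[diff].sum())


def sparseness(
    positions: dict[str, np.ndarray], expressed: set[str], sigma: float = 9.6
) -> float:
    """Checkerboard score of a single promoter against the unlabelled rest."""
    labels = {n: (1,) if n in expressed else (0,) for n in positions}
    return checkerboard_metric(positions, labels, sigma=sigma)


@dataclass
class PanelAssignment:
    """Promoter-to-channel assignment with its checkerboard score."""

    channel_promoters: tuple[frozenset[str], ...]
    score: float | None = None
    rank: int | None = None
    overlap_count: int | None = None

    def __post_init__(self) -> None:
        all_proms = [p for ch in self.channel_promoters for p in ch]
        if len(set(all_proms)) != len(all_proms):
            raise ValueError("a promoter may appear in at most one channel")

    @property
    def key(self) -> tuple:
        """Deterministic lexicographic sort key."""
        return tuple(tuple(sorted(ch)) for ch in self.channel_promoters)

    def __str__(self) -> str:
        return " | ".join("+".join(sorted(ch)) or "-" for ch in self.channel_promoters)


def enumerate_panels(
    promoters, n_channels: int = 2, max_total: int = 3
) -> list[PanelAssignment]:
    """All promoter-to-channel assignments for two distinguishable channels.

    Two-promoter panels place one distinct promoter per channel (ordered:
    n(n−1) assignments); three-promoter panels place a singleton in channel 1
    and an unordered pair in channel 2 (n·C(n−1, 2) assignments — the metric
    is invariant under swapping channels, so the mirrored arrangement is
    redundant).  For 35 promoters this yields the full set of 20,825
    combinations.
    """
    if isinstance(promoters, int):
        promoters = [f"P{i:02d}" for i in range(promoters)]
    ids = sorted(str(p) for p in promoters)
    if n_channels != 2:
        raise NotImplementedError("only two-channel panels are enumerated")
    if not 2 <= max_total <= 3:
        raise ValueError("max_total must be 2 or 3")
    if len(ids) < n_channels:
        raise ValueError("need at least as many promoters as channels")
    panels = [
        PanelAssignment(channel_promoters=(frozenset([a]), frozenset([b])))
        for a, b in itertools.permutations(ids, 2)
    ]
    if max_total == 3 and len(ids) >= 3:
        for s in ids:
            rest = [p for p in ids if p != s]
            for pair in itertools.combinations(rest, 2):
                panels.append(
                    PanelAssignment(
                        channel_promoters=(frozenset([s]), frozenset(pair))
                    )
                )
    return panels


def expected_labels(
    table: ExpressionTable, panel: PanelAssignment, threshold: float = 0.5
) -> dict[str, tuple[int, ...]]:
    """Expected per-cell channel bits for a panel.

    A cell counts as positive for a channel when the maximum positive ratio
    over the channel's promoters reaches ``threshold``.
    """
    out: dict[str, tuple[int, ...]] = {}
    for name in table.ratios.columns:
        bits = []
        for ch in panel.channel_promoters:
            p = max((table.ratios.at[prom, name] for prom in ch), default=0.0)
            bits.append(1 if p >= threshold else 0)
        out[name] = tuple(bits)
    return out


def rank_panels(
    positions: dict[str, np.ndarray],
    table: ExpressionTable,
    panels: list[PanelAssignment],
    sigma: float = 9.6,
    threshold: float = 0.5,
) -> list[PanelAssignment]:
    """Score panels by the checkerboard metric and sort best-first.

    Cells are scored at their reference positions with labels from
    :func:`expected_labels`.  Ties break by the panel's lexicographic key;
    rank 1 is best.  ``overlap_count`` reports cells expected positive in
    both channels simultaneously.
    """
    scored = []
    for p in panels:
        labels = expected_labels(table, p, threshold=threshold)
        labels = {n: labels.get(n, (0,) * len(p.channel_promoters)) for n in positions}
        score = checkerboard_metric(positions, labels, sigma=sigma)
        overlap = sum(1 for bits in labels.values() if all(b == 1 for b in bits))
        scored.append(
            PanelAssignment(
                channel_promoters=p.channel_promoters,
                score=score,
                overlap_count=overlap,
            )
        )
    scored.sort(key=lambda p: (-p.score, p.key))
    for i, p in enumerate(scored):
        p.rank = i + 1
    return scored
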