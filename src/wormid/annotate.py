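"""Cell-identity annotation by bipartite matching and majority voting.

Target cells are matched one-to-one to atlas names by minimizing a weighted
sum of feature dissimilarities,

    A = w_distance * A_position + w_landmark * A_landmark,

with Euclidean position distance (μm), per-channel Hamming distance of the
binarized landmark-expression bits, and default weights w_distance = 1,
w_landmark = 20.  Human corrections are hard constraints: assignments
incompatible with a fixed annotation get infinite dissimilarity.  Repeating
the matching against many atlases gives one vote per round; candidates per
cell are ranked by vote count.  The rank-R error rate is
1 − N_correct/N_annotated, a cell counting correct when its true name
appears among its top R candidates; cells without a ground-truth name are
ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .atlas import SyntheticAtlas, generate_atlases
from .model import WormSample

logger = logging.getLogger(__name__)

__all__ = [
    "MatchCost",
    "AnnotationResult",
    "position_cost",
    "landmark_cost",
    "build_cost",
    "constrain",
    "match",
    "vote",
    "resolve_unique",
    "error_rate",
    "cross_validate",
    "sequential_correction",
]

DEFAULT_WEIGHTS = {"w_distance": 1.0, "w_landmark": 20.0}


@dataclass
class MatchCost:
    """Dissimilarity matrix between target cells and atlas names.

    Entries are nonnegative; forbidden assignments are ``inf``.
    """

    matrix: np.ndarray
    target_ids: list[str]
    names: list[str]
    feature_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.target_ids), len(self.names)):
            raise ValueError("cost matrix shape mismatch")
        if np.any(self.matrix < 0):
            raise ValueError("cost entries must be >= 0")


def _target_cells(sample: WormSample) -> list:
    return [c for c in sample.cells if not c.is_excluded]


def position_cost(target: WormSample, atlas: SyntheticAtlas) -> np.ndarray:
    """Euclidean distances (μm) between target cells and atlas entries."""
    cells = _target_cells(target)
    P = np.array([c.position for c in cells])
    return cdist(P, atlas.positions())


def landmark_cost(
    target: WormSample, atlas_channels: dict[str, np.ndarray], names: list[str] | None = None
) -> np.ndarray:
    """Hamming distance between landmark bit-vectors (one per mismatch)."""
    cells = _target_cells(target)
    names = names if names is not None else sorted(atlas_channels)
    A = np.array([np.asarray(atlas_channels[n], dtype=np.uint8) for n in names])
    T = np.array([c.channels for c in cells], dtype=np.uint8)
    if T.shape[1] != A.shape[1]:
        raise ValueError(
            f"channel-vector length mismatch: target {T.shape[1]} vs atlas {A.shape[1]}"
        )
    return (T[:, None, :] != A[None, :, :]).sum(axis=2).astype(float)


def build_cost(
    target: WormSample,
    atlas: SyntheticAtlas,
    weights: dict[str, float] | None = None,
    fixed: dict[str, str] | None = None,
) -> MatchCost:
    """Assemble the weighted-feature cost matrix for one atlas.

    The landmark term enters only when both the target carries channel bits
    and the atlas has expected channel bits.  ``fixed`` applies human
    constraints via :func:`constrain`.
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    names = atlas.names
    cells = _target_cells(target)
    M = w["w_distance"] * position_cost(target, atlas)
    if target.n_channels and atlas.channels is not None:
        M = M + w["w_landmark"] * landmark_cost(target, atlas.channels, names=names)
    cost = MatchCost(
        matrix=M, target_ids=[c.cell_id for c in cells], names=names, feature_weights=w
    )
    if fixed:
        cost = constrain(cost, fixed)
    return cost


def constrain(cost: MatchCost, fixed: dict[str, str]) -> MatchCost:
    """Force fixed cell -> name assignments via infinite dissimilarity.

    A fixed cell's row becomes ``inf`` except at its fixed name, and that
    name's column becomes ``inf`` except at the fixed cell.  Fixing two
    cells to the same name, or to a name absent from the atlas, raises.
    """
    if not fixed:
        return cost
    used: dict[str, str] = {}
    for cid, name in fixed.items():
        if name in used:
            raise ValueError(
                f"cells {used[name]!r} and {cid!r} both fixed to name {name!r}"
            )
        used[name] = cid
    M = cost.matrix.copy()
    row_of = {cid: i for i, cid in enumerate(cost.target_ids)}
    col_of = {n: j for j, n in enumerate(cost.names)}
    for cid, name in fixed.items():
        if cid not in row_of:
            continue  # constraint on a cell not present in this target
        if name not in col_of:
            raise KeyError(f"fixed name {name!r} not present in atlas")
        i, j = row_of[cid], col_of[name]
        keep = M[i, j]
        M[i, :] = np.inf
        M[:, j] = np.inf
        M[i, j] = keep
    return MatchCost(
        matrix=M,
        target_ids=cost.target_ids,
        names=cost.names,
        feature_weights=cost.feature_weights,
    )


def match(cost: MatchCost) -> dict[str, str]:
    """Minimum-total-cost one-to-one assignment (Hungarian algorithm).

    Rectangular matrices are handled: the surplus side stays unmatched.  If
    no complete matching of the smaller side avoids ``inf``, the maximal
    feasible matching is returned instead (forbidden assignments dropped).
    Rows that are entirely ``inf`` raise, listing the blocking cells.
    """
    M = cost.matrix
    blocked = [cost.target_ids[i] for i in np.flatnonzero(~np.isfinite(M).any(axis=1))]
    if blocked:
        raise ValueError(f"infeasible constraints: no finite assignment for {blocked}")
    try:
        rows, cols = linear_sum_assignment(M)
    except ValueError:
        finite = M[np.isfinite(M)]
        big = float(finite.sum()) + 1.0 if finite.size else 1.0
        rows, cols = linear_sum_assignment(np.where(np.isfinite(M), M, big))
    return {
        cost.target_ids[i]: cost.names[j]
        for i, j in zip(rows, cols)
        if np.isfinite(M[i, j])
    }


@dataclass
class AnnotationResult:
    """Ranked candidate names per target cell from repeated matchings."""

    ranking: dict[str, list[tuple[str, int]]]
    n_rounds: int
    fixed: dict[str, str] = field(default_factory=dict)

    def top(self, cell_id: str, rank: int = 1) -> list[str]:
        """The top-``rank`` candidate names for a cell (may be shorter)."""
        return [name for name, _ in self.ranking.get(cell_id, [])[:rank]]

    def rank1(self) -> dict[str, str]:
        return {cid: lst[0][0] for cid, lst in self.ranking.items() if lst}

    def to_frame(self, animal_id: str = "") -> pd.DataFrame:
        rows = []
        for cid, lst in self.ranking.items():
            for r, (name, votes) in enumerate(lst, start=1):
                rows.append(
                    {
                        "animal_id": animal_id,
                        "cell_id": cid,
                        "rank": r,
                        "name": name,
                        "votes": votes,
                    }
                )
        return pd.DataFrame(rows, columns=["animal_id", "cell_id", "rank", "name", "votes"])


def _select_rounds(
    atlases: list[SyntheticAtlas], n_rounds: int, rng: np.random.Generator
) -> list[SyntheticAtlas]:
    if n_rounds < len(atlases):
        idx = rng.choice(len(atlases), size=n_rounds, replace=False)
        return [atlases[i] for i in idx]
    if n_rounds == len(atlases):
        return list(atlases)
    idx = rng.choice(len(atlases), size=n_rounds, replace=True)
    return [atlases[i] for i in idx]


def vote(
    target: WormSample,
    atlases: list[SyntheticAtlas],
    weights: dict[str, float] | None = None,
    fixed: dict[str, str] | None = None,
    n_rounds: int = 500,
    seed: int | None = None,
) -> AnnotationResult:
    """Majority voting over repeated bipartite matchings.

    ``n_rounds`` atlases are drawn uniformly without replacement from the
    pool (with replacement if the pool is smaller); each matching casts one
    vote per matched cell.  Candidates per cell are ranked by vote count,
    ties broken by lower mean position cost of the rounds that cast the
    vote, then lexicographically.  Estimations are independent across cells,
    so different cells may share a rank-1 name.
    """
    if not atlases:
        raise ValueError("vote: need >= 1 atlas")
    rng = np.random.default_rng(seed)
    pool = _select_rounds(atlases, n_rounds, rng)
    votes: dict[str, dict[str, int]] = {}
    cost_sums: dict[str, dict[str, float]] = {}
    for atl in pool:
        cost = build_cost(target, atl, weights=weights, fixed=fixed)
        pos = position_cost(target, atl)
        col_of = {n: j for j, n in enumerate(cost.names)}
        assignment = match(cost)
        row_of = {cid: i for i, cid in enumerate(cost.target_ids)}
        for cid, name in assignment.items():
            votes.setdefault(cid, {})[name] = votes.get(cid, {}).get(name, 0) + 1
            cost_sums.setdefault(cid, {})[name] = (
                cost_sums.get(cid, {}).get(name, 0.0) + pos[row_of[cid], col_of[name]]
            )
    ranking: dict[str, list[tuple[str, int]]] = {}
    for cid in (c.cell_id for c in _target_cells(target)):
        cand = votes.get(cid, {})
        order = sorted(
            cand,
            key=lambda nm: (-cand[nm], cost_sums[cid][nm] / cand[nm], nm),
        )
        ranking[cid] = [(nm, cand[nm]) for nm in order]
    return AnnotationResult(ranking=ranking, n_rounds=len(pool), fixed=dict(fixed or {}))


def resolve_unique(result: AnnotationResult) -> dict[str, str]:
    """Non-overlapping naming from the vote table.

    Builds a cost matrix of (n_rounds − votes) over all voted names and
    solves the assignment, so each name is used at most once and highly
    voted cells keep their names.
    """
    cells = [cid for cid, lst in result.ranking.items() if lst]
    if not cells:
        return {}
    names = sorted({nm for cid in cells for nm, _ in result.ranking[cid]})
    col_of = {n: j for j, n in enumerate(names)}
    M = np.full((len(cells), len(names)), float(result.n_rounds))
    for i, cid in enumerate(cells):
        for nm, v in result.ranking[cid]:
            M[i, col_of[nm]] = result.n_rounds - v
    rows, cols = linear_sum_assignment(M)
    return {cells[i]: names[j] for i, j in zip(rows, cols)}


def error_rate(
    predicted: AnnotationResult | dict[str, str],
    truth: dict[str, str],
    rank: int = 1,
) -> float | None:
    """Rank-R error rate: 1 − N_correct / N_annotated.

    A cell is correct when its true name appears among its top ``rank``
    candidates.  Cells without a ground-truth name are ignored; ``None``
    when nothing is annotated.
    """
    if isinstance(predicted, AnnotationResult):
        cells = set(predicted.ranking)
        tops = {cid: predicted.top(cid, rank) for cid in cells}
    else:
        cells = set(predicted)
        tops = {cid: [predicted[cid]] for cid in cells}
    annotated = [cid for cid in truth if cid in cells]
    if not annotated:
        return None
    n_correct = sum(1 for cid in annotated if truth[cid] in tops[cid])
    return 1.0 - n_correct / len(annotated)


def cross_validate(
    samples: list[WormSample],
    k: int = 5,
    seed: int | None = None,
    n_atlases: int = 100,
    n_rounds: int = 50,
    ranks: tuple[int, ...] = (1, 5),
    weights: dict[str, float] | None = None,
    min_annotated: int = 30,
    params=None,
    reference=None,
    min_first_annotated: int = 60,
    min_shared_fraction: float = 0.5,
    atlas_channels: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """k-fold cross-validation of the annotation pipeline.

    Animals are randomly split into ``k`` folds (seeded).  For each fold,
    atlases are built from the training animals only; held-out animals with
    at least ``min_annotated`` named cells are annotated by voting and
    scored with their own annotations as ground truth.  Returns one row per
    (fold, animal) with a rank-R error column per requested rank; folds with
    no evaluable animal contribute a single all-NaN row.
    """
    if len(samples) < k:
        raise ValueError("cross_validate: need >= k samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    folds = np.array_split(order, k)
    rows = []
    for f, test_idx in enumerate(folds):
        test_set = set(int(i) for i in test_idx)
        train = [s for i, s in enumerate(samples) if i not in test_set]
        atlases = generate_atlases(
            train,
            n_atlases=n_atlases,
            params=params,
            seed=int(rng.integers(2**31 - 1)),
            reference=reference,
            min_first_annotated=min_first_annotated,
            min_shared_fraction=min_shared_fraction,
        )
        if atlas_channels is not None:
            for a in atlases:
                a.channels = {n: atlas_channels[n] for n in a.entries if n in atlas_channels}
        evaluated = 0
        for i in sorted(test_set):
            s = samples[i]
            truth = s.names_by_cell()
            if len(truth) < min_annotated:
                continue
            res = vote(
                s,
                atlases,
                weights=weights,
                n_rounds=n_rounds,
                seed=int(rng.integers(2**31 - 1)),
            )
            row = {"fold": f, "animal_id": s.animal_id, "n_annotated": len(truth)}
            for r in ranks:
                row[f"rank{r}_error"] = error_rate(res, truth, rank=r)
            rows.append(row)
            evaluated += 1
        if evaluated == 0:
            rows.append(
                {"fold": f, "animal_id": None, "n_annotated": 0}
                | {f"rank{r}_error": np.nan for r in ranks}
            )
    return pd.DataFrame(rows)


def sequential_correction(
    sample: WormSample,
    truth: dict[str, str],
    atlases: list[SyntheticAtlas],
    weights: dict[str, float] | None = None,
    n_rounds: int = 50,
    seed: int | None = None,
) -> pd.DataFrame:
    """Human-in-the-loop correction curve.

    Repeatedly: annotate by voting, pick one randomly chosen cell whose
    rank-1 estimate is wrong, fix it to its true name (hard constraint) and
    re-vote.  Records the rank-1 error and correct-label count after each
    round; terminates at zero error (or when no wrong annotated cell
    remains).
    """
    if not truth:
        raise ValueError("sequential_correction: truth is empty")
    rng = np.random.default_rng(seed)
    # the voting pool stays fixed across iterations so that successive
    # estimates differ only through the added constraints
    vote_seed = int(rng.integers(2**31 - 1))
    fixed: dict[str, str] = {}
    rows = []
    while True:
        res = vote(
            sample,
            atlases,
            weights=weights,
            fixed=fixed,
            n_rounds=n_rounds,
            seed=vote_seed,
        )
        top1 = res.rank1()
        annotated = [cid for cid in truth if cid in res.ranking]
        correct = [cid for cid in annotated if top1.get(cid) == truth[cid]]
        err = 1.0 - len(correct) / len(annotated) if annotated else np.nan
        rows.append(
            {
                "n_corrections": len(fixed),
                "error_rate": err,
                "n_correct": len(correct),
                "n_annotated": len(annotated),
            }
        )
        wrong = [cid for cid in annotated if top1.get(cid) != truth[cid] and cid not in fixed]
        if not wrong:
            break
        pick = wrong[int(rng.integers(len(wrong)))]
        fixed[pick] = truth[pick]
    return pd.DataFrame(rows)
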