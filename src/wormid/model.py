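"""Domain types shared by all pipeline stages.

Coordinate convention (after posture correction): x is the anterior–posterior
axis with anterior negative, y is dorsal–ventral with dorsal positive, z is
left–right.  All positions are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CellRecord",
    "WormSample",
    "ReferenceAtlas",
    "CellDistribution",
]


@dataclass
class CellRecord:
    """One detected nucleus: position, optional identity, landmark bits.

    ``channels`` holds the binarized landmark-fluorescence state of the cell,
    one bit per color channel (promoters sharing a color collapse to one bit).
    ``is_excluded`` marks non-neuronal records (e.g. hypodermal nuclei) that
    must not enter annotation or evaluation.
    """

    cell_id: str
    position: np.ndarray
    name: str | None = None
    channels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.uint8))
    is_excluded: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"cell {self.cell_id!r}: position is not finite")
        self.channels = np.asarray(self.channels, dtype=np.uint8).reshape(-1)
        if self.channels.size and not np.all(np.isin(self.channels, (0, 1))):
            raise ValueError(f"cell {self.cell_id!r}: channel values must be 0 or 1")
        if self.name is not None and self.name == "":
            raise ValueError(f"cell {self.cell_id!r}: name must be nonempty when present")


@dataclass
class WormSample:
    """One animal's point cloud of detected nuclei.

    ``posture_state`` is ``"raw"`` for microscope-frame coordinates and
    ``"corrected"`` after posture correction.  ``promoter_id`` records which
    cell-specific promoter labelled this animal, if known.
    """

    animal_id: str
    cells: list[CellRecord]
    posture_state: str = "raw"
    promoter_id: str | None = None

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError(f"animal {self.animal_id!r}: needs at least one cell")
        if self.posture_state not in ("raw", "corrected"):
            raise ValueError(f"invalid posture_state {self.posture_state!r}")
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"animal {self.animal_id!r}: duplicate cell ids {dup}")
        lengths = {c.channels.size for c in self.cells}
        if len(lengths) > 1:
            raise ValueError(
                f"animal {self.animal_id!r}: cells disagree on channel-vector length"
            )

    # -- convenience views -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_channels(self) -> int:
        return self.cells[0].channels.size

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) float array of positions in cell order."""
        return np.array([c.position for c in self.cells], dtype=float)

    @property
    def channel_matrix(self) -> np.ndarray:
        """(n, n_channels) uint8 matrix of landmark bits in cell order."""
        return np.array([c.channels for c in self.cells], dtype=np.uint8).reshape(
            self.n_cells, -1
        )

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    def named_cells(self, include_excluded: bool = False) -> dict[str, np.ndarray]:
        """Map of identity name -> position for annotated cells."""
        out: dict[str, np.ndarray] = {}
        for c in self.cells:
            if c.name is None or (c.is_excluded and not include_excluded):
                continue
            out[c.name] = c.position
        return out

    def names_by_cell(self) -> dict[str, str]:
        return {c.cell_id: c.name for c in self.cells if c.name is not None}

    def with_positions(
        self, positions: np.ndarray, posture_state: str | None = None
    ) -> "WormSample":
        """Copy of this sample with cell positions replaced (same order)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_cells, 3):
            raise ValueError("positions shape must be (n_cells, 3)")
        cells = [replace(c, position=positions[i]) for i, c in enumerate(self.cells)]
        return WormSample(
            animal_id=self.animal_id,
            cells=cells,
            posture_state=posture_state or self.posture_state,
            promoter_id=self.promoter_id,
        )


@dataclass
class ReferenceAtlas:
    """A fully annotated reference position table (e.g. an EM-atlas stand-in).

    Used only to fill in names never observed in the dataset during atlas
    assembly (final fill-in step).
    """

    entries: dict[str, np.ndarray]
    source: str = ""

    def __post_init__(self) -> None:
        self.entries = {
            str(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.entries.items()
        }

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CellDistribution:
    """Trivariate Gaussian model of one cell's position across animals.

    ``covariance`` is the sample covariance (denominator n−1) and is ``None``
    when the cell was observed only once.  With ``count`` ≤ 3 the covariance
    estimate is flagged unreliable.
    """

    name: str
    mean: np.ndarray
    covariance: np.ndarray | None
    count: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(3)
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.covariance is not None:
            self.covariance = np.asarray(self.covariance, dtype=float).reshape(3, 3)
            if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
                raise ValueError(f"{self.name}: covariance must be symmetric")
            if self.count < 2:
                raise ValueError("covariance defined only when count >= 2")

    @property
    def covariance_unreliable(self) -> bool:
        return self.count <= 3
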