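"""Tabular readers and writers for worm point clouds and reference atlases.

Worm tables are delimited text (CSV or TSV) with one row per detected
nucleus.  Default columns::

    animal_id, cell_id, x_um, y_um, z_um[, name][, is_excluded][, ch0, ch1, ...]

Column names can be remapped with an explicit ``schema`` so externally
deposited tables can be loaded without code changes.  Reference atlases are
CSV with columns ``name, x_um, y_um, z_um``.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CellRecord, ReferenceAtlas, WormSample

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SCHEMA",
    "read_worm_table",
    "write_worm_table",
    "read_reference_atlas",
    "write_reference_atlas",
]

#: Default column-name mapping for worm tables.
DEFAULT_SCHEMA: dict[str, str] = {
    "animal_id": "animal_id",
    "cell_id": "cell_id",
    "x": "x_um",
    "y": "y_um",
    "z": "z_um",
    "name": "name",
    "is_excluded": "is_excluded",
    "channel_prefix": "ch",
}

_CHANNEL_RE = re.compile(r"^(?P<prefix>.+?)(?P<idx>\d+)$")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype={0: str})


def _channel_columns(columns: list[str], prefix: str) -> list[str]:
    chans = []
    for col in columns:
        m = _CHANNEL_RE.match(col)
        if m and m.group("prefix") == prefix:
            chans.append((int(m.group("idx")), col))
    return [c for _, c in sorted(chans)]


def read_worm_table(
    path: str | Path,
    schema: dict[str, str] | None = None,
    posture_state: str = "raw",
) -> list[WormSample]:
    """Load a worm table, one :class:`WormSample` per distinct animal id.

    Rows are kept in file order within each animal.  Missing names yield
    unnamed cells; absent channel columns yield zero-length channel vectors.
    Malformed rows and duplicate (animal, cell) ids raise ``ValueError``
    naming the offending row.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    df = _read_table(path)
    required = [sch["animal_id"], sch["cell_id"], sch["x"], sch["y"], sch["z"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    chan_cols = _channel_columns(list(df.columns), sch["channel_prefix"])
    name_col = sch["name"] if sch["name"] in df.columns else None
    excl_col = sch["is_excluded"] if sch["is_excluded"] in df.columns else None

    samples: list[WormSample] = []
    for animal_id, grp in df.groupby(sch["animal_id"], sort=False):
        cells: list[CellRecord] = []
        seen: set[str] = set()
        for row_idx, row in grp.iterrows():
            cell_id = str(row[sch["cell_id"]])
            if cell_id in seen:
                raise ValueError(
                    f"{path}: row {row_idx + 2}: duplicate cell id {cell_id!r} "
                    f"for animal {animal_id!r}"
                )
            seen.add(cell_id)
            try:
                pos = np.array(
                    [float(row[sch["x"]]), float(row[sch["y"]]), float(row[sch["z"]])]
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: row {row_idx + 2}: malformed position ({exc})"
                ) from exc
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"{path}: row {row_idx + 2}: non-finite position")
            name = None
            if name_col is not None:
                val = row[name_col]
                if not (isinstance(val, float) and np.isnan(val)):
                    name = str(val)
            excluded = False
            if excl_col is not None:
                excluded = bool(int(row[excl_col]))
            channels = (
                np.array([int(row[c]) for c in chan_cols], dtype=np.uint8)
                if chan_cols
                else np.zeros(0, dtype=np.uint8)
            )
            cells.append(
                CellRecord(
                    cell_id=cell_id,
                    position=pos,
                    name=name,
                    channels=channels,
                    is_excluded=excluded,
                )
            )
        samples.append(
            WormSample(animal_id=str(animal_id), cells=cells, posture_state=posture_state)
        )
    return samples


def write_worm_table(
    samples: list[WormSample], path: str | Path, schema: dict[str, str] | None = None
) -> None:
    """Write samples to a delimited table; inverse of :func:`read_worm_table`.

    Positions round-trip to at least six significant digits; names, channel
    bits and exclusion flags round-trip exactly.
    """
    if not samples:
        raise ValueError("write_worm_table: sample list is empty")
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    n_ch = samples[0].n_channels
    any_names = any(c.name is not None for s in samples for c in s.cells)
    any_excl = any(c.is_excluded for s in samples for c in s.cells)
    rows = []
    for s in samples:
        for c in s.cells:
            row = {
                sch["animal_id"]: s.animal_id,
                sch["cell_id"]: c.cell_id,
                sch["x"]: c.position[0],
                sch["y"]: c.position[1],
                sch["z"]: c.position[2],
            }
            if any_names:
                row[sch["name"]] = c.name if c.name is not None else ""
            if any_excl:
                row[sch["is_excluded"]] = int(c.is_excluded)
            for k in range(n_ch):
                row[f"{sch['channel_prefix']}{k}"] = int(c.channels[k])
            rows.append(row)
    df = pd.DataFrame(rows)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_reference_atlas(path: str | Path) -> ReferenceAtlas:
    """Load a ``name, x_um, y_um, z_um`` CSV as a :class:`ReferenceAtlas`."""
    path = Path(path)
    try:
        df = _read_table(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty reference atlas", path)
        return ReferenceAtlas(entries={}, source=str(path))
    if df.empty:
        logger.warning("%s: empty reference atlas", path)
        return ReferenceAtlas(entries={}, source=str(path))
    entries: dict[str, np.ndarray] = {}
    for row_idx, row in df.iterrows():
        name = str(row["name"])
        if name in entries:
            raise ValueError(f"{path}: row {row_idx + 2}: duplicate name {name!r}")
        entries[name] = np.array([row["x_um"], row["y_um"], row["z_um"]], dtype=float)
    return ReferenceAtlas(entries=entries, source=str(path))


def write_reference_atlas(atlas: ReferenceAtlas, path: str | Path) -> None:
    rows = [
        {"name": n, "x_um": p[0], "y_um": p[1], "z_um": p[2]}
        for n, p in atlas.entries.items()
    ]
    pd.DataFrame(rows, columns=["name", "x_um", "y_um", "z_um"]).to_csv(
        path, index=False, float_format="%.10g"
    )
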