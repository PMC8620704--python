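"""Reading and writing delimited object tables.

The upstream segmentation tool exports one row per detected object with
3D position, volume in voxels and mean intensity.  Rows whose channel
label equals the configured nucleus label define the cell's reference
point (the nucleus center of mass, computed with the same virtual-mass
formula as receptor distributions).  CSV and TSV dialects are detected
from the file extension.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import center_of_mass
from .model import CellRecord, DomainError, IngestConfig, ReceptorObject

log = logging.getLogger(__name__)


class IngestError(ValueError):
    """Raised when an input table cannot be ingested as configured."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_object_table(
    path: str | Path, config: IngestConfig | None = None
) -> list[CellRecord]:
    """Read an object table into one :class:`CellRecord` per (cell, channel).

    Nucleus-channel rows become the cell's reference point.  Cells
    without a nucleus object are rejected and cells whose receptor
    channel has zero objects are skipped; both are logged, so row counts
    in equal rows assigned plus rows logged.
    """
    config = config or IngestConfig()
    path = Path(path)
    if not path.exists():
        raise IngestError(f"no such table: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    missing = [c for c in config.required_columns() if c not in df.columns]
    if missing:
        raise IngestError(
            f"table {path} is missing mapped column(s): {', '.join(missing)}"
        )

    meta_cols = {}
    for attr in ("shape", "treatment"):
        col = getattr(config, attr)
        if col is not None and col in df.columns:
            meta_cols[attr] = col

    records: list[CellRecord] = []
    for cell_id, cell_df in df.groupby(config.cell_id, sort=False):
        nuc = cell_df[cell_df[config.channel] == config.nucleus_label]
        rec_df = cell_df[cell_df[config.channel] != config.nucleus_label]
        if nuc.empty:
            log.warning(
                "cell %r rejected: no nucleus object (%d rows dropped)",
                cell_id, len(cell_df),
            )
            continue
        ref = center_of_mass(_rows_to_objects(nuc, config))
        meta = {
            attr: (str(cell_df[col].iloc[0]) if pd.notna(cell_df[col].iloc[0]) else None)
            for attr, col in meta_cols.items()
        }
        for channel, ch_df in rec_df.groupby(config.channel, sort=False):
            records.append(
                CellRecord(
                    cell_id=str(cell_id),
                    objects=_rows_to_objects(ch_df, config),
                    reference_point=ref,
                    voxel_size_um=config.voxel_size_um,
                    receptor=str(channel),
                    **meta,
                )
            )
        if rec_df.empty:
            log.warning("cell %r has zero receptor objects; excluded from metrics",
                        cell_id)
    return records


def _rows_to_objects(df: pd.DataFrame, config: IngestConfig) -> list[ReceptorObject]:
    objs = []
    for d in df.to_dict("records"):
        objs.append(
            ReceptorObject(
                x=float(d[config.x]),
                y=float(d[config.y]),
                z=float(d[config.z]),
                n_voxels=int(d[config.n_voxels]),
                mean_intensity=float(d[config.mean_intensity]),
            )
        )
    return objs


def write_object_table(
    cells: Sequence[CellRecord],
    path: str | Path,
    config: IngestConfig | None = None,
) -> None:
    """Write cells as a delimited object table readable by :func:`read_object_table`.

    Each cell's reference point is emitted as a single nucleus-channel row
    with unit volume and intensity, so the round trip reproduces it
    exactly.  Positions and intensities are written at full precision.
    """
    if not cells:
        raise DomainError("write_object_table needs at least one cell")
    config = config or IngestConfig()
    path = Path(path)
    rows = []

    def base(cell: CellRecord) -> dict:
        d = {config.cell_id: cell.cell_id}
        if config.shape is not None:
            d[config.shape] = cell.shape
        if config.treatment is not None:
            d[config.treatment] = cell.treatment
        return d

    for cell in cells:
        if cell.reference_point is not None:
            rows.append(
                base(cell)
                | {
                    config.channel: config.nucleus_label,
                    config.x: cell.reference_point[0],
                    config.y: cell.reference_point[1],
                    config.z: cell.reference_point[2],
                    config.n_voxels: 1,
                    config.mean_intensity: 1.0,
                }
            )
        for o in cell.objects:
            rows.append(
                base(cell)
                | {
                    config.channel: cell.receptor or "receptor",
                    config.x: o.x,
                    config.y: o.y,
                    config.z: o.z,
                    config.n_voxels: o.n_voxels,
                    config.mean_intensity: o.mean_intensity,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def config_from_mapping(raw: dict) -> IngestConfig:
    """Build an :class:`IngestConfig` from a plain key/value mapping."""
    kwargs = dict(raw.get("columns", {}))
    if "voxel_size_um" in raw:
        v = raw["voxel_size_um"]
        kwargs["voxel_size_um"] = tuple(v) if isinstance(v, (list, tuple)) else float(v)
    if "nucleus_label" in raw:
        kwargs["nucleus_label"] = raw["nucleus_label"]
    try:
        return IngestConfig(**kwargs)
    except TypeError as exc:
        raise IngestError(f"bad ingest config: {exc}") from exc


def load_config(path: str | Path) -> IngestConfig:
    """Load an :class:`IngestConfig` from a YAML key/value file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_mapping(raw)
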