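"""Center-of-mass metrics for receptor distributions.

The physical mass in the classical center-of-mass formula
``r = Σ m_i r_i / Σ m_i`` is replaced by a *virtual mass*
``v_i = (I_i / I_g) · n_i`` — the object's mean intensity normalized by
the image's global mean intensity, times its volume in voxels.  The
global normalization ``I_g`` cancels in the ratio, so the distribution
center of mass is simply the ``I_i·n_i``-weighted mean position.

Two scalar metrics summarize one cell:

reference metric
    Euclidean distance (µm) between the receptor distribution's center
    of mass and a reference point, here the nucleus center of mass.
    Sensitive to a shift of the whole distribution.
spread metric
    Mean Euclidean distance (µm) of each accumulation to the
    distribution's center of mass.  Sensitive to dispersion.

Voxel coordinates are converted to µm per axis *before* distances are
taken, which keeps both metrics correct for anisotropic stacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .model import CellRecord, DomainError, ReceptorObject, StudyGroup

MetricName = Literal["reference", "spread"]


@dataclass(frozen=True)
class MetricResult:
    cell_id: str
    metric: MetricName
    value_um: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.value_um) and self.value_um >= 0):
            raise DomainError(f"metric value must be finite and >= 0: {self.value_um}")


def virtual_mass(obj: ReceptorObject, global_mean_intensity: float) -> float:
    """Virtual mass ``(I_i / I_g) · n_i`` of one accumulation."""
    if not (np.isfinite(global_mean_intensity) and global_mean_intensity > 0):
        raise DomainError(
            f"global mean intensity must be > 0, got {global_mean_intensity}"
        )
    return (obj.mean_intensity / global_mean_intensity) * obj.n_voxels


def center_of_mass(objects: Iterable[ReceptorObject]) -> np.ndarray:
    """Intensity·volume-weighted mean position, in voxel coordinates.

    Independent of any global intensity normalization (it cancels).
    """
    objects = list(objects)
    if not objects:
        raise DomainError("center of mass of an empty object list")
    pos = np.array([[o.x, o.y, o.z] for o in objects], dtype=float)
    w = np.array([o.mean_intensity * o.n_voxels for o in objects], dtype=float)
    total = w.sum()
    if not total > 0:
        raise DomainError("all virtual masses are zero")
    return (w[:, None] * pos).sum(axis=0) / total


def reference_metric(cell: CellRecord) -> MetricResult:
    """Distance (µm) from the distribution COM to the cell's reference point."""
    if cell.reference_point is None:
        raise DomainError(f"cell {cell.cell_id!r} has no reference point")
    com = center_of_mass(cell.objects)
    d_um = (com - cell.reference_point) * np.asarray(cell.voxel_size_um)
    return MetricResult(cell.cell_id, "reference", float(np.linalg.norm(d_um)))


def spread_metric(cell: CellRecord, weighted: bool = False) -> MetricResult:
    """Mean distance (µm) of each accumulation to the distribution COM.

    By default each accumulation counts once; ``weighted=True`` averages
    with the virtual masses instead.
    """
    com = center_of_mass(cell.objects)
    d_um = (cell.positions() - com) * np.asarray(cell.voxel_size_um)
    dist = np.linalg.norm(d_um, axis=1)
    if weighted:
        w = cell.weights()
        value = float(np.average(dist, weights=w))
    else:
        value = float(dist.mean())
    return MetricResult(cell.cell_id, "spread", value)


def metrics_table(group: StudyGroup, weighted_spread: bool = False) -> pd.DataFrame:
    """Tidy per-cell metric table for one study group.

    Columns: group, cell_id, shape, treatment, receptor, metric, value_um.
    Cells without objects or reference point raise; filter upstream.
    """
    rows = []
    for cell in group:
        for res in (reference_metric(cell), spread_metric(cell, weighted_spread)):
            rows.append(
                {
                    "group": group.name,
                    "cell_id": cell.cell_id,
                    "shape": cell.shape,
                    "treatment": cell.treatment,
                    "receptor": cell.receptor,
                    "metric": res.metric,
                    "value_um": res.value_um,
                }
            )
    return pd.DataFrame(rows)


def metric_values(group: StudyGroup, metric: MetricName,
                  weighted_spread: bool = False) -> np.ndarray:
    """Per-cell values of one metric across a group, as an array."""
    if metric == "reference":
        return np.array([reference_metric(c).value_um for c in group])
    if metric == "spread":
        return np.array([spread_metric(c, weighted_spread).value_um for c in group])
    raise DomainError(f"unknown metric {metric!r}")
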