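"""Core data model: receptor accumulations, cells, study groups.

A segmented receptor *accumulation* (one immunofluorescence punctum) is
reduced to a point object carrying its 3D centroid in continuous voxel
coordinates, its volume in voxels and its mean voxel intensity.  A cell
bundles all accumulations of one receptor channel together with the
center of mass of its nucleus, which serves as the frame of reference for
the shift (reference) metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

#: Default physical voxel volume in µm³ (confocal stack, 63x oil objective).
DEFAULT_VOXEL_VOLUME_UM3 = 0.0037

#: Isotropic per-axis voxel edge length derived from the default volume.
DEFAULT_VOXEL_SIZE_UM = DEFAULT_VOXEL_VOLUME_UM3 ** (1.0 / 3.0)


class DomainError(ValueError):
    """Raised when an operation's scientific preconditions are violated."""


@dataclass(frozen=True)
class ReceptorObject:
    """One detected receptor accumulation.

    Parameters
    ----------
    x, y, z
        Object centroid in continuous voxel coordinates (origin at the
        corner of voxel ``(0, 0, 0)``), as exported by the upstream
        segmentation tool.
    n_voxels
        Object volume in voxels (>= 1).
    mean_intensity
        Mean voxel intensity of the object (>= 0).
    """

    x: float
    y: float
    z: float
    n_voxels: int
    mean_intensity: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in (self.x, self.y, self.z)):
            raise DomainError("object position must be finite")
        if self.n_voxels < 1:
            raise DomainError(f"n_voxels must be >= 1, got {self.n_voxels}")
        if not (math.isfinite(self.mean_intensity) and self.mean_intensity >= 0):
            raise DomainError(
                f"mean_intensity must be finite and >= 0, got {self.mean_intensity}"
            )

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def _as_voxel_size(voxel_size: float | Sequence[float] | None) -> tuple[float, float, float]:
    if voxel_size is None:
        s = DEFAULT_VOXEL_SIZE_UM
        return (s, s, s)
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3  # type: ignore[assignment]
    vs = tuple(float(v) for v in voxel_size)  # type: ignore[union-attr]
    if len(vs) != 3:
        raise DomainError("voxel_size needs one value per axis (x, y, z)")
    if any(not (math.isfinite(v) and v > 0) for v in vs):
        raise DomainError(f"voxel_size must be strictly positive, got {vs}")
    return vs  # type: ignore[return-value]


@dataclass
class CellRecord:
    """All accumulations of one receptor channel in one cell.

    ``reference_point`` is the intensity-weighted center of mass of the
    nucleus, in the same voxel coordinate frame as the objects.
    ``voxel_size_um`` holds the physical edge length of one voxel per axis
    in µm; the default is the isotropic cube root of 0.0037 µm³.
    """

    cell_id: str
    objects: list[ReceptorObject]
    reference_point: np.ndarray | None = None
    voxel_size_um: tuple[float, float, float] = (
        DEFAULT_VOXEL_SIZE_UM,
    ) * 3
    shape: str | None = None
    treatment: str | None = None
    receptor: str | None = None

    def __post_init__(self) -> None:
        self.voxel_size_um = _as_voxel_size(self.voxel_size_um)
        if self.reference_point is not None:
            ref = np.asarray(self.reference_point, dtype=float)
            if ref.shape != (3,) or not np.all(np.isfinite(ref)):
                raise DomainError("reference_point must be a finite 3-vector")
            self.reference_point = ref

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def positions(self) -> np.ndarray:
        """(n, 3) array of object centroids in voxel coordinates."""
        if not self.objects:
            return np.empty((0, 3), dtype=float)
        return np.array([[o.x, o.y, o.z] for o in self.objects], dtype=float)

    def weights(self) -> np.ndarray:
        """Virtual masses up to the global normalization: I_i * n_i."""
        return np.array(
            [o.mean_intensity * o.n_voxels for o in self.objects], dtype=float
        )

    def volumes(self) -> np.ndarray:
        return np.array([o.n_voxels for o in self.objects], dtype=float)

    def intensities(self) -> np.ndarray:
        return np.array([o.mean_intensity for o in self.objects], dtype=float)

    def translated(self, t: Sequence[float]) -> "CellRecord":
        """Return a copy with objects and reference shifted by ``t`` (voxels)."""
        t = np.asarray(t, dtype=float)
        objs = [
            replace(o, x=o.x + t[0], y=o.y + t[1], z=o.z + t[2]) for o in self.objects
        ]
        ref = None if self.reference_point is None else self.reference_point + t
        return CellRecord(
            cell_id=self.cell_id,
            objects=objs,
            reference_point=ref,
            voxel_size_um=self.voxel_size_um,
            shape=self.shape,
            treatment=self.treatment,
            receptor=self.receptor,
        )


@dataclass
class StudyGroup:
    """Named collection of cells to be analyzed and compared as one group."""

    name: str
    cells: list[CellRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterator[CellRecord]:
        return iter(self.cells)

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        if not self.cells:
            raise DomainError(f"group {self.name!r} is empty")
        sizes = {c.voxel_size_um for c in self.cells}
        if len(sizes) > 1:
            raise DomainError(
                f"group {self.name!r} mixes voxel sizes: {sorted(sizes)}"
            )
        return self.cells[0].voxel_size_um


@dataclass
class IngestConfig:
    """Column mapping and physical calibration for delimited object tables.

    The upstream segmentation export dialect varies; this mapping absorbs
    it.  ``nucleus_label`` marks rows belonging to the nucleus channel,
    whose objects define the cell's reference point.
    """

    cell_id: str = "cell_id"
    channel: str = "channel"
    x: str = "x_vox"
    y: str = "y_vox"
    z: str = "z_vox"
    n_voxels: str = "n_voxels"
    mean_intensity: str = "mean_intensity"
    nucleus_label: str = "nucleus"
    shape: str | None = "shape"
    treatment: str | None = "treatment"
    voxel_size_um: tuple[float, float, float] = (DEFAULT_VOXEL_SIZE_UM,) * 3

    def __post_init__(self) -> None:
        self.voxel_size_um = _as_voxel_size(self.voxel_size_um)

    def required_columns(self) -> list[str]:
        return [self.cell_id, self.channel, self.x, self.y, self.z,
                self.n_voxels, self.mean_intensity]
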