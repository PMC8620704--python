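"""Synthetic test data: micropattern-shaped cells and two-channel images.

The cell generator emulates the object tables an upstream segmentation
tool would export for single cells on 50 µm adhesive micropatterns
(circle or crossbow): a cloud of receptor accumulations, clustered as an
axis-aligned Gaussian around a configurable offset from the nucleus,
with lognormal volumes and gamma-distributed mean intensities, placed in
a confocal-like voxel frame.  The planted offset is the expected
reference metric; for an isotropic cluster with scale sigma the expected
spread metric is the 3D half-normal radial mean ``2·sigma·sqrt(2/pi)``
(when the planted offset noise is negligible).

The image generator produces paired spot images with a tunable
co-occurring fraction rho: rho of the channel-B spots are placed at
channel-A spot centers, the remainder uniformly at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coloc import ChannelPair
from .metrics import center_of_mass
from .model import (
    DEFAULT_VOXEL_SIZE_UM,
    CellRecord,
    DomainError,
    ReceptorObject,
    StudyGroup,
)


@dataclass
class CellGeneratorSpec:
    """Parameters of the synthetic single-cell generator.

    Geometry is specified in µm and converted to voxel coordinates with
    ``voxel_size_um``.  Defaults emulate a 50 µm micropattern imaged in
    a 512x512x40 stack at 0.0037 µm³/voxel: ~150 accumulations per cell
    spread with sigma ~8 µm in-plane, the receptor cloud offset 12 µm
    from the nucleus along +x, and the nucleus jittering by ~0.5 µm
    around the pattern center.
    """

    shape: str = "circle"                       # circle | crossbow footprint
    pattern_diameter_um: float = 50.0
    frame_vox: tuple[int, int, int] = (512, 512, 40)
    voxel_size_um: tuple[float, float, float] = (DEFAULT_VOXEL_SIZE_UM,) * 3
    z_center_um: float = 2.0
    n_objects_mean: float = 150.0               # Poisson mean per cell
    cluster_sigma_um: tuple[float, float, float] = (8.0, 8.0, 0.8)  # planted spread
    com_offset_um: tuple[float, float, float] = (12.0, 0.0, 0.0)    # planted shift
    nucleus_jitter_um: tuple[float, float, float] = (0.5, 0.5, 0.15)
    nucleus_sigma_um: tuple[float, float, float] = (2.5, 2.5, 0.8)
    n_nucleus_objects: int = 20
    volume_median_vox: float = 30.0
    volume_sigma_log: float = 0.6
    intensity_shape: float = 3.0
    intensity_scale: float = 40.0
    clip_to_footprint: bool = True
    treatment: str = "control"
    receptor: str = "BMPRIb"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "crossbow"):
            raise DomainError(f"unknown footprint shape {self.shape!r}")
        for name in ("pattern_diameter_um", "n_objects_mean", "volume_median_vox",
                     "volume_sigma_log", "intensity_shape", "intensity_scale"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")
        if any(s <= 0 for s in self.cluster_sigma_um):
            raise DomainError("cluster_sigma_um must be strictly positive")
        if not all(math.isfinite(v) for v in self.com_offset_um):
            raise DomainError("com_offset_um must be finite")

    @property
    def pattern_center_um(self) -> np.ndarray:
        fx, fy, _ = self.frame_vox
        vx, vy, _ = self.voxel_size_um
        return np.array([fx * vx / 2.0, fy * vy / 2.0, self.z_center_um])


def _in_footprint(spec: CellGeneratorSpec, xy_um: np.ndarray) -> np.ndarray:
    """Boolean mask of points inside the micropattern footprint (xy, µm,
    relative to the pattern center)."""
    r = spec.pattern_diameter_um / 2.0
    x, y = xy_um[:, 0], xy_um[:, 1]
    if spec.shape == "circle":
        return x**2 + y**2 <= r**2
    # crossbow contract: upper half-disc (y >= 0) plus a stem rectangle
    # of width 0.4*r reaching down to the circle's lowest point.
    in_half_disc = (y >= 0) & (x**2 + y**2 <= r**2)
    in_stem = (np.abs(x) <= 0.2 * r) & (y >= -r) & (y < 0)
    return in_half_disc | in_stem


def _sample_positions(
    spec: CellGeneratorSpec,
    center_um: np.ndarray,
    sigma_um: np.ndarray,
    count: int,
    rng: np.random.Generator,
    clip: bool,
) -> np.ndarray:
    """Gaussian cluster in µm, rejection-sampled into footprint and frame."""
    frame_hi = np.array(spec.frame_vox) * np.array(spec.voxel_size_um)
    out = np.empty((0, 3))
    guard = 0
    while out.shape[0] < count:
        m = max(count - out.shape[0], 16)
        pts = rng.normal(center_um, sigma_um, size=(2 * m, 3))
        ok = np.all((pts >= 0) & (pts < frame_hi), axis=1)
        if clip:
            ok &= _in_footprint(spec, pts[:, :2] - spec.pattern_center_um[:2])
        out = np.vstack([out, pts[ok]])
        guard += 1
        if guard > 200:
            raise DomainError(
                "rejection sampling failed; cluster lies outside the footprint"
            )
    return out[:count]


def _make_objects(
    positions_um: np.ndarray, spec: CellGeneratorSpec, rng: np.random.Generator
) -> list[ReceptorObject]:
    count = positions_um.shape[0]
    vox = positions_um / np.array(spec.voxel_size_um)
    volumes = np.maximum(
        1,
        np.rint(
            rng.lognormal(math.log(spec.volume_median_vox), spec.volume_sigma_log, count)
        ),
    ).astype(int)
    intensities = rng.gamma(spec.intensity_shape, spec.intensity_scale, count)
    return [
        ReceptorObject(
            x=float(vox[i, 0]),
            y=float(vox[i, 1]),
            z=float(vox[i, 2]),
            n_voxels=int(volumes[i]),
            mean_intensity=float(intensities[i]),
        )
        for i in range(count)
    ]


def generate_cells(
    spec: CellGeneratorSpec, n_cells: int, name: str | None = None
) -> StudyGroup:
    """Generate a study group of synthetic cells; deterministic per spec.seed."""
    if n_cells < 1:
        raise DomainError("n_cells must be >= 1")
    ss = np.random.SeedSequence(spec.seed)
    cells = []
    for i, child in enumerate(ss.spawn(n_cells)):
        rng = np.random.default_rng(child)
        nucleus_center = spec.pattern_center_um + rng.normal(
            0.0, spec.nucleus_jitter_um
        )
        nuc_pos = _sample_positions(
            spec, nucleus_center, np.array(spec.nucleus_sigma_um),
            spec.n_nucleus_objects, rng, clip=False,
        )
        nuc_objs = _make_objects(nuc_pos, spec, rng)
        ref = center_of_mass(nuc_objs)

        count = max(1, int(rng.poisson(spec.n_objects_mean)))
        cluster_center = nucleus_center + np.array(spec.com_offset_um)
        pos = _sample_positions(
            spec, cluster_center, np.array(spec.cluster_sigma_um),
            count, rng, clip=spec.clip_to_footprint,
        )
        cells.append(
            CellRecord(
                cell_id=f"cell-{i:04d}",
                objects=_make_objects(pos, spec, rng),
                reference_point=ref,
                voxel_size_um=spec.voxel_size_um,
                shape=spec.shape,
                treatment=spec.treatment,
                receptor=spec.receptor,
            )
        )
    return StudyGroup(name or f"synthetic-{spec.shape}", cells)


def expected_spread_metric(sigma_um: float) -> float:
    """Expected spread metric of an isotropic 3D Gaussian cluster."""
    return 2.0 * sigma_um * math.sqrt(2.0 / math.pi)


@dataclass
class ImageGeneratorSpec:
    """Parameters of the paired two-channel spot image generator."""

    image_shape: tuple[int, ...] = (128, 128)
    n_spots_a: int = 40
    n_spots_b: int = 40
    spot_sigma_px: float = 2.0
    spot_amplitude: float = 200.0
    co_occurring_fraction: float = 0.5         # rho
    noise_level: float = 2.0                   # additive Gaussian sd
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.co_occurring_fraction <= 1.0):
            raise DomainError("co_occurring_fraction must be within [0, 1]")
        if any(d <= 0 for d in self.image_shape):
            raise DomainError("image dimensions must be positive")
        if self.n_spots_a < 1 or self.n_spots_b < 1:
            raise DomainError("need at least one spot per channel")
        if self.noise_level < 0 or self.spot_sigma_px <= 0:
            raise DomainError("invalid spot/noise parameters")


def _render_spots(
    shape: tuple[int, ...], centers: np.ndarray, sigma: float, amplitude: float
) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(d, dtype=float) for d in shape], indexing="ij")
    img = np.zeros(shape, dtype=float)
    for c in centers:
        sq = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        img += amplitude * np.exp(-sq / (2.0 * sigma**2))
    return img


def generate_image_pair(spec: ImageGeneratorSpec) -> ChannelPair:
    """Generate a two-channel spot image pair with co-occurring fraction rho.

    ``rho = 1`` with equal spot counts and no noise yields identical
    channels; ``rho = 0`` places every channel-B spot independently.
    Deterministic per spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    dims = np.array(shape, dtype=float)
    centers_a = rng.uniform(0, dims, size=(spec.n_spots_a, len(shape)))
    n_shared = int(round(spec.co_occurring_fraction * spec.n_spots_b))
    n_shared = min(n_shared, spec.n_spots_a)
    shared_idx = rng.choice(spec.n_spots_a, size=n_shared, replace=False)
    centers_b = np.vstack(
        [
            centers_a[shared_idx],
            rng.uniform(0, dims, size=(spec.n_spots_b - n_shared, len(shape))),
        ]
    )
    img_a = _render_spots(shape, centers_a, spec.spot_sigma_px, spec.spot_amplitude)
    img_b = _render_spots(shape, centers_b, spec.spot_sigma_px, spec.spot_amplitude)
    if spec.noise_level > 0:
        img_a = np.maximum(0.0, img_a + rng.normal(0, spec.noise_level, shape))
        img_b = np.maximum(0.0, img_b + rng.normal(0, spec.noise_level, shape))
    return ChannelPair(img_a, img_b)
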