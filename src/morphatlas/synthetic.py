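"""Synthetic phantom atlas database.

Real brachial-plexus (BP) atlas databases are built from anatomically
validated cadaver delineations and a clinical deformable-registration
engine; neither is publicly distributable.  This module generates a phantom
database with the same *statistical structure*:

* each atlas carries a gold-standard BP-like mask — a curved, branched tube
  running from the lower cervical spine toward the axilla;
* two landmarks (anterior tubercle of C5, infraglenoid tubercle) whose
  anterior–posterior offset equals a per-atlas protraction distance;
* a simulated registration that deforms labels with a smooth random
  displacement field whose RMS magnitude grows linearly with the
  atlas–patient protraction difference:  rms = a + b * |Δprotraction|.

The error model is the substantive assumption: morphometrically closer
atlases register better.  It is deliberately simple and pluggable so a real
registration engine can be substituted.

Axis convention: axis 0 right–left, axis 1 anterior–posterior, axis 2
superior–inferior; protraction lives on axis 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morphometry import AtlasRecord, LandmarkSet
from .volume import DEFAULT_FRAME, GeometryError, LabelVolume

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Phantom-database generation settings.

    Defaults emulate a 12-atlas database on a 48^3 grid of 2 mm isotropic
    voxels (96 mm field of view per axis), protraction distances uniform on
    [20, 70] mm, and a registration whose label-transfer error has RMS
    ``error_base_mm + error_slope * |Δprotraction|`` millimetres.
    """

    n_atlases: int = 12
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    protraction_range_mm: tuple[float, float] = (20.0, 70.0)
    error_base_mm: float = 4.0
    error_slope: float = 0.4
    warp_smoothness_mm: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atlases < 3:
            raise ValueError(f"n_atlases must be >= 3, got {self.n_atlases}")
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError(f"invalid grid_shape {self.grid_shape}")
        if isinstance(self.spacing_mm, (int, float)):
            self.spacing_mm = (float(self.spacing_mm),) * 3
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        lo, hi = self.protraction_range_mm
        if not lo < hi:
            raise ValueError(
                f"protraction range lower bound must be < upper, got {lo}, {hi}"
            )
        if self.warp_smoothness_mm <= 0:
            raise ValueError("warp_smoothness_mm must be > 0")
        if self.error_base_mm < 0 or self.error_slope < 0:
            raise ValueError("error model coefficients must be >= 0")


@dataclass
class PhantomAtlas:
    """A generated atlas plus the protraction parameter used to build it."""

    atlas: AtlasRecord
    true_protraction_mm: float


def _extent_mm(config: SyntheticConfig) -> np.ndarray:
    return np.asarray(config.grid_shape) * np.asarray(config.spacing_mm)


def generate_phantom(
    protraction_mm: float, config: SyntheticConfig, seed: int, atlas_id: str = "phantom"
) -> PhantomAtlas:
    """Generate one phantom atlas with the requested protraction distance.

    The mask is a curved tube from a fixed "C5" landmark towards an
    "infraglenoid" landmark placed exactly ``protraction_mm`` further along
    the anterior–posterior axis, with 2 short branches mimicking the
    plexus trunks.  Same (protraction, config, seed) -> bitwise-identical
    output.
    """
    lo, hi = config.protraction_range_mm
    if not lo <= protraction_mm <= hi:
        raise ValueError(
            f"protraction {protraction_mm} mm outside configured range [{lo}, {hi}]"
        )
    extent = _extent_mm(config)
    spacing = np.asarray(config.spacing_mm)
    rng = np.random.default_rng(seed)

    # Landmarks: C5 near the posterior-superior-medial corner of the grid,
    # the infraglenoid tubercle anterior (axis 1) by exactly protraction_mm
    # and inferior-lateral of it.
    c5 = np.array([0.32 * extent[0], 0.12 * extent[1], 0.82 * extent[2]])
    infra = np.array(
        [0.68 * extent[0], c5[1] + protraction_mm, 0.26 * extent[2]]
    )
    margin = 2.0 * spacing  # room for the tube radius
    for name, pt in (("c5_anterior_tubercle", c5), ("infraglenoid_tubercle", infra)):
        for ax in range(3):
            if not margin[ax] <= pt[ax] <= extent[ax] - margin[ax]:
                raise GeometryError(
                    f"landmark {name} at {pt[ax]:.1f} mm exceeds grid extent "
                    f"{extent[ax]:.1f} mm on axis {ax}"
                )

    # Quadratic Bezier trunk from C5 to the infraglenoid landmark, with a
    # seeded perturbation of the control point for per-atlas shape variation.
    ctrl = 0.5 * (c5 + infra)
    ctrl += rng.uniform(-6.0, 6.0, size=3)
    ctrl = np.clip(ctrl, margin, extent - margin)
    t = np.linspace(0.0, 1.0, 160)[:, None]
    trunk = (1 - t) ** 2 * c5 + 2 * t * (1 - t) * ctrl + t**2 * infra

    radius = 4.5 + rng.uniform(-0.5, 0.5)  # mm; plexus trunk calibre
    points = [trunk]
    radii = [np.full(len(trunk), radius)]
    # Two short branches leaving the trunk at seeded positions.
    for _ in range(2):
        s = rng.uniform(0.25, 0.7)
        base = (1 - s) ** 2 * c5 + 2 * s * (1 - s) * ctrl + s**2 * infra
        direction = rng.normal(size=3)
        direction[2] = -abs(direction[2])  # branches run inferiorly
        direction /= np.linalg.norm(direction)
        length = rng.uniform(10.0, 18.0)
        tb = np.linspace(0.0, 1.0, 40)[:, None]
        branch = base + tb * length * direction
        branch = np.clip(branch, margin, extent - margin)
        points.append(branch)
        radii.append(np.full(len(branch), 0.7 * radius))

    centres = np.concatenate(points)
    rads = np.concatenate(radii)

    # Rasterise: voxel centre within the local radius of any path point.
    shape = tuple(config.grid_shape)
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    mask = np.zeros(shape, dtype=bool)
    # distance check restricted to a per-point neighbourhood for speed
    for c, r in zip(centres, rads):
        lo_idx = np.maximum(((c - r) / spacing).astype(int), 0)
        hi_idx = np.minimum(((c + r) / spacing).astype(int) + 2, shape)
        sl = tuple(slice(l, h) for l, h in zip(lo_idx, hi_idx))
        gx, gy, gz = np.meshgrid(
            coords[0][sl[0]], coords[1][sl[1]], coords[2][sl[2]], indexing="ij"
        )
        d2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        mask[sl] |= d2 <= r**2

    if not mask.any():
        raise GeometryError("generated phantom mask is empty")

    volume = LabelVolume(mask.astype(np.uint8), tuple(spacing), (0.0, 0.0, 0.0))
    landmarks = LandmarkSet(tuple(c5), tuple(infra))
    record = AtlasRecord(id=atlas_id, gold_mask=volume, landmarks=landmarks)
    return PhantomAtlas(atlas=record, true_protraction_mm=float(protraction_mm))


def generate_database(config: SyntheticConfig) -> list[PhantomAtlas]:
    """Generate ``config.n_atlases`` phantoms with uniform protractions.

    Protraction distances are drawn uniformly from
    ``config.protraction_range_mm`` using ``config.seed``; per-atlas shape
    seeds are derived from the same stream, so the whole database is a pure
    function of the config.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protraction_range_mm
    protractions = rng.uniform(lo, hi, size=config.n_atlases)
    shape_seeds = rng.integers(0, 2**31 - 1, size=config.n_atlases)
    database = []
    for i, (prot, s) in enumerate(zip(protractions, shape_seeds)):
        atlas_id = f"atlas_{i:02d}"
        database.append(
            generate_phantom(float(prot), config, int(s), atlas_id=atlas_id)
        )
    logger.info(
        "generated %d phantom atlases, protraction %.1f-%.1f mm",
        len(database), protractions.min(), protractions.max(),
    )
    return database


def _as_record(atlas: PhantomAtlas | AtlasRecord) -> AtlasRecord:
    return atlas.atlas if isinstance(atlas, PhantomAtlas) else atlas


def simulate_registration(
    atlas: PhantomAtlas | AtlasRecord,
    patient: PhantomAtlas | AtlasRecord,
    config: SyntheticConfig,
    seed: int,
) -> LabelVolume:
    """Simulate propagating the atlas delineation onto the patient.

    Returns the patient's gold mask corrupted by a smooth random
    displacement field with RMS magnitude ``a + b * |Δprotraction|`` mm
    (Δprotraction = atlas minus patient protraction), applied with
    nearest-neighbour label resampling — the deformed atlas contour as it
    would land on the patient, with error increasing in morphometric
    distance.  Deterministic given the seed.
    """
    atlas_rec = _as_record(atlas)
    patient_rec = _as_record(patient)
    patient_rec.gold_mask.require_same_grid(atlas_rec.gold_mask)

    delta = abs(atlas_rec.protraction_mm - patient_rec.protraction_mm)
    target_rms = config.error_base_mm + config.error_slope * delta
    return warp_mask(
        patient_rec.gold_mask, target_rms, config.warp_smoothness_mm, seed
    )


def warp_mask(
    mask: LabelVolume, rms_mm: float, smoothness_mm: float, seed: int
) -> LabelVolume:
    """Deform a binary mask by a smooth random displacement field.

    The field is i.i.d. Gaussian per voxel and component, smoothed with a
    Gaussian kernel of scale ``smoothness_mm``, then rescaled so the voxel-
    wise displacement magnitude has the requested RMS (mm).  Labels are
    pulled back with nearest-neighbour interpolation.  ``rms_mm = 0`` is the
    identity.
    """
    if rms_mm < 0:
        raise ValueError("displacement RMS must be >= 0")
    if rms_mm == 0:
        return mask.with_voxels(mask.voxels.copy())
    rng = np.random.default_rng(seed)
    shape = mask.shape
    spacing = np.asarray(mask.spacing_mm)
    sigma_vox = smoothness_mm / spacing  # per-axis smoothing in voxel units

    disp = rng.normal(size=(3,) + shape)
    for ax in range(3):
        disp[ax] = ndimage.gaussian_filter(disp[ax], sigma=sigma_vox)
    mag2 = (disp**2).sum(axis=0)
    rms_now = np.sqrt(mag2.mean())
    disp *= rms_mm / rms_now  # field now in mm

    grid = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    # pull-back sampling coordinates, displacement converted mm -> voxels
    sample = [g + d / s for g, d, s in zip(grid, disp, spacing)]
    warped = ndimage.map_coordinates(
        mask.voxels, sample, order=0, mode="constant", cval=0
    )
    return mask.with_voxels(warped)
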