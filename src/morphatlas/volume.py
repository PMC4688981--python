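"""Core spatial containers and error types.

All label volumes in the pipeline live on a regular 3-D voxel grid with a
fixed axis convention (see :data:`DEFAULT_FRAME`): axis 0 runs right–left,
axis 1 anterior–posterior, axis 2 superior–inferior.  The protraction
distance — the morphometric selection criterion — is measured along the
anterior–posterior axis (axis 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Axis-convention tag used throughout: axis 0 = right–left,
#: axis 1 = anterior–posterior, axis 2 = superior–inferior.
DEFAULT_FRAME = "RL-AP-SI"

#: Index of the anterior–posterior axis in the default frame.
AP_AXIS = 1


class MorphAtlasError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(MorphAtlasError):
    """Two volumes were expected on identical grids but are not."""


class GeometryError(MorphAtlasError):
    """A generated structure does not fit the requested grid."""


class UndefinedMetricError(MorphAtlasError):
    """An overlap index is undefined for the given masks (e.g. both empty)."""


@dataclass
class LabelVolume:
    """A binary segmentation mask on a regular 3-D grid.

    Parameters
    ----------
    voxels
        3-D array; coerced to ``uint8`` with values in {0, 1}.
    spacing_mm
        Per-axis voxel size in millimetres, all entries > 0.
    origin_mm
        Physical coordinate of voxel (0, 0, 0), millimetres.
    frame
        Axis-convention tag; volumes only interoperate within one frame.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame: str = DEFAULT_FRAME

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise GeometryError(f"expected a 3-D volume, got {arr.ndim}-D")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("label volume must be binary (values in {0, 1})")
        self.voxels = arr.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def volume_count(self) -> int:
        """Number of foreground voxels."""
        return int(self.voxels.sum())

    def same_grid(self, other: "LabelVolume") -> bool:
        return (
            self.shape == other.shape
            and self.spacing_mm == other.spacing_mm
            and self.origin_mm == other.origin_mm
            and self.frame == other.frame
        )

    def require_same_grid(self, other: "LabelVolume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.spacing_mm}/{self.origin_mm}"
                f"/{self.frame} vs {other.shape}/{other.spacing_mm}"
                f"/{other.origin_mm}/{other.frame}"
            )

    def with_voxels(self, voxels: np.ndarray) -> "LabelVolume":
        """A copy of this volume's grid carrying new voxel data."""
        return LabelVolume(voxels, self.spacing_mm, self.origin_mm, self.frame)
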