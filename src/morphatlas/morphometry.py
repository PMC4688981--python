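"""Protraction-distance measurement and morphometric atlas ranking.

The protraction distance is the horizontal (anterior–posterior) distance, in
the sagittal plane, between a vertical line through the anterior tubercle of
C5 and a vertical line through the infraglenoid tubercle of the scapula.  It
summarises shoulder protraction in a single scalar and is the criterion used
to pick, for a given patient, the most morphometrically similar atlases from
a database.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import AP_AXIS, DEFAULT_FRAME, LabelVolume


@dataclass(frozen=True)
class LandmarkSet:
    """The two bony landmarks defining the protraction distance (mm)."""

    c5_anterior_tubercle: tuple[float, float, float]
    infraglenoid_tubercle: tuple[float, float, float]
    frame: str = DEFAULT_FRAME

    def __post_init__(self) -> None:
        for name in ("c5_anterior_tubercle", "infraglenoid_tubercle"):
            point = np.asarray(getattr(self, name), dtype=float)
            if point.shape != (3,):
                raise ValueError(f"{name} must be a 3-D point, got {point.shape}")
            if not np.isfinite(point).all():
                raise ValueError(f"{name} has non-finite coordinates: {point}")
        if not self.frame:
            raise ValueError("landmark frame tag must be present")


@dataclass
class AtlasRecord:
    """One atlas: an identifier, its gold-standard mask and its landmarks.

    ``protraction_mm`` is derived from the landmarks on construction.
    """

    id: str
    gold_mask: LabelVolume
    landmarks: LandmarkSet
    protraction_mm: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        derived = protraction_distance(self.landmarks)
        if self.protraction_mm is None:
            self.protraction_mm = derived
        elif abs(self.protraction_mm - derived) > 1e-9:
            raise ValueError(
                f"protraction_mm {self.protraction_mm} inconsistent with "
                f"landmarks (measured {derived})"
            )


def protraction_distance(landmarks: LandmarkSet) -> float:
    """Protraction distance in mm from a landmark pair.

    The absolute anterior–posterior coordinate difference between the two
    landmarks; symmetric in the two points and always >= 0.
    """
    a = np.asarray(landmarks.c5_anterior_tubercle, dtype=float)
    b = np.asarray(landmarks.infraglenoid_tubercle, dtype=float)
    return float(abs(a[AP_AXIS] - b[AP_AXIS]))


def rank_atlases(
    patient_protraction: float, atlases: list[AtlasRecord]
) -> list[AtlasRecord]:
    """Sort atlases by closeness of protraction to the patient's.

    Ascending in |atlas protraction - patient protraction|; ties broken by
    atlas id (lexicographic) so runs are reproducible.
    """
    if not atlases:
        raise ValueError("cannot rank an empty atlas list")
    return sorted(
        atlases,
        key=lambda a: (abs(a.protraction_mm - patient_protraction), a.id),
    )


def select_top_k(ranked: list[AtlasRecord], k: int) -> list[AtlasRecord]:
    """First ``k`` atlases of a ranked list, order preserved."""
    if not 1 <= k <= len(ranked):
        raise ValueError(
            f"k={k} out of range for a ranked list of length {len(ranked)}"
        )
    return list(ranked[:k])
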