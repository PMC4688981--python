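"""Readers and writers: NIfTI masks, landmark JSON, manifests, results tables.

Masks travel as NIfTI-1 (.nii or .nii.gz); voxel spacing is carried in the
affine (diagonal, with the origin in the translation column).  Landmarks use
a small JSON dialect::

    {"c5_anterior_tubercle": [x, y, z], "infraglenoid_tubercle": [x, y, z],
     "frame": "RL-AP-SI"}

coordinates in millimetres.  A database manifest is a CSV with columns
``id, protraction_mm, mask_path, landmarks_path`` (paths relative to the
manifest's directory).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .experiment import EquivalenceResult, GroupSummary, RunRecord
from .morphometry import AtlasRecord, LandmarkSet
from .synthetic import PhantomAtlas
from .volume import DEFAULT_FRAME, GeometryError, LabelVolume

logger = logging.getLogger(__name__)


class FormatError(Exception):
    """A file could not be interpreted in the expected format."""


def read_mask(path: str | Path) -> LabelVolume:
    """Load a binary mask from NIfTI.

    Non-binary label values are coerced to {0, 1} (anything nonzero becomes
    foreground) with a warning.  Non-3-D images are rejected.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    values = np.unique(data)
    if not np.isin(values, (0, 1)).all():
        logger.warning(
            "%s: labels %s coerced to binary (nonzero -> 1)", path, values
        )
        data = (data != 0).astype(np.uint8)
    affine = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    return LabelVolume(data.astype(np.uint8), spacing, origin)


def write_mask(volume: LabelVolume, path: str | Path) -> None:
    """Write a mask as NIfTI-1 with spacing/origin encoded in the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    affine[:3, 3] = volume.origin_mm
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.uint8), affine), str(path))


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Load a landmark pair from the JSON dialect; extra keys are ignored."""
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    try:
        return LandmarkSet(
            c5_anterior_tubercle=tuple(payload["c5_anterior_tubercle"]),
            infraglenoid_tubercle=tuple(payload["infraglenoid_tubercle"]),
            frame=payload.get("frame", DEFAULT_FRAME),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing landmark key {exc}") from exc


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "c5_anterior_tubercle": list(landmarks.c5_anterior_tubercle),
        "infraglenoid_tubercle": list(landmarks.infraglenoid_tubercle),
        "frame": landmarks.frame,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")


def write_database(
    database: list[PhantomAtlas], out_dir: str | Path
) -> Path:
    """Write phantom masks, landmarks and a manifest CSV; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for phantom in database:
        record = phantom.atlas
        mask_path = f"{record.id}_mask.nii.gz"
        lm_path = f"{record.id}_landmarks.json"
        write_mask(record.gold_mask, out_dir / mask_path)
        write_landmarks(record.landmarks, out_dir / lm_path)
        rows.append(
            {
                "id": record.id,
                "protraction_mm": record.protraction_mm,
                "mask_path": mask_path,
                "landmarks_path": lm_path,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    logger.info("wrote %d atlases to %s", len(database), out_dir)
    return manifest


def read_database(manifest_path: str | Path) -> list[AtlasRecord]:
    """Load an atlas database from a manifest CSV."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    required = {"id", "mask_path", "landmarks_path"}
    if not required <= set(table.columns):
        raise FormatError(
            f"{manifest_path}: manifest needs columns {sorted(required)}"
        )
    records = []
    for row in table.itertuples():
        records.append(
            AtlasRecord(
                id=str(row.id),
                gold_mask=read_mask(base / row.mask_path),
                landmarks=read_landmarks(base / row.landmarks_path),
            )
        )
    return records


def runs_to_frame(records: list[RunRecord]) -> pd.DataFrame:
    """Per-run scores as a tidy DataFrame (one row per fused combination)."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "k": r.k,
                "strategy": r.strategy,
                "combination": "+".join(sorted(r.combination)),
                "dsc": r.scores.dsc,
                "ji": r.scores.ji,
                "ini": r.scores.ini,
            }
            for r in records
        ]
    ).sort_values(["strategy", "k", "patient_id", "combination"], kind="stable")


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strategy": s.strategy,
                "k": s.k,
                "n_runs": s.n_runs,
                "dsc_mean": s.dsc_mean,
                "dsc_sd": s.dsc_sd,
                "ji_mean": s.ji_mean,
                "ji_sd": s.ji_sd,
                "ini_mean": s.ini_mean,
                "ini_sd": s.ini_sd,
            }
            for s in summaries
        ]
    )


def equivalence_to_dict(result: EquivalenceResult) -> dict:
    return {
        "reference_k": result.reference_k,
        "comparison_k": result.comparison_k,
        "mean_difference": result.mean_difference,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "margin": result.margin,
        "equivalent": result.equivalent,
    }
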