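"""NIfTI round-trip for maps and masks, plus cohort manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .cohort import QuantitativeMap, RoiMask, cohort_summary

__all__ = ["write_subject", "read_subject", "write_cohort"]


def _affine(spacing_mm: tuple[float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = spacing_mm[0]
    aff[1, 1] = spacing_mm[1]
    return aff


def write_subject(qmap: QuantitativeMap, mask: RoiMask, directory: str | Path) -> tuple[Path, Path]:
    """Store one subject as ``<id>_map.nii.gz`` + ``<id>_mask.nii.gz``.

    Spacing is encoded in the affine / header zooms; a round-trip read
    reproduces values and spacing exactly (float64 map, uint8 mask).
    """
    mask.check_congruent(qmap)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(qmap.spacing_mm)
    map_path = directory / f"{qmap.subject_id}_map.nii.gz"
    mask_path = directory / f"{qmap.subject_id}_mask.nii.gz"
    nib.save(nib.Nifti1Image(qmap.values.astype(np.float64), aff), map_path)
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), aff), mask_path)
    return map_path, mask_path


def read_subject(
    map_path: str | Path, mask_path: str | Path, modality: str = "T1", subject_id: str | None = None
) -> tuple[QuantitativeMap, RoiMask]:
    map_img = nib.load(str(map_path))
    mask_img = nib.load(str(mask_path))
    zooms = map_img.header.get_zooms()[:2]
    values = np.asarray(map_img.dataobj, dtype=np.float64)
    mask = np.asarray(mask_img.dataobj) > 0
    if subject_id is None:
        subject_id = Path(map_path).name.split("_map")[0]
    return (
        QuantitativeMap(values, (float(zooms[0]), float(zooms[1])), modality, subject_id),
        RoiMask(mask),
    )


def write_cohort(
    cohort: Sequence[tuple[QuantitativeMap, RoiMask]], directory: str | Path, seed: int | None = None
) -> Path:
    """Write every subject plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    files = []
    for qmap, roi in cohort:
        mp, kp = write_subject(qmap, roi, directory)
        files.append({"subject_id": qmap.subject_id, "map": mp.name, "mask": kp.name})
    manifest = {
        "seed": seed,
        "modality": cohort[0][0].modality if cohort else None,
        "subjects": files,
        "calibration": cohort_summary(cohort),
    }
    path = directory / "cohort_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
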