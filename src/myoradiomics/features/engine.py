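"""Feature extraction at one preprocessing coordinate.

A "coordinate" is a (voxel size, bin width, filter) triple.  The
pipeline order is resample -> filter -> discretize -> features; shape
features are computed for unfiltered coordinates only (98 records) and
skipped for filtered maps (89 records).  Directional features (GLCM,
GLRLM) are computed per angle and the feature values averaged over the
four in-plane angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..cohort import QuantitativeMap, RoiMask
from ..preprocess import (
    DiscretizationSpec,
    DiscretizedRoi,
    FilterSpec,
    apply_filter,
    discretize_roi,
    resample_map,
)
from . import registry
from .firstorder import firstorder_features
from .matrices import (
    ANGLES,
    GrayLevelMatrix,
    compute_glcm,
    compute_gldm,
    compute_glrlm,
    compute_glszm,
    compute_ngtdm,
)
from .shape2d import shape2d_features
from .texture import (
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["FeatureRecord", "extract_all", "extract_from_resampled", "texture_features_from_matrices"]


@dataclass(frozen=True)
class FeatureRecord:
    subject_id: str
    modality: str
    voxel_size_mm: float
    bin_width_ms: float
    filter_name: str
    feature_class: str
    feature_name: str
    value: float  # nan marks an undefined (flagged) value

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.value)


def _average_over_angles(per_angle: list[dict[str, float]]) -> dict[str, float]:
    keys = per_angle[0].keys()
    return {k: float(np.mean([d[k] for d in per_angle])) for k in keys}


def texture_features_from_matrices(
    glcm_by_angle: dict[int, GrayLevelMatrix],
    glrlm_by_angle: dict[int, GrayLevelMatrix],
    glszm: GrayLevelMatrix,
    gldm: GrayLevelMatrix,
    ngtdm: GrayLevelMatrix,
    n_pixels: int,
) -> dict[tuple[str, str], float]:
    """All 73 texture features keyed by (feature_class, feature_name)."""
    out: dict[tuple[str, str], float] = {}
    glcm_avg = _average_over_angles([glcm_features(glcm_by_angle[a]) for a in ANGLES])
    out.update({("glcm", k): v for k, v in glcm_avg.items()})
    glrlm_avg = _average_over_angles([glrlm_features(glrlm_by_angle[a], n_pixels) for a in ANGLES])
    out.update({("glrlm", k): v for k, v in glrlm_avg.items()})
    out.update({("glszm", k): v for k, v in glszm_features(glszm, n_pixels).items()})
    out.update({("gldm", k): v for k, v in gldm_features(gldm).items()})
    out.update({("ngtdm", k): v for k, v in ngtdm_features(ngtdm).items()})
    return out


def _texture_from_discretized(d: DiscretizedRoi) -> dict[tuple[str, str], float]:
    glcms = {a: compute_glcm(d, a) for a in ANGLES}
    glrlms = {a: compute_glrlm(d, a) for a in ANGLES}
    n_pixels = int(d.mask.sum())
    return texture_features_from_matrices(
        glcms, glrlms, compute_glszm(d), compute_gldm(d), compute_ngtdm(d), n_pixels
    )


def extract_from_resampled(
    qmap: QuantitativeMap,
    mask: RoiMask,
    bin_width_ms: float,
    filter_name: str = "original",
    anchor_rule: str = "multiples-of-W",
    classes: tuple[str, ...] | None = None,
) -> list[FeatureRecord]:
    """Extract features from an already-resampled map.

    ``classes`` restricts the computed feature classes (default: all
    applicable — shape only for the unfiltered map).
    """
    include_shape = filter_name == "original"
    wanted = set(classes) if classes is not None else {
        c for c in registry.FEATURE_CLASSES if include_shape or c != "shape"
    }
    if not include_shape:
        wanted.discard("shape")

    source = qmap if filter_name == "original" else apply_filter(qmap, FilterSpec(filter_name))

    values: dict[tuple[str, str], float] = {}
    needs_disc = wanted & {"firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm"}
    if needs_disc:
        d = discretize_roi(source, mask, DiscretizationSpec(bin_width_ms, anchor_rule))
    if "shape" in wanted:
        values.update({("shape", k): v for k, v in shape2d_features(mask, qmap.spacing_mm).items()})
    if "firstorder" in wanted:
        values.update({("firstorder", k): v for k, v in firstorder_features(source, mask, d).items()})
    if needs_disc - {"firstorder"}:
        tex = _texture_from_discretized(d)
        values.update({k: v for k, v in tex.items() if k[0] in wanted})

    records = []
    for cls, name in registry.feature_registry(include_shape=include_shape):
        if cls not in wanted:
            continue
        records.append(
            FeatureRecord(
                subject_id=qmap.subject_id,
                modality=qmap.modality,
                voxel_size_mm=float(qmap.spacing_mm[0]),
                bin_width_ms=float(bin_width_ms),
                filter_name=filter_name,
                feature_class=cls,
                feature_name=name,
                value=float(values[(cls, name)]),
            )
        )
    return records


def extract_all(
    qmap: QuantitativeMap,
    mask: RoiMask,
    voxel_size_mm: float,
    bin_width_ms: float,
    filter_name: str = "original",
    anchor_rule: str = "multiples-of-W",
    classes: tuple[str, ...] | None = None,
) -> list[FeatureRecord]:
    """Resample to ``voxel_size_mm`` then extract the feature inventory:
    98 records for the unfiltered map, 89 (no shape) for filtered ones."""
    rs_map, rs_mask = resample_map(qmap, mask, voxel_size_mm)
    return extract_from_resampled(
        rs_map, rs_mask, bin_width_ms, filter_name, anchor_rule, classes
    )
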