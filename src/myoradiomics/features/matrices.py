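"""Gray-level texture matrices on a discretized ROI.

All five matrix families are computed strictly within the ROI with a
Chebyshev (L-infinity) neighbourhood of distance 1:

* GLCM — symmetric co-occurrence probabilities per direction;
* GLRLM — maximal same-level run lengths per direction;
* GLSZM — 8-connected same-level zone sizes;
* GLDM — per-pixel dependence counts (alpha = 0, i.e. equal levels);
* NGTDM — per-level counts and absolute deviations from the mean of the
  in-ROI neighbours.

Directional matrices use image angles 0°, 45°, 90°, 135° with pixel
offsets (0,1), (-1,1), (-1,0), (-1,-1) in (row, col) coordinates.
Gray levels run 1..N_g; empty levels are retained as zero rows so that
fixed-bin-width level counts stay meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..preprocess import DiscretizedRoi

__all__ = [
    "ANGLES",
    "OFFSETS",
    "GrayLevelMatrix",
    "compute_glcm",
    "compute_glrlm",
    "compute_glszm",
    "compute_gldm",
    "compute_ngtdm",
]

ANGLES = (0, 45, 90, 135)
OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_CHEBYSHEV_1 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


@dataclass
class GrayLevelMatrix:
    kind: str  # glcm | glrlm | glszm | gldm | ngtdm
    values: np.ndarray
    n_levels: int
    distance: int = 1
    direction: int | None = None
    degenerate: bool = False


def _cropped(d: DiscretizedRoi) -> tuple[np.ndarray, np.ndarray]:
    rows = np.any(d.mask, axis=1)
    cols = np.any(d.mask, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    return d.levels[r0 : r1 + 1, c0 : c1 + 1], d.mask[r0 : r1 + 1, c0 : c1 + 1]


def _shift(arr: np.ndarray, dr: int, dc: int, fill=0) -> np.ndarray:
    """arr translated so that out[r, c] = arr[r + dr, c + dc]."""
    out = np.full_like(arr, fill)
    rows, cols = arr.shape
    rs = slice(max(dr, 0), rows + min(dr, 0))
    rd = slice(max(-dr, 0), rows + min(-dr, 0))
    cs = slice(max(dc, 0), cols + min(dc, 0))
    cd = slice(max(-dc, 0), cols + min(-dc, 0))
    out[rd, cd] = arr[rs, cs]
    return out


def compute_glcm(d: DiscretizedRoi, angle: int) -> GrayLevelMatrix:
    """Symmetric co-occurrence probability matrix at one angle."""
    if angle not in OFFSETS:
        raise ValueError(f"angle must be one of {ANGLES}, got {angle}")
    lev, mask = _cropped(d)
    ng = d.n_levels
    if ng > 4096:
        raise ValueError(
            f"N_g = {ng} gray levels would need a {ng}x{ng} co-occurrence "
            "matrix; the bin width is almost certainly too small for the "
            "intensity scale of this (possibly filtered) map"
        )
    dr, dc = OFFSETS[angle]
    nb_lev = _shift(lev, dr, dc)
    nb_in = _shift(mask.astype(np.int8), dr, dc) > 0
    valid = mask & nb_in
    a = lev[valid] - 1
    b = nb_lev[valid] - 1
    counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
    counts = counts + counts.T  # symmetric pairing
    total = counts.sum()
    if total == 0:
        return GrayLevelMatrix("glcm", counts, ng, direction=angle, degenerate=True)
    return GrayLevelMatrix("glcm", counts / total, ng, direction=angle)


def _lines(lev: np.ndarray, angle: int) -> list[np.ndarray]:
    if angle == 0:
        return [lev[r] for r in range(lev.shape[0])]
    if angle == 90:
        return [lev[:, c] for c in range(lev.shape[1])]
    src = np.fliplr(lev) if angle == 45 else lev
    return [np.diagonal(src, k) for k in range(-src.shape[0] + 1, src.shape[1])]


def compute_glrlm(d: DiscretizedRoi, angle: int) -> GrayLevelMatrix:
    """Run-length count matrix (level x run length) at one angle.

    Runs are maximal collinear sequences of equal levels; background
    pixels (outside the ROI) break runs.
    """
    if angle not in OFFSETS:
        raise ValueError(f"angle must be one of {ANGLES}, got {angle}")
    lev, _ = _cropped(d)
    ng = d.n_levels
    max_len = max(lev.shape)
    counts = np.zeros((ng, max_len), dtype=float)
    for line in _lines(lev, angle):
        if line.size == 0:
            continue
        boundaries = np.flatnonzero(np.diff(line)) + 1
        for seg in np.split(np.asarray(line), boundaries):
            if seg[0] > 0:
                counts[seg[0] - 1, len(seg) - 1] += 1
    degenerate = counts.sum() == 0
    return GrayLevelMatrix("glrlm", counts, ng, direction=angle, degenerate=degenerate)


def compute_glszm(d: DiscretizedRoi) -> GrayLevelMatrix:
    """Zone-size count matrix; zones are 8-connected equal-level regions."""
    lev, mask = _cropped(d)
    ng = d.n_levels
    structure = np.ones((3, 3), dtype=int)
    zones: list[tuple[int, int]] = []
    for g in np.unique(lev[mask]):
        lab, n = ndimage.label(lev == g, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((int(g), int(s)) for s in sizes)
    if not zones:
        return GrayLevelMatrix("glszm", np.zeros((ng, 1)), ng, degenerate=True)
    max_size = max(s for _, s in zones)
    counts = np.zeros((ng, max_size), dtype=float)
    for g, s in zones:
        counts[g - 1, s - 1] += 1
    return GrayLevelMatrix("glszm", counts, ng)


def compute_gldm(d: DiscretizedRoi) -> GrayLevelMatrix:
    """Dependence matrix: for every ROI pixel, the number of in-ROI
    Chebyshev-1 neighbours with an equal level (alpha = 0)."""
    lev, mask = _cropped(d)
    ng = d.n_levels
    dep = np.zeros(lev.shape, dtype=np.int64)
    for dr, dc in _CHEBYSHEV_1:
        nb_lev = _shift(lev, dr, dc)
        nb_in = _shift(mask.astype(np.int8), dr, dc) > 0
        dep += (mask & nb_in & (nb_lev == lev)).astype(np.int64)
    max_dep = int(dep[mask].max()) if mask.any() else 0
    counts = np.zeros((ng, max_dep + 1), dtype=float)
    np.add.at(counts, (lev[mask] - 1, dep[mask]), 1.0)
    return GrayLevelMatrix("gldm", counts, ng, degenerate=not mask.any())


def compute_ngtdm(d: DiscretizedRoi) -> GrayLevelMatrix:
    """Neighbourhood gray-tone difference table.

    Returned ``values`` has one row per gray level with columns
    ``[n_i, s_i]``: the count of valid pixels at level i and the summed
    absolute difference between i and the mean level of each pixel's
    in-ROI Chebyshev-1 neighbours.  Pixels with no in-ROI neighbour are
    excluded from both columns.
    """
    lev, mask = _cropped(d)
    ng = d.n_levels
    nb_sum = np.zeros(lev.shape, dtype=float)
    nb_cnt = np.zeros(lev.shape, dtype=float)
    for dr, dc in _CHEBYSHEV_1:
        nb_in = _shift(mask.astype(np.int8), dr, dc) > 0
        nb_sum += np.where(nb_in, _shift(lev, dr, dc), 0)
        nb_cnt += nb_in
    valid = mask & (nb_cnt > 0)
    n_i = np.bincount(lev[valid] - 1, minlength=ng).astype(float)
    diffs = np.abs(lev[valid] - nb_sum[valid] / nb_cnt[valid])
    s_i = np.bincount(lev[valid] - 1, weights=diffs, minlength=ng)
    values = np.stack([n_i, s_i], axis=1)
    return GrayLevelMatrix("ngtdm", values, ng, degenerate=not valid.any())
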