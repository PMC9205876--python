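"""Independent brute-force oracles used only by the tests.

Everything here is written as plain nested loops / direct formula
transcription, deliberately sharing no code with the package: matrix
builders enumerate pixels one at a time, the ICC comes from explicit
sums of squares, and rmcorr from normal equations on a dummy design.
"""

from __future__ import annotations

import math

import numpy as np

NEIGHBOURS_8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def _in(mask, r, c):
    return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]


def glcm_bf(levels, mask, ng, angle):
    """Symmetric co-occurrence counts by enumerating every pixel pair."""
    dr, dc = OFFSETS[angle]
    counts = np.zeros((ng, ng))
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c]:
                continue
            for sr, sc in ((dr, dc), (-dr, -dc)):
                rr, cc = r + sr, c + sc
                if _in(mask, rr, cc):
                    counts[levels[r, c] - 1, levels[rr, cc] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def glrlm_bf(levels, mask, ng, angle):
    """Maximal-run counts by walking each line pixel by pixel."""
    dr, dc = OFFSETS[angle]
    runs = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c]:
                continue
            # only start at the head of a run
            pr, pc = r - dr, c - dc
            if _in(mask, pr, pc) and levels[pr, pc] == levels[r, c]:
                continue
            length = 1
            rr, cc = r + dr, c + dc
            while _in(mask, rr, cc) and levels[rr, cc] == levels[r, c]:
                length += 1
                rr, cc = rr + dr, cc + dc
            runs.append((levels[r, c], length))
    max_len = max((l for _, l in runs), default=1)
    counts = np.zeros((ng, max(max_len, max(mask.shape))))
    for g, l in runs:
        counts[g - 1, l - 1] += 1
    return counts


def glszm_bf(levels, mask, ng):
    """Zone sizes by explicit 8-connected flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c] or seen[r, c]:
                continue
            g = levels[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in NEIGHBOURS_8:
                    nr, nc = rr + dr, cc + dc
                    if _in(mask, nr, nc) and not seen[nr, nc] and levels[nr, nc] == g:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            zones.append((g, size))
    max_size = max((s for _, s in zones), default=1)
    counts = np.zeros((ng, max_size))
    for g, s in zones:
        counts[g - 1, s - 1] += 1
    return counts


def gldm_bf(levels, mask, ng):
    """Dependence counts (alpha = 0) by per-pixel neighbour loops."""
    deps = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c]:
                continue
            d = sum(
                1
                for dr, dc in NEIGHBOURS_8
                if _in(mask, r + dr, c + dc) and levels[r + dr, c + dc] == levels[r, c]
            )
            deps.append((levels[r, c], d))
    max_dep = max((d for _, d in deps), default=0)
    counts = np.zeros((ng, max_dep + 1))
    for g, d in deps:
        counts[g - 1, d] += 1
    return counts


def ngtdm_bf(levels, mask, ng):
    """(n_i, s_i) table by per-pixel neighbour-mean computation."""
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c]:
                continue
            nb = [
                levels[r + dr, c + dc]
                for dr, dc in NEIGHBOURS_8
                if _in(mask, r + dr, c + dc)
            ]
            if not nb:
                continue
            g = levels[r, c]
            n_i[g - 1] += 1
            s_i[g - 1] += abs(g - sum(nb) / len(nb))
    return np.stack([n_i, s_i], axis=1)


def icc_bf(data):
    """Absolute-agreement single-rater ICC from explicit sums of squares."""
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_r = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_c = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_e = ss_tot - ss_r - ss_c
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    den = ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e)
    return ms_r, ms_c, ms_e, (ms_r - ms_e) / den if den else 1.0


def rmcorr_bf(subjects, x, y):
    """rmcorr by least squares on a subject-dummy + common-slope design."""
    subjects = np.asarray(subjects)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    uniq = sorted(set(subjects.tolist()))
    dummies = np.stack([(subjects == s).astype(float) for s in uniq], axis=1)
    full = np.column_stack([dummies, x])
    beta, *_ = np.linalg.lstsq(full, y, rcond=None)
    resid_full = y - full @ beta
    beta0, *_ = np.linalg.lstsq(dummies, y, rcond=None)
    resid_red = y - dummies @ beta0
    ss_err = float(resid_full @ resid_full)
    ss_slope = float(resid_red @ resid_red) - ss_err
    slope = beta[-1]
    r = math.copysign(math.sqrt(max(ss_slope, 0.0) / (ss_slope + ss_err)), slope)
    df = len(y) - len(uniq) - 1
    return r, df, slope
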