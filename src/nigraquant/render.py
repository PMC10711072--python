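"""Volume-level phantom rendering.

Paints per-subject NM, QSM, and SWI-magnitude volumes plus SN/background
masks such that feature extraction on the noiseless volumes reproduces the
subject's truth feature vector exactly (to float tolerance).

The in-mask value sets are built as sorted block multisets: constant
blocks pin the interpolated 10th/90th percentiles, a bounded water-fill
sets the exact mean, and block boundaries realise the exact
above/below-cutoff voxel counts.  Values are assigned to mask voxels in
posterolateral-to-anteromedial order, so low NM signal appears
posterolaterally first -- the spatial pattern of nigral depigmentation --
and low susceptibility sits dorsolaterally (the nigrosome-1 locale).

Size features are quantised to the in-plane voxel lattice (0.25 mm^2);
where a sampled feature combination is geometrically unrealisable (e.g. a
mean susceptibility below the low-chi cutoff with almost no low-chi
voxels) the nearest realisable value is painted and the truth record is
updated to the painted value, keeping round trips exact.
"""

from __future__ import annotations

from dataclasses import replace
from math import ceil, floor
from typing import TYPE_CHECKING

import numpy as np

from .datatypes import FeatureVector, MaskSet, ThresholdPolicy, VolumeImage

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import PhantomConfig

# Grid geometry: 40 mm in-plane field of view at 0.5 mm; NM slabs are
# 3 mm thick (7 slices), the iron grid 1 mm (15 slices); the SN occupies
# three analysis slices on each grid.
NM_SHAPE = (80, 80, 7)
NM_SLICES = (2, 3, 4)
QSM_SHAPE = (80, 80, 15)
QSM_SLICES = (6, 7, 8)
#: Ellipse centres (x, y) per hemisphere, voxels; half-window extents
#: (windows are disjoint between hemispheres).
SN_CENTERS = ((20, 40), (60, 40))
SN_WINDOW = (19, 14)
#: Background ROI box (x-range, y-range) on the analysis slices.
BG_BOX = ((20, 60), (4, 14))

QSM_BACKGROUND = 0.0  # ppb
SMWI_BACKGROUND = 120.0  # a.u.; magnitude background equals this (weight 1)
QSM_LOW_FLOOR = -50.0  # ppb; lowest paintable susceptibility
SMWI_LOW_FLOOR = 10.0  # a.u.
CHI_CAP_MARGIN = 10.0  # keep painted chi below chi_high by this margin


class RenderError(ValueError):
    """Raised when the SN template cannot be placed on the grid."""


# --------------------------------------------------------------------------
# Bounded water-fill over ordered value blocks
# --------------------------------------------------------------------------

def _water_fill(counts, lo, hi, target_sum):
    """Per-block values in [lo, hi] summing (x count) to ``target_sum``.

    Blocks are filled from the last (largest) downwards, so at most one
    block sits strictly between its bounds.  Returns (values, achieved):
    if the target is outside the feasible interval the nearest bound is
    achieved instead.
    """
    counts = np.asarray(counts, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    vals = lo.copy()
    deficit = target_sum - float(np.dot(counts, lo))
    if deficit <= 0:
        return vals, float(np.dot(counts, vals))
    for i in range(len(counts) - 1, -1, -1):
        if counts[i] == 0:
            continue
        room = (hi[i] - lo[i]) * counts[i]
        take = min(room, deficit)
        vals[i] = lo[i] + take / counts[i]
        deficit -= take
        if deficit <= 1e-9 * max(1.0, abs(target_sum)):
            deficit = 0.0
            break
    return vals, float(np.dot(counts, vals))


def _expand(counts, vals):
    return np.repeat(vals, np.asarray(counts, dtype=int))


# --------------------------------------------------------------------------
# Multiset builders
# --------------------------------------------------------------------------

def _nm_multiset(n: int, mean: float, ratio: float, k_above: int
                 ) -> tuple[np.ndarray, float, dict]:
    """Sorted NM in-mask values with exact mean, P90/P10 ratio and
    high-signal count.

    Returns (values ascending, background level, achieved stats).  The
    background level is placed strictly between the (n - k)th and
    (n - k + 1)th order statistics so a background-mean cutoff recovers
    ``k_above`` exactly.
    """
    if n < 20:
        raise RenderError(f"NM mask of {n} voxels is too small to paint")
    ratio = max(ratio, 1.0 + 1e-6)
    k_above = int(np.clip(k_above, 0, n))
    h10, h90 = 0.10 * (n - 1), 0.90 * (n - 1)
    f10, c10 = floor(h10), ceil(h10)
    f90, c90 = floor(h90), ceil(h90)

    # The background crossing may not fall inside a fixed percentile block.
    c = n - k_above
    for lo_i, hi_i in ((f10, c10), (f90, c90)):
        if lo_i < c <= hi_i:
            c = lo_i if (c - lo_i) <= (hi_i + 1 - c) else hi_i + 1
    k_above = n - c

    # Blocks in units of p10: bottom, P10, mid, P90, top.
    counts = [f10, c10 - f10 + 1, f90 - c10 - 1, c90 - f90 + 1, n - 1 - c90]
    lo_u = [0.5, 1.0, 1.0, ratio, ratio]
    hi_u = [1.0, 1.0, ratio, ratio, 50.0 * ratio]
    # Split the free block containing the crossing to separate values there.
    idx_starts = np.concatenate([[0], np.cumsum(counts)])
    blocks = list(zip(counts, lo_u, hi_u))
    eps = 2e-5 * max(1.0, ratio)
    if 0 < k_above < n:
        split_at = None
        for bi in range(5):
            if idx_starts[bi] < c < idx_starts[bi + 1]:
                split_at = bi
                break
        if split_at is not None:
            cnt, lo_b, hi_b = blocks[split_at]
            left = c - idx_starts[split_at]
            gap = min(eps, (hi_b - lo_b) / 4.0)
            blocks[split_at:split_at + 1] = [(left, lo_b, hi_b - gap),
                                             (cnt - left, lo_b + gap, hi_b)]
        else:
            # Crossing on a block boundary: force a value gap across it.
            bi = int(np.searchsorted(idx_starts, c))  # right block index
            while blocks[bi][0] == 0:
                bi += 1
            right_fixed = blocks[bi][1] == blocks[bi][2]
            li = bi - 1
            while blocks[li][0] == 0:
                li -= 1
            if right_fixed:
                cnt, lo_b, hi_b = blocks[li]
                gap = min(eps, (hi_b - lo_b) / 4.0)
                blocks[li] = (cnt, min(lo_b, hi_b - gap), hi_b - gap)
            else:
                cnt, lo_b, hi_b = blocks[bi]
                gap = min(eps, (hi_b - lo_b) / 4.0)
                blocks[bi] = (cnt, lo_b + gap, hi_b)
    counts = [b[0] for b in blocks]
    lo_u = [b[1] for b in blocks]
    hi_u = [b[2] for b in blocks]

    # Scale so the minimum achievable mean sits 3% below the target.
    unit_min = float(np.dot(counts, lo_u)) / n
    p10 = mean / unit_min * 0.97
    vals, got = _water_fill(counts, np.array(lo_u) * p10,
                            np.array(hi_u) * p10, mean * n)
    v = _expand(counts, vals)
    if 0 < k_above < n:
        background = 0.5 * (v[c - 1] + v[c])
    elif k_above == 0:
        background = v[-1] * 1.02
    else:
        background = v[0] * 0.98
    achieved = {"mean": got / n, "ratio": float(ratio), "k_above": k_above}
    return v, float(background), achieved


def _two_level_multiset(n: int, mean: float, k_low: int, cutoff: float,
                        lo_floor: float, hi_cap: float
                        ) -> tuple[np.ndarray, dict]:
    """Sorted two-level values: ``k_low`` strictly below ``cutoff``.

    The low block lives in [lo_floor, cutoff - eps], the high block in
    [cutoff, hi_cap].  ``k_low`` is adjusted to the nearest count for
    which the target mean is achievable; the achieved mean is exact
    whenever feasible.
    """
    if n < 2:
        raise RenderError("mask too small to paint")
    eps = max(1e-4, 1e-6 * abs(cutoff))
    lo_hi = cutoff - eps
    k_low = int(np.clip(k_low, 0, n))
    # Feasible k range for the requested mean.
    if mean < cutoff:
        k_min = ceil(n * (cutoff - mean) / (cutoff - lo_floor) - 1e-9)
    else:
        k_min = 0
    if mean > lo_hi:
        k_max = floor(n * (hi_cap - mean) / (hi_cap - lo_hi) + 1e-9)
    else:
        k_max = n
    if k_min <= k_max:
        k_low = int(np.clip(k_low, max(k_min, 0), min(k_max, n)))
    else:  # mean itself out of range; paint the closest achievable
        k_low = 0 if mean > hi_cap else n
    counts = [k_low, n - k_low]
    vals, got = _water_fill(counts, [lo_floor, cutoff], [lo_hi, hi_cap],
                            mean * n)
    return _expand(counts, vals), {"mean": got / n, "k_low": k_low}


# --------------------------------------------------------------------------
# Mask construction
# --------------------------------------------------------------------------

def _sn_voxel_order(shape, slices, n_voxels: int) -> list[tuple[int, int, int]]:
    """SN voxel coordinates, posterolateral first, exact count.

    Voxels fill two elliptical templates (aspect ~1.6 lateral:AP) from the
    centre outwards; within the selection, ordering is by a
    posterolateral score so value assignment can realise the
    depigmentation gradient.
    """
    per_slice = len(slices)
    capacity = per_slice * len(SN_CENTERS) * (2 * SN_WINDOW[0] + 1) * (2 * SN_WINDOW[1] + 1)
    if n_voxels > capacity:
        raise RenderError("volume too small to contain the SN template")
    # Distribute voxels across slice x hemisphere regions.
    n_regions = per_slice * len(SN_CENTERS)
    base, rem = divmod(n_voxels, n_regions)
    region_counts = [base + (1 if i < rem else 0) for i in range(n_regions)]
    coords: list[tuple[float, int, int, int]] = []  # (score, x, y, z)
    ri = 0
    for z in slices:
        for (cx, cy) in SN_CENTERS:
            cnt = region_counts[ri]
            ri += 1
            if cnt == 0:
                continue
            wx, wy = SN_WINDOW
            if cnt > (2 * wx + 1) * (2 * wy + 1):
                raise RenderError("volume too small to contain the SN template")
            xs = np.arange(cx - wx, cx + wx + 1)
            ys = np.arange(cy - wy, cy + wy + 1)
            if xs[0] < 0 or xs[-1] >= shape[0] or ys[0] < 0 or ys[-1] >= shape[1]:
                raise RenderError("volume too small to contain the SN template")
            gx, gy = np.meshgrid(xs, ys, indexing="ij")
            # Elliptical radius, lateral semi-axis 1.6x the AP axis.
            r2 = ((gx - cx) / 1.6) ** 2 + (gy - cy) ** 2
            order = np.argsort(r2.ravel(), kind="stable")[:cnt]
            sel_x, sel_y = gx.ravel()[order], gy.ravel()[order]
            lateral = (sel_x - cx) if cx > shape[0] // 2 else (cx - sel_x)
            score = lateral + (sel_y - cy)  # +y = posterior
            for s, x, y in zip(score, sel_x, sel_y):
                coords.append((float(-s), int(x), int(y), int(z)))
    coords.sort()  # most posterolateral (largest score) first
    return [(x, y, z) for _, x, y, z in coords]


def _paint(shape, coords, values_sorted: np.ndarray,
           background: float, ascending_with_order: bool) -> np.ndarray:
    """Fill a volume at ``background`` and paint sorted values onto the
    ordered SN voxels (ascending or descending along the order)."""
    vol = np.full(shape, background, dtype=np.float64)
    vals = values_sorted if ascending_with_order else values_sorted[::-1]
    idx = np.asarray(coords)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = vals
    return vol


def _mask_from_coords(shape, coords, slices) -> MaskSet:
    sn = np.zeros(shape, dtype=bool)
    for (x, y, z) in coords:
        sn[x, y, z] = True
    bg = np.zeros(shape, dtype=bool)
    (x0, x1), (y0, y1) = BG_BOX
    for z in slices:
        bg[x0:x1, y0:y1, z] = True
    return MaskSet(sn_mask=sn, background_mask=bg,
                   analysis_slices=tuple(slices))


# --------------------------------------------------------------------------
# Subject rendering
# --------------------------------------------------------------------------

def render_subject_volumes(truth: FeatureVector, config: "PhantomConfig",
                           rng: np.random.Generator
                           ) -> tuple[dict, dict, FeatureVector]:
    """Render (volumes, masks) for one subject from its truth features.

    Returns the volumes (``NM``, ``QSM``, ``SWI_MAG``), per-grid mask sets
    (``NM``, ``QSM``), and the truth vector updated to the painted
    (lattice-quantised) values.  With ``config.noise_sd == 0`` feature
    extraction under the default threshold policy reproduces the returned
    truth exactly.
    """
    policy = ThresholdPolicy()
    area = config.voxel_dims_nm[0] * config.voxel_dims_nm[1]
    area_q = config.voxel_dims_qsm[0] * config.voxel_dims_qsm[1]

    n_nm = max(int(round(truth.nm_size / area)), 24)
    k_nm = int(np.clip(round(truth.nm_size_high / area), 0, n_nm))
    n_q = max(int(round(truth.qsm_size / area_q)), 24)
    k_chi = int(np.clip(round(truth.qsm_size_low / area_q), 0, n_q))
    k_smwi = int(np.clip(round(truth.smwi_size_lowsig / area_q), 0, n_q))

    nm_vals, nm_bg, nm_got = _nm_multiset(n_nm, truth.nm_signal,
                                          truth.nm_contrast_range, k_nm)
    chi_cap = policy.smwi_chi_high - CHI_CAP_MARGIN
    chi_vals, chi_got = _two_level_multiset(
        n_q, truth.qsm_chi_mean, k_chi, policy.qsm_chi_cutoff,
        QSM_LOW_FLOOR, chi_cap)
    smwi_vals, smwi_got = _two_level_multiset(
        n_q, truth.smwi_signal, k_smwi, SMWI_BACKGROUND,
        SMWI_LOW_FLOOR, 3.0 * SMWI_BACKGROUND)

    nm_coords = _sn_voxel_order(NM_SHAPE, NM_SLICES, n_nm)
    q_coords = _sn_voxel_order(QSM_SHAPE, QSM_SLICES, n_q)

    # NM: lowest signal most posterolateral (depigmentation gradient).
    nm_vol = _paint(NM_SHAPE, nm_coords, nm_vals, nm_bg, True)
    # QSM: lowest chi dorsolateral (nigrosome locale); SMWI anti-ordered
    # with chi so iron-rich voxels are dark, as in the weighting physics.
    chi_vol = _paint(QSM_SHAPE, q_coords, chi_vals, QSM_BACKGROUND, True)
    smwi_desired = _paint(QSM_SHAPE, q_coords, smwi_vals, SMWI_BACKGROUND,
                          False)
    w = np.clip((policy.smwi_chi_high - chi_vol)
                / (policy.smwi_chi_high - policy.smwi_chi_low), 0.0, 1.0)
    mag_vol = smwi_desired / w**policy.smwi_power

    if config.noise_sd > 0:
        nm_vol = nm_vol + rng.normal(0.0, config.noise_sd, NM_SHAPE)
        chi_vol = chi_vol + rng.normal(0.0, config.noise_sd, QSM_SHAPE)
        mag_vol = mag_vol + rng.normal(0.0, config.noise_sd, QSM_SHAPE)

    volumes = {
        "NM": VolumeImage(nm_vol, tuple(config.voxel_dims_nm), "NM"),
        "QSM": VolumeImage(chi_vol, tuple(config.voxel_dims_qsm), "QSM"),
        "SWI_MAG": VolumeImage(mag_vol, tuple(config.voxel_dims_qsm),
                               "SWI_MAG"),
    }
    masks = {
        "NM": _mask_from_coords(NM_SHAPE, nm_coords, NM_SLICES),
        "QSM": _mask_from_coords(QSM_SHAPE, q_coords, QSM_SLICES),
    }
    truth_painted = replace(
        truth,
        nm_signal=nm_got["mean"],
        nm_contrast_range=nm_got["ratio"],
        nm_size=n_nm * area,
        nm_size_high=nm_got["k_above"] * area,
        qsm_chi_mean=chi_got["mean"],
        qsm_size=n_q * area_q,
        qsm_size_low=chi_got["k_low"] * area_q,
        smwi_signal=smwi_got["mean"],
        smwi_size=n_q * area_q,
        smwi_size_lowsig=smwi_got["k_low"] * area_q,
    )
    return volumes, masks, truth_painted
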