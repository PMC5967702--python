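"""Dense disparity estimation by semi-global matching, and height maps.

The matcher follows the classic SGM recipe: a per-pixel matching cost (5x5
census transform + Hamming distance, robust to illumination differences
between the two cameras), approximate global smoothing by aggregating
scanline dynamic-programming costs along eight image directions with a
small penalty ``P1`` for one-level disparity changes and a larger ``P2``
for jumps, winner-take-all selection with parabolic sub-pixel refinement,
and a left-right consistency check that masks occlusions and mismatches
rather than filling them in.

Ground disparity ``d_g`` is estimated as the median disparity of ground
pixels (robust to stray plant pixels in the ground mask), and heights come
from the normalized disparity ``eta = d - d_g`` so that any rig-vibration
offset common to the frame cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import CameraRig, height_from_normalized_disparity
from .scene import StereoPair

__all__ = [
    "DisparityMap",
    "HeightMap",
    "census_transform",
    "cost_volume",
    "sgm_aggregate",
    "disparity_select",
    "estimate_ground_disparity",
    "height_map",
    "disparity_search_range",
    "compute_disparity",
]

#: Hamming distances for a 5x5 census window lie in [0, 24]; out-of-bounds
#: candidates carry this sentinel so they can never win.
COST_SENTINEL = 25

#: Default SGM penalties on the census Hamming scale.
DEFAULT_P1 = 8
DEFAULT_P2 = 96

_DIRECTIONS_8 = ((0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass
class DisparityMap:
    """Per-pixel disparity with validity mask and search-range bookkeeping."""

    disparity: np.ndarray  # float32, sub-pixel
    valid: np.ndarray  # bool; invalid pixels are masked, never zero-filled
    d_min: int
    d_max: int
    d_g: float | None = None  # ground disparity once estimated
    d_g_spread: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = self.disparity[self.valid]
        if d.size and (d.min() < self.d_min - 1 or d.max() > self.d_max + 1):
            raise ValueError("valid disparities outside the search range")


@dataclass
class HeightMap:
    """Per-pixel height above the ground reference (mm)."""

    height_mm: np.ndarray
    valid: np.ndarray
    clamped_below_ground: int = 0
    meta: dict = field(default_factory=dict)


def to_gray(image: np.ndarray) -> np.ndarray:
    """Luminance as float64 in [0, 255]."""
    image = np.asarray(image)
    if image.ndim == 3:
        return image[..., :3].astype(float) @ np.array([0.299, 0.587, 0.114])
    return image.astype(float)


def census_transform(gray: np.ndarray, window: int = 5) -> np.ndarray:
    """Census codes: each pixel's neighbourhood encoded as comparison bits.

    Bit ``i`` is set when the ``i``-th neighbour in the ``window x window``
    patch is brighter than the centre.  Edges use edge-replicated padding.
    """
    if window % 2 != 1 or window < 3 or window * window - 1 > 32:
        raise ValueError("window must be odd and hold at most 33 pixels")
    r = window // 2
    padded = np.pad(gray, r, mode="edge")
    codes = np.zeros(gray.shape, dtype=np.uint32)
    rows, cols = gray.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dy == 0 and dx == 0:
                continue
            neigh = padded[r + dy : r + dy + rows, r + dx : r + dx + cols]
            codes = (codes << np.uint32(1)) | (neigh > gray)
    return codes


def cost_volume(
    pair: StereoPair,
    d_range: tuple,
    window: int = 5,
    reference: str = "left",
) -> np.ndarray:
    """Census/Hamming matching costs for one reference view.

    With the left view as reference, ``cost[y, x, i]`` is the Hamming
    distance between the census codes of left pixel ``(y, x)`` and right
    pixel ``(y, x - (d_min + i))``; with the right view as reference the
    candidate partner is left pixel ``(y, x + (d_min + i))``.  Candidates
    that fall off the partner image carry :data:`COST_SENTINEL`.
    """
    if not pair.rectified:
        raise ValueError("cost_volume requires a rectified pair")
    if reference not in ("left", "right"):
        raise ValueError("reference must be 'left' or 'right'")
    d_min, d_max = int(d_range[0]), int(d_range[1])
    n_d = d_max - d_min + 1
    if not 0 < n_d <= 256:
        raise ValueError("disparity range must be non-empty and at most 256 wide")
    cl = census_transform(to_gray(pair.left), window)
    cr = census_transform(to_gray(pair.right), window)
    rows, cols = cl.shape
    cost = np.full((rows, cols, n_d), COST_SENTINEL, dtype=np.uint8)
    for i, d in enumerate(range(d_min, d_max + 1)):
        if d >= cols or d < 0:
            continue
        if d == 0:
            cost[:, :, i] = np.bitwise_count(cl ^ cr)
        elif reference == "left":
            cost[:, d:, i] = np.bitwise_count(cl[:, d:] ^ cr[:, :-d])
        else:
            cost[:, :-d, i] = np.bitwise_count(cr[:, :-d] ^ cl[:, d:])
    return cost


def _relax(prev: np.ndarray, P1: float, P2: float) -> np.ndarray:
    """One SGM step: min over same-d, d±1 (+P1), any-d (+P2), minus min."""
    m = prev.min(axis=-1, keepdims=True)
    cand = prev.copy()
    cand[..., :-1] = np.minimum(cand[..., :-1], prev[..., 1:] + P1)
    cand[..., 1:] = np.minimum(cand[..., 1:], prev[..., :-1] + P1)
    np.minimum(cand, m + P2, out=cand)
    return cand - m


def sgm_aggregate(
    cost: np.ndarray,
    P1: float = DEFAULT_P1,
    P2: float = DEFAULT_P2,
    directions=_DIRECTIONS_8,
) -> np.ndarray:
    """Sum of directional scanline DP costs over the configured path set.

    Each path obeys the SGM recurrence ``L_r(p, d) = C(p, d) +
    min(L_r(p-r, d), L_r(p-r, d±1) + P1, min_d' L_r(p-r, d') + P2) -
    min_d' L_r(p-r, d')``; pixels with no predecessor along a direction
    start at the raw cost.
    """
    if not (P2 >= P1 >= 0):
        raise ValueError("penalties must satisfy P2 >= P1 >= 0")
    cost = cost.astype(np.float32)
    total = np.zeros_like(cost)
    for dy, dx in directions:
        if dy == 0 and dx == 0:
            raise ValueError("invalid aggregation direction (0, 0)")
        total += _aggregate_direction(cost, dy, dx, P1, P2)
    return total


def _aggregate_direction(cost, dy, dx, P1, P2):
    rows, cols, _ = cost.shape
    L = cost.copy()
    if dx != 0:
        xs = range(1, cols) if dx > 0 else range(cols - 2, -1, -1)
        for x in xs:
            prev = L[:, x - dx, :]
            if dy == 0:
                L[:, x, :] = cost[:, x, :] + _relax(prev, P1, P2)
            elif dy > 0:
                L[dy:, x, :] = cost[dy:, x, :] + _relax(prev[:-dy], P1, P2)
            else:
                L[:dy, x, :] = cost[:dy, x, :] + _relax(prev[-dy:], P1, P2)
    else:
        ys = range(1, rows) if dy > 0 else range(rows - 2, -1, -1)
        for y in ys:
            L[y, :, :] = cost[y, :, :] + _relax(L[y - dy, :, :], P1, P2)
    return L


def _subpixel(agg: np.ndarray, best: np.ndarray) -> np.ndarray:
    """Parabola fit through the winning cost and its two neighbours."""
    rows, cols, n_d = agg.shape
    yy, xx = np.indices(best.shape)
    interior = (best > 0) & (best < n_d - 1)
    c0 = agg[yy, xx, np.clip(best - 1, 0, n_d - 1)]
    c1 = agg[yy, xx, best]
    c2 = agg[yy, xx, np.clip(best + 1, 0, n_d - 1)]
    denom = c0 - 2 * c1 + c2
    delta = np.where((denom > 1e-9) & interior, 0.5 * (c0 - c2) / np.where(denom == 0, 1, denom), 0.0)
    return np.clip(delta, -0.5, 0.5)


def disparity_select(
    agg_left: np.ndarray,
    d_range: tuple,
    agg_right: np.ndarray | None = None,
    lr_tolerance: float = 1.0,
    raw_cost: np.ndarray | None = None,
    max_match_cost: float = 12.0,
) -> DisparityMap:
    """Winner-take-all disparity with sub-pixel refinement and LR check.

    Ties go to the lowest disparity.  ``agg_right`` should be aggregated
    from an independently built right-reference cost volume: when it is
    omitted the right-as-reference costs are read out of the left volume
    (``agg_R[y, x, d] = agg_L[y, x + d, d]``), which is cheaper but shares
    the left volume's failure modes near frame edges.  Pixels whose left-
    and right-referenced disparities disagree by more than
    ``lr_tolerance`` px (occlusions, mismatches) are masked invalid, as are
    pixels whose *raw* matching cost at the winning disparity exceeds
    ``max_match_cost`` (half the census bits: the similarity of two
    unrelated patches) when ``raw_cost`` is supplied — aggregation can
    otherwise hallucinate smooth disparities where no true match exists.
    """
    d_min, d_max = int(d_range[0]), int(d_range[1])
    rows, cols, n_d = agg_left.shape
    best = np.argmin(agg_left, axis=2)  # ties -> lowest disparity
    disp = d_min + best + _subpixel(agg_left, best)

    if agg_right is None:
        agg_right = np.full_like(agg_left, COST_SENTINEL * 8.0)
        for i in range(n_d):
            d = d_min + i
            if 0 <= d < cols:
                if d == 0:
                    agg_right[:, :, i] = agg_left[:, :, i]
                else:
                    agg_right[:, :-d, i] = agg_left[:, d:, i]
    best_r = np.argmin(agg_right, axis=2)
    disp_r = d_min + best_r + _subpixel(agg_right, best_r)

    xx = np.arange(cols)[None, :]
    x_r = np.round(xx - disp).astype(int)
    in_bounds = (x_r >= 0) & (x_r < cols)
    x_r_c = np.clip(x_r, 0, cols - 1)
    lr_ok = np.abs(disp - np.take_along_axis(disp_r, x_r_c, axis=1)) <= lr_tolerance
    valid = in_bounds & lr_ok
    if raw_cost is not None:
        winner_cost = np.take_along_axis(raw_cost, best[..., None], axis=2)[..., 0]
        valid &= winner_cost <= max_match_cost
    disp = disp.astype(np.float32)
    return DisparityMap(disparity=disp, valid=valid, d_min=d_min, d_max=d_max)


def estimate_ground_disparity(
    dmap: DisparityMap,
    ground_mask: np.ndarray | None = None,
    rig: CameraRig | None = None,
    min_pixels: int = 100,
    max_offset_px: float = 8.0,
) -> float:
    """Ground-level disparity ``d_g``: median of valid ground pixels.

    The median (rather than the mean) is robust to residual plant pixels
    inside the ground mask.  When a rig is supplied, the estimate must lie
    within ``max_offset_px`` of the rig-implied ``d_g = f*G/(H*S_c)`` —
    vibration offsets are a few pixels at most, so a larger discrepancy
    means the "ground" pixels were mismatched (e.g. soil deeply occluded
    under a closed canopy) and the rig value is used instead, with a
    warning.  The same fallback applies with too few valid ground pixels.
    Falling back forfeits vibration cancellation.
    """
    if ground_mask is not None:
        sel = dmap.valid & np.asarray(ground_mask, dtype=bool)
    else:
        sel = dmap.valid
    vals = dmap.disparity[sel]
    d_g = spread = None
    if vals.size >= min_pixels:
        d_g = float(np.median(vals))
        spread = float(np.median(np.abs(vals - d_g)))
        if rig is not None and abs(d_g - rig.ground_disparity) > max_offset_px:
            warnings.warn(
                f"ground-pixel disparity median {d_g:.1f} px is implausibly "
                f"far from the rig-implied {rig.ground_disparity:.1f} px; "
                "using the rig value (is the soil visible at all?)",
                stacklevel=2,
            )
            d_g = None
    elif rig is None:
        raise ValueError("too few ground pixels and no rig to fall back on")
    else:
        warnings.warn(
            f"only {vals.size} valid ground pixels (<{min_pixels}); "
            "falling back to the rig-implied ground disparity",
            stacklevel=2,
        )
    if d_g is None:
        if rig is None:
            raise ValueError("ground disparity implausible and no rig to fall back on")
        d_g, spread = rig.ground_disparity, float("nan")
    dmap.d_g = d_g
    dmap.d_g_spread = spread
    return d_g


def height_map(dmap: DisparityMap, rig: CameraRig) -> HeightMap:
    """Per-pixel canopy height from normalized disparity (mm).

    Requires ``dmap.d_g``.  Heights are clamped to ``[0, H)``; the number
    of below-ground pixels clamped to zero is reported as a diagnostic
    (furrows make slightly negative heights physically real).
    """
    if dmap.d_g is None:
        raise ValueError("estimate_ground_disparity must run before height_map")
    eta = dmap.disparity.astype(float) - dmap.d_g
    rig_limit = -rig.focal_length * rig.baseline / (rig.pixel_pitch * rig.camera_height)
    eta = np.clip(eta, rig_limit * 0.99, None)  # keep the denominator positive
    h = height_from_normalized_disparity(rig, eta)
    clamped = int(np.count_nonzero((h < 0) & dmap.valid))
    h = np.clip(h, 0.0, rig.camera_height * (1 - 1e-9))
    h[~dmap.valid] = np.nan
    return HeightMap(
        height_mm=h,
        valid=dmap.valid.copy(),
        clamped_below_ground=clamped,
        meta={"d_g": dmap.d_g, **dmap.meta},
    )


def disparity_search_range(
    rig: CameraRig,
    h_min_mm: float = -50.0,
    h_max_mm: float = 1500.0,
    vibration_margin_px: float = 4.0,
) -> tuple:
    """Geometry-derived disparity search window ``[d_min, d_max]``.

    Spans furrow bottoms (``h_min``) to the tallest pre-heading canopy
    (``h_max``) around the rig's ground disparity, padded for vibration.
    """
    if not -rig.camera_height < h_min_mm < h_max_mm < rig.camera_height:
        raise ValueError("need -H < h_min < h_max < H")
    f, G, S_c, H = rig.focal_length, rig.baseline, rig.pixel_pitch, rig.camera_height
    d_lo = f * G / ((H - h_min_mm) * S_c) - vibration_margin_px
    d_hi = f * G / ((H - h_max_mm) * S_c) + vibration_margin_px
    d_min, d_max = int(np.floor(d_lo)), int(np.ceil(d_hi))
    d_min = max(d_min, 1)
    if d_max - d_min + 1 > 256:
        d_max = d_min + 255
    return d_min, d_max


def compute_disparity(
    pair: StereoPair,
    rig: CameraRig,
    d_range: tuple | None = None,
    P1: float = DEFAULT_P1,
    P2: float = DEFAULT_P2,
    window: int = 5,
) -> DisparityMap:
    """Full matching stage: census costs -> SGM -> WTA + LR check.

    Both views are aggregated independently so the left-right consistency
    check can catch pixels whose true partner is occluded or off-frame.
    """
    if d_range is None:
        d_range = disparity_search_range(rig)
    cost = cost_volume(pair, d_range, window=window)
    agg = sgm_aggregate(cost, P1=P1, P2=P2)
    cost_r = cost_volume(pair, d_range, window=window, reference="right")
    agg_r = sgm_aggregate(cost_r, P1=P1, P2=P2)
    dmap = disparity_select(agg, d_range, agg_right=agg_r, raw_cost=cost)
    dmap.meta["P1"], dmap.meta["P2"] = P1, P2
    return dmap
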