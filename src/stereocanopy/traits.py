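"""Canopy phenotypes from per-pixel height maps.

The central phenotype is the canopy height distribution: the histogram of
plant-pixel heights within a plot.  From it we derive

* canopy height — the top-2% threshold: the smallest height below which 98%
  of plant pixels lie.  Robust to sparse wheat spikes protruding above the
  leaf canopy (they occupy well under 2% of plant pixels near heading).
* median canopy height — the top-50% threshold, robust to spikes altogether.
* coverage — the total weight under the histogram, in pixels or in mm^2.
* an area-normalized distribution, where each pixel contributes its physical
  footprint ``(P*S_c/f)**2`` instead of a unit count, making distributions
  comparable across camera heights and hardware.
* a biomass estimate integrating density-weighted tissue area distributions
  over height, which the naive "coverage x height" block product can only
  overestimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .geometry import CameraRig, pixel_footprint_area

__all__ = [
    "HeightHistogram",
    "CanopyTraits",
    "BiomassInputs",
    "segment_plant_pixels",
    "height_histogram",
    "canopy_height",
    "normalize_histogram",
    "biomass",
    "coverage",
    "extract_traits",
    "central_roi",
]

#: Excess-green threshold separating soil from vegetation when Otsu cannot
#: (single-class scenes).  ExG = 2g - r - b on chromaticity-normalized
#: channels is ~0 for grey/brown soil and >0.1 for green leaves.
_EXG_FALLBACK = 0.05


@dataclass
class HeightHistogram:
    """Binned canopy height distribution.

    ``unit`` is ``"pixels"`` (each plant pixel counts 1) or ``"area_mm2"``
    (each pixel contributes its physical footprint at its depth).
    """

    bin_edges: np.ndarray  # cm, length n_bins + 1, uniform
    weights: np.ndarray  # length n_bins, >= 0
    unit: str = "pixels"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size != self.weights.size + 1:
            raise ValueError("bin_edges must have one more entry than weights")
        if np.any(self.weights < 0):
            raise ValueError("histogram weights must be non-negative")

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def quantile_height(self, top_fraction: float) -> float:
        """Weighted nearest-rank top-``top_fraction`` threshold (cm).

        Reporting convenience; trait extraction uses the exact pixel
        multiset (see :func:`canopy_height`).
        """
        if not 0 < top_fraction < 1:
            raise ValueError("top_fraction must lie in (0, 1)")
        if self.total <= 0:
            raise ValueError("empty histogram has no quantiles")
        cum = np.cumsum(self.weights)
        k = np.searchsorted(cum, (1.0 - top_fraction) * self.total, side="left")
        return float(self.bin_edges[min(k + 1, len(self.weights))])


@dataclass
class CanopyTraits:
    """Scalar phenotypes for one plot/date, heights in cm rounded to 0.1."""

    canopy_height_cm: float
    median_canopy_height_cm: float
    coverage_pixels: int
    coverage_area_mm2: float
    clamped_below_ground: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.median_canopy_height_cm <= self.canopy_height_cm + 1e-9:
            raise ValueError("median canopy height cannot exceed canopy height")


@dataclass
class BiomassInputs:
    """Height-resolved tissue area distributions and densities.

    Each distribution maps height bins (common ``bin_edges``, cm) to area
    per bin (mm^2).  Densities are mass per area (arbitrary units).  Either
    per-tissue (leaf/stem/spike) or a single combined distribution with a
    common density.
    """

    bin_edges: np.ndarray  # cm
    distributions: Mapping[str, np.ndarray]  # tissue -> area per bin (mm^2)
    densities: Mapping[str, float]  # tissue -> mass per area

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        for name, a in self.distributions.items():
            a = np.asarray(a, dtype=float)
            if a.size != self.bin_edges.size - 1:
                raise ValueError(f"distribution {name!r} does not match bin_edges")
            if np.any(a < 0):
                raise ValueError(f"distribution {name!r} has negative area")
        for name, rho in self.densities.items():
            if rho < 0:
                raise ValueError(f"density {name!r} is negative")
        missing = set(self.distributions) - set(self.densities)
        if missing:
            raise ValueError(f"no density supplied for tissues {sorted(missing)}")


def segment_plant_pixels(rgb: np.ndarray) -> np.ndarray:
    """Vegetation mask from an RGB image via the excess-green index.

    ExG = 2g - r - b on chromaticity-normalized channels, thresholded with
    Otsu's method.  When the scene is single-class (all soil or all canopy)
    Otsu would split the one class in half, so the Otsu threshold is only
    trusted when the two classes it induces straddle the fixed fallback
    threshold; otherwise the fallback decides globally.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError(
            "segment_plant_pixels needs an RGB image; for grayscale input "
            "supply an explicit plant mask instead"
        )
    from skimage.filters import threshold_otsu

    chan = rgb[..., :3].astype(float)
    total = chan.sum(axis=2)
    total[total == 0] = 1.0
    r, g, b = (chan[..., i] / total for i in range(3))
    exg = 2 * g - r - b

    try:
        t = float(threshold_otsu(exg))
    except ValueError:  # constant image
        return exg > _EXG_FALLBACK
    lo, hi = exg[exg <= t], exg[exg > t]
    if lo.size == 0 or hi.size == 0:
        return exg > _EXG_FALLBACK
    # single-class scene: both Otsu classes on one side of the fallback
    if lo.mean() > _EXG_FALLBACK or hi.mean() < _EXG_FALLBACK:
        return exg > _EXG_FALLBACK
    return exg > t


def central_roi(shape: tuple, fraction: float = 0.8) -> np.ndarray:
    """Boolean mask selecting the central ``fraction`` of each image axis.

    Plot edges suffer from border rows and occlusion artefacts; analysis is
    restricted to a central rectangular region by default.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    mask = np.zeros(shape[:2], dtype=bool)
    h, w = shape[:2]
    mh, mw = int(round(h * (1 - fraction) / 2)), int(round(w * (1 - fraction) / 2))
    mask[mh : h - mh, mw : w - mw] = True
    return mask


def _valid_plant_heights_cm(
    height_map_mm: np.ndarray,
    mask: np.ndarray,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    sel = np.asarray(mask, dtype=bool)
    if valid is not None:
        sel = sel & np.asarray(valid, dtype=bool)
    return np.asarray(height_map_mm, dtype=float)[sel] / 10.0


def height_histogram(
    height_map_mm: np.ndarray,
    mask: np.ndarray,
    bin_width_cm: float = 1.0,
    valid: np.ndarray | None = None,
    meta: dict | None = None,
) -> HeightHistogram:
    """Pixel-count histogram of plant heights, 1 cm bins by default.

    ``mask`` selects plant pixels; ``valid`` (optional) masks out pixels with
    failed stereo matches.  An empty selection yields an empty, flagged
    histogram rather than an error.
    """
    if bin_width_cm <= 0:
        raise ValueError("bin width must be positive")
    heights = _valid_plant_heights_cm(height_map_mm, mask, valid)
    meta = dict(meta or {})
    if heights.size == 0:
        meta["empty"] = True
        return HeightHistogram(np.array([0.0, bin_width_cm]), np.array([0.0]), "pixels", meta)
    top = max(float(heights.max()), bin_width_cm)
    n_bins = int(np.ceil(top / bin_width_cm + 1e-9))
    edges = np.arange(n_bins + 1) * bin_width_cm
    w, _ = np.histogram(heights, bins=edges)
    return HeightHistogram(edges, w.astype(float), "pixels", meta)


def canopy_height(heights_cm: np.ndarray | HeightHistogram, top_fraction: float = 0.02) -> float:
    """Top-``top_fraction`` canopy height threshold (cm), nearest-rank.

    The smallest height such that at least ``1 - top_fraction`` of the plant
    pixels lie at or below it.  ``top_fraction=0.02`` defines canopy height
    (excluding sparse spikes); ``0.50`` the median canopy height.  Accepts
    the exact pixel-height multiset (preferred) or a binned histogram.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    if isinstance(heights_cm, HeightHistogram):
        return heights_cm.quantile_height(top_fraction)
    h = np.sort(np.asarray(heights_cm, dtype=float).ravel())
    if h.size == 0:
        raise ValueError("cannot define canopy height of an empty pixel set")
    k = int(np.ceil((1.0 - top_fraction) * h.size))
    return float(h[max(k, 1) - 1])


def normalize_histogram(
    height_map_mm: np.ndarray,
    mask: np.ndarray,
    rig: CameraRig,
    bin_width_cm: float = 1.0,
    valid: np.ndarray | None = None,
    meta: dict | None = None,
) -> HeightHistogram:
    """Area-unit canopy height distribution.

    Each plant pixel contributes its physical footprint ``(P*S_c/f)**2`` at
    its own depth ``P = H - h`` instead of a unit count, so that the same
    canopy imaged from different camera heights yields the same totals.
    """
    if bin_width_cm <= 0:
        raise ValueError("bin width must be positive")
    heights = _valid_plant_heights_cm(height_map_mm, mask, valid)
    meta = dict(meta or {})
    if heights.size == 0:
        meta["empty"] = True
        return HeightHistogram(np.array([0.0, bin_width_cm]), np.array([0.0]), "area_mm2", meta)
    depth = rig.camera_height - heights * 10.0
    areas = pixel_footprint_area(rig, depth)
    top = max(float(heights.max()), bin_width_cm)
    n_bins = int(np.ceil(top / bin_width_cm + 1e-9))
    edges = np.arange(n_bins + 1) * bin_width_cm
    w, _ = np.histogram(heights, bins=edges, weights=areas)
    return HeightHistogram(edges, w, "area_mm2", meta)


def biomass(inputs: BiomassInputs) -> float:
    """Plot biomass from height-resolved tissue area distributions.

    ``M = sum_t rho_t * integral_0^T a_t(h) dh`` with the integral taken as
    the Riemann sum of per-bin areas (each bin already holds the area within
    its height slice, so the sum over bins *is* the integral of the density
    ``a_t(h)`` over height).  With a common density the result reduces to
    rho times the area under the combined normalized distribution — always
    at most the naive block estimate ``rho * A * T``.
    """
    total = 0.0
    for name, a in inputs.distributions.items():
        total += float(inputs.densities[name]) * float(np.sum(a))
    return total


def coverage(hist: HeightHistogram) -> float:
    """Total weight under the distribution (pixel count or mm^2 of leaf area)."""
    return hist.total


def extract_traits(
    height_map_mm: np.ndarray,
    mask: np.ndarray,
    rig: CameraRig,
    valid: np.ndarray | None = None,
    top_fraction: float = 0.02,
    median_fraction: float = 0.50,
    meta: dict | None = None,
) -> CanopyTraits:
    """Scalar canopy traits from a height map and plant mask.

    Heights are reported in cm rounded to 0.1 cm.  Below-ground pixels
    (furrow shadows, matching noise) are clamped to 0 and counted in the
    diagnostics field.
    """
    heights = _valid_plant_heights_cm(height_map_mm, mask, valid)
    if heights.size == 0:
        warnings.warn("no valid plant pixels; traits undefined", stacklevel=2)
        raise ValueError("cannot extract traits from an empty plant mask")
    clamped = int(np.count_nonzero(heights < 0))
    heights = np.clip(heights, 0.0, None)
    depth = rig.camera_height - heights * 10.0
    area = float(np.sum(pixel_footprint_area(rig, depth)))
    return CanopyTraits(
        canopy_height_cm=round(canopy_height(heights, top_fraction), 1),
        median_canopy_height_cm=round(canopy_height(heights, median_fraction), 1),
        coverage_pixels=int(heights.size),
        coverage_area_mm2=area,
        clamped_below_ground=clamped,
        meta=dict(meta or {}),
    )
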