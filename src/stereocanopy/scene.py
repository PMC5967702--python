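"""Synthetic canopy scenes with exact ground truth, rendered as stereo pairs.

A scene is a 2.5-D height field over a plot: an undulating ground surface
(sinusoidal furrows), patches of leaf canopy covering a configurable
fraction of the plot, heights drawn from a named distribution family, and
optionally a sparse "spike" layer protruding above the main canopy the way
wheat heads do near heading.  The scene knows its own truth — per-pixel
height, per-pixel disparity under the rig, and plant/ground/spike masks — so
every downstream stage (calibration, matching, trait extraction) can be
scored against exact answers.

Rendering is orthographic-texture plus disparity warp: the left view is the
textured height field seen from above, and the right view is the left view
resampled along rows by the true per-pixel disparity (computed from the rig
geometry), with occluded columns filled from the warped ground layer and
flagged.  No ray tracing; the point is to exercise the matching and the
metric conversions, not photorealism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import ndtr

from .geometry import CameraRig

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "StereoPair",
    "default_rig",
    "generate_scene",
    "render_stereo_pair",
    "write_fixture",
    "load_fixture",
]

#: Horizontal supersampling factor used when splatting the right view, so
#: fractional disparities are honoured to 1/8 px before downsampling.
_UPSAMPLE = 8


def default_rig(ground_disparity: float = 40.0) -> CameraRig:
    """The field rig (f=18 mm, G=20 cm, H=190 cm) with the pixel pitch set
    so the ground plane sits at ``ground_disparity`` pixels.

    At the default 40 px the ground footprint is 5 mm/pixel, so a 640x480
    frame spans a 3.2 m x 2.4 m plot — the scale of a field plot imaged by
    the wagon-mounted rig.
    """
    f, G, H = 18.0, 200.0, 1900.0
    return CameraRig(f, G, H, f * G / (H * ground_disparity))


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to generate a scene deterministically."""

    rig: CameraRig = field(default_factory=default_rig)
    shape: tuple = (480, 640)  # (rows, cols)
    coverage: float = 0.6  # fraction of the plot covered by canopy
    canopy_mode_mm: float = 400.0  # modal canopy height
    canopy_spread_mm: float = 80.0  # spread of the unimodal height family
    canopy_family: str = "normal"  # "normal" | "slab"
    furrow_amplitude_mm: float = 0.0  # ground undulation half-range
    furrow_period_mm: float = 400.0
    patch_scale_px: float = 10.0  # canopy patch (coverage blob) length scale
    canopy_smoothness_px: float = 12.0  # height-field correlation length
    spike_fraction: float = 0.0  # fraction of plant pixels carrying spikes
    spike_offset_mm: float = 150.0  # spike height above the local canopy
    texture_strength: float = 0.25  # high-frequency pattern contrast (0-1)
    distortion: object | None = None  # DistortionModel, applied to both views
    vibration_px: float = 0.0  # constant disparity offset (rig vibration)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if not 0.0 <= self.spike_fraction < 1.0:
            raise ValueError("spike_fraction must lie in [0, 1)")
        H = self.rig.camera_height
        top = self.canopy_mode_mm + (self.spike_offset_mm if self.spike_fraction else 0)
        if not 0 <= self.canopy_mode_mm < H or top >= H:
            raise ValueError("canopy heights must lie in [0, camera_height)")
        if self.shape[0] < 8 or self.shape[1] < 8:
            raise ValueError("degenerate scene extent")
        if self.canopy_family not in ("normal", "slab"):
            raise ValueError(f"unknown canopy height family {self.canopy_family!r}")

    def to_dict(self) -> dict:
        d = {
            "rig": self.rig.to_dict(),
            "shape": list(self.shape),
            "coverage": self.coverage,
            "canopy_mode_mm": self.canopy_mode_mm,
            "canopy_spread_mm": self.canopy_spread_mm,
            "canopy_family": self.canopy_family,
            "furrow_amplitude_mm": self.furrow_amplitude_mm,
            "furrow_period_mm": self.furrow_period_mm,
            "spike_fraction": self.spike_fraction,
            "spike_offset_mm": self.spike_offset_mm,
            "texture_strength": self.texture_strength,
            "vibration_px": self.vibration_px,
            "seed": self.seed,
        }
        if self.distortion is not None:
            d["distortion"] = self.distortion.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        rig = CameraRig.from_dict(d.pop("rig"))
        dist = d.pop("distortion", None)
        if dist is not None:
            from .calibration import DistortionModel

            dist = DistortionModel.from_dict(dist)
        d["shape"] = tuple(d["shape"])
        return cls(rig=rig, distortion=dist, **d)


@dataclass
class SceneTruth:
    """Exact per-pixel ground truth on the left-view grid."""

    height_mm: np.ndarray  # true height above the flat ground reference
    disparity_px: np.ndarray  # true disparity incl. any vibration offset
    plant_mask: np.ndarray
    ground_mask: np.ndarray
    spike_mask: np.ndarray
    ground_disparity_px: float  # mean ground-level disparity incl. vibration
    spec: SceneSpec | None = None

    def __post_init__(self) -> None:
        overlap = self.plant_mask & self.ground_mask
        if overlap.any() or (self.spike_mask & ~self.plant_mask).any():
            raise ValueError("masks must be disjoint (spikes within plants)")
        if not (self.plant_mask | self.ground_mask).all():
            raise ValueError("plant and ground masks must cover the frame")


@dataclass
class StereoPair:
    """A left/right image pair, uint8 RGB, plus bookkeeping flags."""

    left: np.ndarray
    right: np.ndarray
    rectified: bool = False
    occlusion_mask: np.ndarray | None = None  # right-view pixels with no left match
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.left.shape != self.right.shape:
            raise ValueError("stereo images must share a shape")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Band-limited Gaussian random field, zero mean, unit variance."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (f - f.mean()) / max(f.std(), 1e-12)


def generate_scene(spec: SceneSpec) -> SceneTruth:
    """Build the exact height field and truth maps for a scene spec.

    Deterministic given ``spec.seed``.  Canopy heights are a smooth random
    field pushed through the target family's quantile function, so the
    marginal distribution matches the family while staying spatially
    coherent (essential for stereo matching to have support regions).
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    rig = spec.rig

    # undulating ground: furrows run along image rows
    y_mm = np.arange(rows)[:, None] * rig.ground_footprint
    ground = spec.furrow_amplitude_mm * np.sin(2 * np.pi * y_mm / spec.furrow_period_mm)
    ground = np.broadcast_to(ground, (rows, cols)).copy()

    # coherent canopy patches hitting the coverage fraction exactly
    if spec.coverage >= 1.0:
        plant = np.ones((rows, cols), dtype=bool)
    elif spec.coverage <= 0.0:
        plant = np.zeros((rows, cols), dtype=bool)
    else:
        blob = _smooth_field(rng, (rows, cols), sigma=spec.patch_scale_px)
        thr = np.quantile(blob, 1.0 - spec.coverage)
        plant = blob > thr

    height = ground.copy()
    if plant.any():
        if spec.canopy_family == "slab":
            canopy = np.full((rows, cols), spec.canopy_mode_mm)
        else:
            g = _smooth_field(rng, (rows, cols), sigma=spec.canopy_smoothness_px)
            # Gaussian copula: smooth field -> uniform -> target quantiles
            u = ndtr(g)
            canopy = spec.canopy_mode_mm + spec.canopy_spread_mm * _norm_ppf(u)
            canopy = np.clip(canopy, 0.0, rig.camera_height - 1.0)
        height[plant] = canopy[plant]

    spike = np.zeros((rows, cols), dtype=bool)
    if spec.spike_fraction > 0 and plant.any():
        idx = np.flatnonzero(plant)
        n_spike = int(round(spec.spike_fraction * idx.size))
        chosen = rng.choice(idx, size=n_spike, replace=False)
        spike.ravel()[chosen] = True
        height[spike] += spec.spike_offset_mm

    np.clip(height, None, rig.camera_height - 1.0, out=height)
    depth = rig.camera_height - height
    disparity = rig.focal_length * rig.baseline / (depth * rig.pixel_pitch)
    disparity += spec.vibration_px

    d_ground = rig.ground_disparity + spec.vibration_px
    return SceneTruth(
        height_mm=height,
        disparity_px=disparity,
        plant_mask=plant,
        ground_mask=~plant,
        spike_mask=spike,
        ground_disparity_px=float(d_ground),
        spec=spec,
    )


def _norm_ppf(u: np.ndarray) -> np.ndarray:
    from scipy.special import ndtri

    return ndtri(np.clip(u, 1e-9, 1 - 1e-9))


def _textures(spec: SceneSpec, truth: SceneTruth, rng: np.random.Generator):
    """Left-view RGB texture and a ground-only texture (float 0-255)."""
    rows, cols = spec.shape
    soil = np.array([132.0, 102.0, 70.0])
    leaf = np.array([58.0, 138.0, 52.0])
    base = np.where(truth.plant_mask[..., None], leaf, soil)
    # band-limited pattern so block matching is well-posed
    fine = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), 0.8, mode="wrap")
    fine = fine / max(np.abs(fine).max(), 1e-12)
    mod = 1.0 + spec.texture_strength * fine[..., None]
    tex = np.clip(base * mod, 0, 255)
    # the disoccluded ground behind canopy edges carries its own pattern;
    # sharing the canopy pattern would let occluded pixels fake a match
    fine2 = ndimage.gaussian_filter(rng.standard_normal(fine.shape), 0.8, mode="wrap")
    fine2 = fine2 / max(np.abs(fine2).max(), 1e-12)
    ground_tex = np.clip(soil * (1.0 + spec.texture_strength * fine2[..., None]), 0, 255)
    return tex, ground_tex


def render_stereo_pair(truth: SceneTruth, spec: SceneSpec | None = None) -> StereoPair:
    """Render the left/right views of a scene.

    The right view is the left texture forward-splatted along rows by the
    true disparity at 1/8-px resolution, nearer surfaces overwriting farther
    ones; columns no surface lands on are occlusions, filled from the
    ground layer warped by the local ground disparity and flagged in the
    occlusion mask.  Optional radial distortion is applied to both views
    last, as the lens would.
    """
    spec = spec or truth.spec
    if spec is None:
        raise ValueError("no SceneSpec available for rendering")
    rows, cols = spec.shape
    rng = np.random.default_rng(spec.seed + 1)
    left, ground_tex = _textures(spec, truth, rng)

    disp = truth.disparity_px
    up = _UPSAMPLE
    fine_cols = cols * up
    x_fine = np.arange(fine_cols)
    g_shift = int(round(truth.ground_disparity_px * up))

    right = np.zeros_like(left)
    occl = np.zeros((rows, cols), dtype=bool)
    max_span = 4 * up  # surface stretching beyond this is a disocclusion
    for y in range(rows):
        tex_fine = np.repeat(left[y], up, axis=0)  # (fine_cols, 3)
        d_fine = np.repeat(disp[y], up)
        t = x_fine - np.round(d_fine * up).astype(np.int64)
        # span fill: each source covers the run up to its neighbour's target,
        # so smoothly stretched surfaces stay gap-free
        spans = np.clip(np.diff(t, append=t[-1] + 1), 1, max_span)
        src = np.repeat(np.arange(fine_cols), spans)
        pos = np.repeat(t, spans) + np.arange(spans.sum()) - np.repeat(
            np.cumsum(spans) - spans, spans
        )
        ok = (pos >= 0) & (pos < fine_cols)
        src, pos = src[ok], pos[ok]
        # z-buffer: at contested targets the nearest surface (max d) wins
        pri = np.full(fine_cols, -np.inf)
        np.maximum.at(pri, pos, d_fine[src])
        win = d_fine[src] >= pri[pos]
        buf = np.zeros((fine_cols, 3))
        hit = np.zeros(fine_cols, dtype=bool)
        buf[pos[win]] = tex_fine[src[win]]
        hit[pos[win]] = True
        # occlusion fill: ground texture shifted by the ground disparity
        fill = np.repeat(ground_tex[y], up, axis=0)[
            np.clip(x_fine + g_shift, 0, fine_cols - 1)
        ]
        buf[~hit] = fill[~hit]
        right[y] = buf.reshape(cols, up, 3).mean(axis=1)
        occl[y] = (~hit).reshape(cols, up).any(axis=1)

    pair = StereoPair(
        left=np.clip(left, 0, 255).astype(np.uint8),
        right=np.clip(right, 0, 255).astype(np.uint8),
        rectified=spec.distortion is None,
        occlusion_mask=occl,
        meta={"seed": spec.seed, "vibration_px": spec.vibration_px},
    )
    if spec.distortion is not None:
        pair = replace_images_with_distorted(pair, spec.distortion)
    return pair


def replace_images_with_distorted(pair: StereoPair, model) -> StereoPair:
    """Apply a radial lens model to both views (the 'captured' images)."""
    return StereoPair(
        left=model.apply_to_image(pair.left),
        right=model.apply_to_image(pair.right),
        rectified=False,
        occlusion_mask=pair.occlusion_mask,
        meta={**pair.meta, "distorted": True},
    )


def write_fixture(truth: SceneTruth, pair: StereoPair, path: str | Path) -> None:
    """Write a scene to disk: PNG views, float TIFF truth maps, JSON sidecar."""
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path / "left.png", pair.left)
    iio.imwrite(path / "right.png", pair.right)
    tifffile.imwrite(path / "truth_height.tif", truth.height_mm.astype(np.float64))
    tifffile.imwrite(path / "truth_disparity.tif", truth.disparity_px.astype(np.float64))
    masks = (
        truth.plant_mask.astype(np.uint8)
        + 2 * truth.spike_mask.astype(np.uint8)
    )
    tifffile.imwrite(path / "masks.tif", masks)
    if pair.occlusion_mask is not None:
        tifffile.imwrite(path / "occlusion.tif", pair.occlusion_mask.astype(np.uint8))
    sidecar = {
        "spec": truth.spec.to_dict() if truth.spec else None,
        "ground_disparity_px": truth.ground_disparity_px,
    }
    (path / "scene.json").write_text(json.dumps(sidecar, indent=2))


def load_fixture(path: str | Path) -> tuple[SceneTruth, StereoPair]:
    """Round-trip counterpart of :func:`write_fixture`."""
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    sidecar_file = path / "scene.json"
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing scene sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    spec = SceneSpec.from_dict(sidecar["spec"]) if sidecar.get("spec") else None
    height = tifffile.imread(path / "truth_height.tif").astype(np.float64)
    disparity = tifffile.imread(path / "truth_disparity.tif").astype(np.float64)
    masks = tifffile.imread(path / "masks.tif")
    plant = masks % 2 == 1
    spike = masks >= 2
    occl_file = path / "occlusion.tif"
    occl = tifffile.imread(occl_file).astype(bool) if occl_file.exists() else None
    truth = SceneTruth(
        height_mm=height,
        disparity_px=disparity,
        plant_mask=plant,
        ground_mask=~plant,
        spike_mask=spike,
        ground_disparity_px=float(sidecar["ground_disparity_px"]),
        spec=spec,
    )
    pair = StereoPair(
        left=iio.imread(path / "left.png"),
        right=iio.imread(path / "right.png"),
        rectified=spec.distortion is None if spec else True,
        occlusion_mask=occl,
        meta={"seed": spec.seed} if spec else {},
    )
    return truth, pair
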