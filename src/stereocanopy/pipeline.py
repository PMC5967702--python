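"""Batch orchestration: image pairs in, trait tables and histograms out.

A run executes, per plot record: (optional) self-calibration from a
flat-ground pair, rectification, semi-global matching, vegetation
segmentation, ground-disparity estimation, height mapping and trait
extraction.  Failures are logged and skipped; they never abort the batch.
When reference heights (e.g. manual ruler measurements) accompany the
records, the run reports the origin-constrained regression ``y = alpha*x``
of estimated against reference height together with ``R^2`` and the
residual standard deviation, the standard accuracy summary for canopy
height pipelines.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import DistortionModel, rectify, self_calibrate
from .geometry import CameraRig
from .matching import (
    compute_disparity,
    disparity_search_range,
    estimate_ground_disparity,
    height_map,
)
from .scene import StereoPair
from .traits import (
    CanopyTraits,
    HeightHistogram,
    central_roi,
    extract_traits,
    height_histogram,
    normalize_histogram,
    segment_plant_pixels,
)

__all__ = [
    "PlotRecord",
    "PipelineConfig",
    "process_pair",
    "run",
    "fit_through_origin",
    "compare_distributions",
]

log = logging.getLogger("stereocanopy")


@dataclass
class PlotRecord:
    """One plot/date capture and, after processing, its extracted traits."""

    plot_id: str
    date: str
    left: str | Path = ""
    right: str | Path = ""
    variety: str = ""
    treatment: str = ""
    manual_height_cm: float | None = None
    traits: CanopyTraits | None = None


@dataclass
class PipelineConfig:
    rig: CameraRig
    records: list = field(default_factory=list)
    distortion_model: DistortionModel | None = None
    flat_ground: tuple | None = None  # (left_path, right_path) for self-calibration
    roi_fraction: float = 0.8
    p1: float = 8.0
    p2: float = 96.0
    h_min_mm: float = -50.0
    h_max_mm: float = 1500.0
    bin_width_cm: float = 1.0
    canopy_top_fraction: float = 0.02
    median_top_fraction: float = 0.50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping, base: Path | None = None) -> "PipelineConfig":
        if "rig" not in raw or "records" not in raw:
            raise ValueError("pipeline config must define 'rig' and 'records'")
        rig = CameraRig.from_dict(raw["rig"])
        base = base or Path(".")
        records = []
        for r in raw["records"]:
            try:
                records.append(
                    PlotRecord(
                        plot_id=str(r["plot_id"]),
                        date=str(r["date"]),
                        left=base / r["left"],
                        right=base / r["right"],
                        variety=str(r.get("variety", "")),
                        treatment=str(r.get("treatment", "")),
                        manual_height_cm=r.get("manual_height_cm"),
                    )
                )
            except KeyError as e:
                raise ValueError(f"record missing required key: {e}") from e
        keys = [(rec.plot_id, rec.date) for rec in records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (plot_id, date) in records")
        model = None
        if raw.get("distortion_model"):
            model = DistortionModel.from_dict(
                json.loads((base / raw["distortion_model"]).read_text())
            )
        flat = None
        if raw.get("calibration"):
            flat = (base / raw["calibration"]["left"], base / raw["calibration"]["right"])
        opts = raw.get("options", {})
        return cls(
            rig=rig,
            records=records,
            distortion_model=model,
            flat_ground=flat,
            roi_fraction=float(opts.get("roi_fraction", 0.8)),
            p1=float(opts.get("p1", 8.0)),
            p2=float(opts.get("p2", 96.0)),
            h_min_mm=float(opts.get("h_min_mm", -50.0)),
            h_max_mm=float(opts.get("h_max_mm", 1500.0)),
            bin_width_cm=float(opts.get("bin_width_cm", 1.0)),
            canopy_top_fraction=float(opts.get("canopy_top_fraction", 0.02)),
            median_top_fraction=float(opts.get("median_top_fraction", 0.50)),
            seed=int(opts.get("seed", 0)),
        )


def process_pair(
    pair: StereoPair,
    rig: CameraRig,
    model: DistortionModel | None = None,
    cfg: PipelineConfig | None = None,
    plant_mask: np.ndarray | None = None,
    skip_rectification: bool = False,
):
    """Run matching + trait extraction on one stereo pair.

    Returns ``(traits, pixel_hist, area_hist, hmap, dmap)``.  The plant
    mask defaults to excess-green segmentation of the left view; its
    complement inside the region of interest provides the ground pixels
    for the ground-disparity estimate.
    """
    cfg = cfg or PipelineConfig(rig=rig)
    if skip_rectification or (pair.rectified and (model is None or model.is_identity)):
        rect = pair
    else:
        rect, _ = rectify(pair, model, seed=cfg.seed)
    d_range = disparity_search_range(rig, cfg.h_min_mm, cfg.h_max_mm)
    dmap = compute_disparity(rect, rig, d_range, P1=cfg.p1, P2=cfg.p2)
    if plant_mask is None:
        plant_mask = segment_plant_pixels(rect.left)
    roi = central_roi(rect.left.shape, cfg.roi_fraction)
    estimate_ground_disparity(dmap, ground_mask=~plant_mask & roi, rig=rig)
    hmap = height_map(dmap, rig)
    sel = plant_mask & roi
    traits = extract_traits(
        hmap.height_mm,
        sel,
        rig,
        valid=hmap.valid,
        top_fraction=cfg.canopy_top_fraction,
        median_fraction=cfg.median_top_fraction,
    )
    traits.clamped_below_ground += hmap.clamped_below_ground
    hist = height_histogram(hmap.height_mm, sel, cfg.bin_width_cm, valid=hmap.valid)
    hist_area = normalize_histogram(hmap.height_mm, sel, rig, cfg.bin_width_cm, valid=hmap.valid)
    return traits, hist, hist_area, hmap, dmap


def fit_through_origin(x, y) -> dict:
    """Least squares through the origin, ``y = alpha * x``.

    ``alpha = sum(x*y)/sum(x^2)``; ``R^2`` is computed against the
    origin-constrained fit, ``1 - SS_res / SS_tot`` with ``SS_tot`` about
    the mean of ``y``; the residual SD uses ``ddof=1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two same-length vectors with >= 2 points")
    alpha = float(np.sum(x * y) / np.sum(x * x))
    resid = y - alpha * x
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return {
        "alpha": alpha,
        "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
        "residual_sd_cm": float(np.std(resid, ddof=1)),
        "n": int(x.size),
    }


def compare_distributions(
    groups: Mapping[str, Sequence[HeightHistogram]],
) -> pd.DataFrame:
    """Per-bin replicate mean and min-max range for each labelled group.

    All histograms must share bin width and aligned edges; shorter
    histograms are zero-padded to the longest.  With three replicates the
    min-max range is the honest dispersion measure (error bars across
    repeats), so that is what is reported.
    """
    widths = {round(h.bin_width, 9) for hs in groups.values() for h in hs}
    if len(widths) != 1:
        raise ValueError(f"histograms have mismatched bin widths: {sorted(widths)}")
    starts = {float(h.bin_edges[0]) for hs in groups.values() for h in hs}
    if len(starts) != 1:
        raise ValueError("histograms have mismatched bin origins")
    n_bins = max(h.weights.size for hs in groups.values() for h in hs)
    width = widths.pop()
    start = starts.pop()
    rows = []
    for label, hists in groups.items():
        if len(hists) == 0:
            raise ValueError(f"group {label!r} has no histograms")
        stack = np.zeros((len(hists), n_bins))
        for i, h in enumerate(hists):
            stack[i, : h.weights.size] = h.weights
        for b in range(n_bins):
            rows.append(
                {
                    "group": label,
                    "bin_low_cm": start + b * width,
                    "bin_high_cm": start + (b + 1) * width,
                    "mean": stack[:, b].mean(),
                    "range": stack[:, b].max() - stack[:, b].min(),
                    "n_replicates": len(hists),
                }
            )
    return pd.DataFrame(rows)


def _load_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return iio.imread(path)


def run(config: PipelineConfig | str | Path, out_dir: str | Path | None = None):
    """Execute the pipeline over all records of a config.

    Returns ``(traits_table, histograms, report)``; optionally writes
    ``traits.csv``, ``histograms/*.csv`` and ``report.md`` under
    ``out_dir``.  Per-record failures are logged and skipped.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    model = config.distortion_model
    if model is None and config.flat_ground is not None:
        t0 = time.perf_counter()
        flat_pair = StereoPair(
            left=_load_image(config.flat_ground[0]),
            right=_load_image(config.flat_ground[1]),
        )
        model = self_calibrate(flat_pair, config.rig, seed=config.seed)
        log.info("self-calibration: k1=%.4f k2=%.4f (%.1fs)", model.k1, model.k2,
                 time.perf_counter() - t0)

    rows: list[dict] = []
    histograms: dict[str, dict[str, HeightHistogram]] = {}
    failures: list[str] = []
    for rec in config.records:
        key = f"{rec.plot_id}_{rec.date}"
        t0 = time.perf_counter()
        try:
            pair = StereoPair(left=_load_image(rec.left), right=_load_image(rec.right))
            pair.rectified = model is None or model.is_identity
            traits, hist, hist_area, _, dmap = process_pair(
                pair, config.rig, model=model, cfg=config
            )
        except Exception as e:  # noqa: BLE001 - batch must continue
            log.warning("record %s failed: %s", key, e)
            failures.append(f"{key}: {e}")
            continue
        rec.traits = traits
        histograms[key] = {"pixels": hist, "area_mm2": hist_area}
        rows.append(
            {
                "plot_id": rec.plot_id,
                "date": rec.date,
                "variety": rec.variety,
                "treatment": rec.treatment,
                "canopy_height_cm": traits.canopy_height_cm,
                "median_canopy_height_cm": traits.median_canopy_height_cm,
                "coverage_pixels": traits.coverage_pixels,
                "coverage_area_mm2": traits.coverage_area_mm2,
                "clamped_below_ground": traits.clamped_below_ground,
                "ground_disparity_px": dmap.d_g,
                "manual_height_cm": rec.manual_height_cm,
            }
        )
        log.info("record %s done in %.1fs", key, time.perf_counter() - t0)

    table = pd.DataFrame(rows)
    report_lines = [
        "# stereocanopy run report",
        "",
        f"- records processed: {len(rows)} / {len(config.records)}",
        f"- failures: {len(failures)}",
    ]
    report_lines += [f"  - {f}" for f in failures]
    if len(rows) == 0:
        log.warning("empty batch: no records processed")
    ref = table.dropna(subset=["manual_height_cm"]) if len(rows) else table
    if len(ref) >= 2:
        fit = fit_through_origin(ref["manual_height_cm"], ref["canopy_height_cm"])
        report_lines += [
            "",
            "## Comparison with reference heights (least squares through origin,",
            "## y = alpha*x; R^2 against the origin-constrained fit)",
            f"- alpha: {fit['alpha']:.4f}",
            f"- R2: {fit['r2']:.4f}",
            f"- residual SD: {fit['residual_sd_cm']:.2f} cm",
            f"- n: {fit['n']}",
        ]
    report = "\n".join(report_lines) + "\n"

    if out_dir is not None:
        out = Path(out_dir)
        (out / "histograms").mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "traits.csv", index=False)
        for key, hs in histograms.items():
            df = pd.DataFrame(
                {
                    "bin_low_cm": hs["pixels"].bin_edges[:-1],
                    "bin_high_cm": hs["pixels"].bin_edges[1:],
                    "pixel_count": hs["pixels"].weights,
                }
            )
            area = np.zeros(len(df))
            aw = hs["area_mm2"].weights
            area[: aw.size] = aw[: len(df)]
            df["area_mm2"] = area
            df.to_csv(out / "histograms" / f"{key}.csv", index=False)
        (out / "report.md").write_text(report)
    return table, histograms, report
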