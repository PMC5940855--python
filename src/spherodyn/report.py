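"""Quality-control overlays and summary figures.

Overlay frames show the 1-px segmentation boundary over the
contrast-stretched intensity image with an "HH:MM" timestamp, so a user can
flip through (or watch the optional GIF) and judge segmentation quality at
a glance. Summary figures plot per-condition mean feature trajectories with
shaded confidence bands, and per-replicate fitted model curves.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from scipy import ndimage as ndi

from .dynamics import ModelFit, aggregate_replicates

log = logging.getLogger(__name__)

#: the six headline features shown in the multi-panel summary figure.
SUMMARY_FEATURES = [
    ("branch_count", "branch number"),
    ("invasive_radius_px", "invasive radius (px)"),
    ("core_radius_px", "core radius (px)"),
    ("area_px2", "area (px$^2$)"),
    ("perimeter_px", "perimeter (px)"),
    ("complexity", "complexity"),
]

_MODEL_STYLES = {"linear": "-.", "quadratic": ":", "exponential": "--"}


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Inner morphological boundary: mask minus its erosion."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros_like(mask)
    eroded = ndi.binary_erosion(mask, structure=np.ones((3, 3), bool))
    return mask & ~eroded


def _stretch(frame: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        return np.zeros_like(frame, dtype=np.uint8)
    return (np.clip((frame - lo) / (hi - lo), 0, 1) * 255).astype(np.uint8)


def export_overlay_sequence(
    masks: np.ndarray,
    intensities: np.ndarray,
    out_dir: str | Path,
    frame_interval: float = 10.0,
    make_gif: bool = False,
) -> List[Path]:
    """Write one timestamped boundary-overlay PNG per frame.

    Contrast limits are the 2nd/98th intensity percentiles of the whole
    sequence so brightness is comparable across frames. Frames with empty
    masks get a timestamp but no contour (and a warning).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo, hi = np.percentile(intensities, [2, 98])
    paths = []
    for k in range(masks.shape[0]):
        gray = _stretch(intensities[k], lo, hi)
        rgb = np.stack([gray] * 3, axis=-1)
        boundary = mask_boundary(masks[k])
        if boundary.any():
            rgb[boundary] = (255, 255, 0)
        else:
            log.warning("frame %d: empty mask, overlay has no contour", k)
        img = Image.fromarray(rgb)
        minutes = int(round(k * frame_interval))
        stamp = f"{minutes // 60:02d}:{minutes % 60:02d}"
        ImageDraw.Draw(img).text((4, 4), stamp, fill=(255, 255, 255))
        p = out_dir / f"overlay_{k:04d}.png"
        img.save(p)
        paths.append(p)
    if make_gif:
        import imageio.v3 as iio

        frames = [iio.imread(p) for p in paths]
        iio.imwrite(out_dir / "overlay.gif", frames, duration=100, loop=0)
    return paths


def plot_condition_features(
    series_by_condition: Dict[str, Sequence[pd.DataFrame]],
    out_dir: str | Path,
    ci_level: float = 0.95,
) -> List[Path]:
    """Multi-panel mean +/- CI figure plus one single panel per feature."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, axes = plt.subplots(2, 3, figsize=(13, 7))
    for ax, (feat, label) in zip(axes.ravel(), SUMMARY_FEATURES):
        _draw_panel(ax, series_by_condition, feat, label, ci_level)
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    p = out_dir / "features_summary.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    for feat, label in SUMMARY_FEATURES:
        fig, ax = plt.subplots(figsize=(5, 4))
        _draw_panel(ax, series_by_condition, feat, label, ci_level)
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = out_dir / f"feature_{feat}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written


def _draw_panel(ax, series_by_condition, feature, label, ci_level) -> None:
    any_data = False
    for cond in sorted(series_by_condition):
        reps = series_by_condition[cond]
        if not reps:
            continue
        agg = aggregate_replicates(list(reps), feature, ci_level)
        if not len(agg):
            continue
        any_data = True
        (line,) = ax.plot(agg["time_hours"], agg["mean"], label=cond)
        ax.fill_between(
            agg["time_hours"], agg["ci_low"], agg["ci_high"],
            alpha=0.25, color=line.get_color(),
        )
    if not any_data:
        ax.annotate("no data", (0.5, 0.5), xycoords="axes fraction", ha="center")
    ax.set_xlabel("time (h)")
    ax.set_ylabel(label)


def plot_model_fits(
    series: pd.DataFrame,
    fits: Sequence[ModelFit],
    feature: str,
    out_path: str | Path,
    label: Optional[str] = None,
) -> Path:
    """One replicate's data points with all fitted model curves overlaid."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    t = series["time_hours"].to_numpy()
    y = series[feature].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(t, y, "x", color="k", ms=4, label="data")
    tt = np.linspace(np.nanmin(t), np.nanmax(t), 200)
    for fit in fits:
        ax.plot(
            tt,
            fit.predict(tt),
            _MODEL_STYLES.get(fit.model, "-"),
            label=f"{fit.model} (adj $R^2$={fit.adj_r2:.3f})",
        )
    ax.set_xlabel("time (h)")
    ax.set_ylabel(label or feature)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
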