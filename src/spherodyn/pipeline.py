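"""End-to-end pipeline: discover -> read -> project -> smooth -> segment ->
features -> fit -> select -> compare -> report.

Each replicate is processed independently; a failure in one replicate is
logged and skipped so the run continues. All randomness is confined to the
synthetic generator — the analysis itself is deterministic, and repeated
runs with the same configuration produce byte-identical CSVs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import RunConfig
from .dynamics import (
    MODEL_KINDS,
    ModelFit,
    compare_all,
    fit_all_models,
    select_best_model,
)
from .io_experiment import (
    ExperimentIOError,
    ReplicateSource,
    check_writable,
    discover_experiment,
    read_sequence,
    write_feature_csv,
    write_model_csv,
    write_outputs,
    write_params_csv,
    write_stats_csv,
)
from .morphometry import MorphometryConfig, build_feature_series
from .preprocess import SmoothingConfig, gaussian_smooth_xyt, std_projection
from .report import plot_condition_features, plot_model_fits
from .segmentation import GraphCutConfig, estimate_unary, graphcut_segment
from .synthetic import FEATURE_COLUMNS

log = logging.getLogger(__name__)

#: feature columns that get model fits (identity and time columns excluded).
MODELED_FEATURES = [c for c in FEATURE_COLUMNS if c not in ("replicate", "frame", "time_hours")]


@dataclass
class ReplicateResult:
    replicate: ReplicateSource
    masks: np.ndarray
    features: pd.DataFrame
    fits: List[ModelFit] = field(default_factory=list)


@dataclass
class PipelineResult:
    status: int
    output_root: Optional[Path]
    replicates: List[ReplicateResult] = field(default_factory=list)
    fits_df: Optional[pd.DataFrame] = None
    best_models: Optional[Dict[str, str]] = None
    stats_df: Optional[pd.DataFrame] = None


def segment_sequence(data: np.ndarray, config: RunConfig):
    """Project, smooth and segment one (t, z, rows, cols) stack.

    Returns (masks, projected) — the projected pre-smoothing volume is kept
    for intensity measurements and overlays.
    """
    projected = std_projection(data)
    smoothed = gaussian_smooth_xyt(
        projected, SmoothingConfig(config.sigma_xy, config.sigma_t)
    )
    # class statistics come from the un-smoothed projection: boundary and
    # thin-branch pixels are mixtures after blurring, which would bias the
    # fitted class means; the costs themselves are evaluated on the
    # smoothed volume that is being cut.
    model = estimate_unary(projected)
    masks = graphcut_segment(
        smoothed,
        GraphCutConfig(
            lambda_spatial=config.lambda_spatial,
            lambda_temporal=config.lambda_temporal,
            contrast_sigma=config.contrast_sigma,
            mode=config.mode,
            fill_holes=config.fill_holes,
            min_object_area=config.min_object_area,
        ),
        model=model,
    )
    return masks, projected


def analyze_replicate(rep: ReplicateSource, config: RunConfig) -> ReplicateResult:
    t0 = time.perf_counter()
    seq = read_sequence(
        rep.source, config.frame_interval, config.z_planes,
        origin=f"{rep.condition}/{rep.name}",
    )
    masks, projected = segment_sequence(seq.data, config)
    features = build_feature_series(
        masks,
        projected,
        config.frame_interval,
        origin=f"{rep.condition}/{rep.name}",
        config=MorphometryConfig(
            prune_length=config.prune_length,
            single_cell_min_area=config.single_cell_min_area,
            single_cell_max_area=config.single_cell_max_area,
            enclosing_mode=config.enclosing_mode,
        ),
    )
    log.info(
        "replicate %s/%s: %d frames analyzed in %.1f s",
        rep.condition, rep.name, masks.shape[0], time.perf_counter() - t0,
    )
    result = ReplicateResult(replicate=rep, masks=masks, features=features)
    result._projected = projected  # kept for overlays
    return result


def fit_replicate_models(
    features: pd.DataFrame, config: RunConfig, origin: str
) -> List[ModelFit]:
    fits = []
    t = features["time_hours"]
    for feat in MODELED_FEATURES:
        fits.extend(
            fit_all_models(t, features[feat], config.models, feature=feat, origin=origin)
        )
    return fits


def fits_to_frame(
    fits: List[ModelFit], condition: str, replicate: str
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": condition,
                "replicate": replicate,
                "feature": f.feature,
                "model": f.model,
                "a": f.a,
                "b": f.b,
                "c": f.c if f.c is not None else float("nan"),
                "adj_r2": f.adj_r2,
            }
            for f in fits
        ]
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis for a discovered experiment."""
    if not config.input_root or not config.output_root:
        raise ExperimentIOError("config must set input_root and output_root")
    layout = discover_experiment(config.input_root, config.z_planes)
    out_root = check_writable(config.output_root)

    results: List[ReplicateResult] = []
    fit_frames: List[pd.DataFrame] = []
    series_by_condition: Dict[str, List[pd.DataFrame]] = {}
    for cond, reps in layout.conditions:
        for rep in reps:
            try:
                res = analyze_replicate(rep, config)
            except Exception:
                log.exception(
                    "replicate %s/%s failed; continuing", rep.condition, rep.name
                )
                continue
            res.fits = fit_replicate_models(
                res.features, config, origin=f"{cond}/{rep.name}"
            )
            write_outputs(
                rep, res.masks, res.features, out_root,
                params=config.to_dict(), intensities=res._projected,
            )
            for fit in res.fits:
                plot_model_fits(
                    res.features,
                    [f for f in res.fits if f.feature == fit.feature],
                    fit.feature,
                    out_root / cond / rep.name / "fits" / f"{fit.feature}.png",
                )
            fit_frames.append(fits_to_frame(res.fits, cond, rep.name))
            series_by_condition.setdefault(cond, []).append(res.features)
            results.append(res)

    if not results:
        raise ExperimentIOError("every replicate failed; no outputs written")

    fits_df = pd.concat(fit_frames, ignore_index=True)

    # condition-mean series are modeled too (statistics use per-replicate fits)
    mean_fit_frames = []
    for cond, series in sorted(series_by_condition.items()):
        mean_series = _mean_series(series)
        fits = fit_replicate_models(mean_series, config, origin=f"{cond}/mean")
        mean_fit_frames.append(fits_to_frame(fits, cond, "mean"))
    all_fits_df = pd.concat([fits_df] + mean_fit_frames, ignore_index=True)
    write_model_csv(all_fits_df, out_root / "models.csv")

    best: Dict[str, Optional[str]] = {}
    for feat in MODELED_FEATURES:
        sub = fits_df[fits_df.feature == feat]
        best[feat] = select_best_model(
            [
                ModelFit(
                    model=r.model, a=r.a, b=r.b, c=r.c, adj_r2=r.adj_r2,
                    r2=float("nan"), n_points=0, feature=feat,
                    origin=f"{r.condition}/{r.replicate}",
                )
                for r in sub.itertuples()
            ]
        )

    stats_df = compare_all(
        fits_df, {f: m for f, m in best.items() if m},
        welch=config.welch, bh_correction=config.bh_correction,
    )
    write_stats_csv(stats_df, out_root / "stats.csv")
    write_params_csv(config.to_dict(), out_root / "parameters.csv")
    plot_condition_features(series_by_condition, out_root / "plots", config.ci_level)

    return PipelineResult(
        status=0,
        output_root=out_root,
        replicates=results,
        fits_df=all_fits_df,
        best_models={f: m for f, m in best.items() if m},
        stats_df=stats_df,
    )


def _mean_series(series: List[pd.DataFrame]) -> pd.DataFrame:
    base = series[0][["frame", "time_hours"]].copy()
    for col in MODELED_FEATURES:
        base[col] = np.nanmean(
            np.stack([s[col].to_numpy(dtype=float) for s in series]), axis=0
        )
    base["replicate"] = "mean"
    return base
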