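"""Experiment discovery, image reading and tabular/mask output.

Experiments are organized as a simple folder hierarchy::

    root/
      condition_A/
        replicate_1/            # folder of 2-D frames (TIFF/PNG/JPG), or
        replicate_2.tif         # a multi-page TIFF
      condition_B/
        ...

Conditions, replicates and frames are enumerated in sorted (lexicographic,
locale-independent) order so discovery is deterministic. Multi-page TIFFs
with more than one focal plane must declare the page layout via the
``z_planes`` config key (pages are t-major, then z); nothing is guessed.

Coordinate/time conventions used everywhere: 0-based (row, col) with row
increasing downward; boolean masks; frame k at physical time
t_k = k * frame_interval / 60 hours. CSV output uses the full double
precision repr, "." decimal separator, UTF-8 and a mandatory header, so
repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .synthetic import FEATURE_COLUMNS

log = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}

MODEL_CSV_COLUMNS = ["condition", "replicate", "feature", "model", "a", "b", "c", "adj_r2"]
STATS_CSV_COLUMNS = ["feature", "model", "parameter", "test", "statistic", "p_value"]

#: ITU-R BT.709 luminance weights (the scikit-image rgb2gray convention).
_LUMA = np.array([0.2125, 0.7154, 0.0721])


class ExperimentIOError(ValueError):
    pass


@dataclass(frozen=True)
class ReplicateSource:
    condition: str
    name: str
    source: Path  # frame folder or multi-page TIFF
    n_frames: int


@dataclass(frozen=True)
class ExperimentLayout:
    root: Path
    conditions: Tuple[Tuple[str, Tuple[ReplicateSource, ...]], ...]

    def all_replicates(self) -> List[ReplicateSource]:
        return [rep for _, reps in self.conditions for rep in reps]


@dataclass
class FrameSequence:
    """An image sequence in memory: (t, z, rows, cols) float64 data."""

    data: np.ndarray
    frame_interval: float  # minutes
    origin: str = ""
    pixel_size: Optional[float] = None

    @property
    def times_hours(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.frame_interval / 60.0


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------


def _image_files(folder: Path) -> List[Path]:
    return sorted(
        p for p in folder.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )


def _count_frames(source: Path, z_planes: int = 1) -> int:
    if source.is_dir():
        return len(_image_files(source))
    with tifffile.TiffFile(source) as tf:
        return len(tf.pages) // max(1, z_planes)


def discover_experiment(root: str | Path, z_planes: int = 1) -> ExperimentLayout:
    """Enumerate the condition/replicate hierarchy under ``root``.

    Immediate subfolders are conditions; inside each, subfolders of frames
    and multi-page TIFF files are replicates. Empty replicates are skipped
    with a warning; an experiment with no readable replicate is an error.
    """
    root = Path(root)
    if not root.is_dir():
        raise ExperimentIOError(f"experiment root does not exist: {root}")
    conditions = []
    for cond_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        reps: List[ReplicateSource] = []
        candidates = sorted(
            [p for p in cond_dir.iterdir() if p.is_dir()]
            + [p for p in cond_dir.iterdir()
               if p.is_file() and p.suffix.lower() in (".tif", ".tiff")]
        )
        for cand in candidates:
            n = _count_frames(cand, z_planes)
            if n < 2:
                log.warning("skipping replicate %s: %d frame(s)", cand, n)
                continue
            reps.append(
                ReplicateSource(
                    condition=cond_dir.name,
                    name=cand.stem if cand.is_file() else cand.name,
                    source=cand,
                    n_frames=n,
                )
            )
        if reps:
            conditions.append((cond_dir.name, tuple(reps)))
    if not conditions:
        raise ExperimentIOError(f"no readable replicates under {root}")
    return ExperimentLayout(root=root, conditions=tuple(conditions))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _to_gray(frame: np.ndarray, path: Path) -> np.ndarray:
    if frame.ndim == 2:
        return frame.astype(np.float64)
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        return frame[..., :3].astype(np.float64) @ _LUMA
    raise ExperimentIOError(f"cannot interpret image {path} with shape {frame.shape}")


def read_sequence(
    source: str | Path,
    frame_interval: float,
    z_planes: int = 1,
    origin: str = "",
) -> FrameSequence:
    """Read a replicate into a (t, z, rows, cols) float64 stack.

    Multi-page TIFFs are split t-major into ``z_planes`` focal planes per
    time point (the page count must be divisible); frame folders yield
    z = 1, with RGB frames converted to luminance. Intensities are
    converted to float without rescaling.
    """
    source = Path(source)
    if frame_interval <= 0:
        raise ExperimentIOError("frame_interval must be > 0 minutes")
    if source.is_dir():
        files = _image_files(source)
        if len(files) < 2:
            raise ExperimentIOError(f"replicate folder {source} has < 2 frames")
        frames = []
        shape = None
        for f in files:
            try:
                img = _to_gray(np.asarray(iio.imread(f)), f)
            except ExperimentIOError:
                raise
            except Exception as exc:
                raise ExperimentIOError(f"cannot decode image file {f}") from exc
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ExperimentIOError(
                    f"frame {f} has shape {img.shape}, expected {shape}"
                )
            frames.append(img)
        data = np.stack(frames)[:, None, :, :]
    else:
        try:
            pages = np.asarray(tifffile.imread(source))
        except Exception as exc:
            raise ExperimentIOError(f"cannot decode TIFF {source}") from exc
        if pages.ndim == 2:
            pages = pages[None]
        if pages.ndim != 3:
            raise ExperimentIOError(
                f"TIFF {source} has unsupported shape {pages.shape}"
            )
        n_pages = pages.shape[0]
        if z_planes < 1:
            raise ExperimentIOError("z_planes must be >= 1")
        if n_pages % z_planes != 0:
            raise ExperimentIOError(
                f"TIFF {source} has {n_pages} pages, not divisible by "
                f"z_planes = {z_planes}; declare the (t, z) layout explicitly"
            )
        data = pages.reshape(
            n_pages // z_planes, z_planes, *pages.shape[1:]
        ).astype(np.float64)
    if data.shape[0] < 2:
        raise ExperimentIOError(f"sequence {source} has < 2 time points")
    if not np.all(np.isfinite(data)) or data.min() < 0:
        raise ExperimentIOError(
            f"sequence {source} contains non-finite or negative intensities"
        )
    return FrameSequence(
        data=data,
        frame_interval=frame_interval,
        origin=origin or source.stem,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_mask_volume(masks: np.ndarray, out_dir: str | Path) -> List[Path]:
    """Write per-frame masks as 8-bit TIFF (0 background / 255 foreground)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(masks.shape[0]):
        p = out_dir / f"mask_{k:04d}.tif"
        tifffile.imwrite(p, masks[k].astype(np.uint8) * 255)
        paths.append(p)
    return paths


def read_mask_volume(mask_dir: str | Path) -> np.ndarray:
    files = sorted(Path(mask_dir).glob("mask_*.tif"))
    if not files:
        raise ExperimentIOError(f"no mask TIFFs under {mask_dir}")
    return np.stack([tifffile.imread(f) > 0 for f in files])


def write_feature_csv(features: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features[FEATURE_COLUMNS].to_csv(path, index=False, encoding="utf-8")
    return path


def write_params_csv(params: dict, path: str | Path) -> Path:
    """Echo every analysis setting as a two-column key/value CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {"parameter": list(params), "value": [repr(v) for v in params.values()]}
    )
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def write_model_csv(fits_df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fits_df[MODEL_CSV_COLUMNS].to_csv(path, index=False, encoding="utf-8")
    return path


def write_stats_csv(stats_df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = STATS_CSV_COLUMNS + (
        ["p_bh"] if "p_bh" in getattr(stats_df, "columns", []) else []
    )
    if len(stats_df) == 0:
        stats_df = pd.DataFrame(columns=cols)
    stats_df[cols].to_csv(path, index=False, encoding="utf-8")
    return path


def check_writable(out_root: str | Path) -> Path:
    """Fail fast, before any computation output would be discarded."""
    out_root = Path(out_root)
    try:
        out_root.mkdir(parents=True, exist_ok=True)
        probe = out_root / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ExperimentIOError(f"output root {out_root} is not writable") from exc
    return out_root


def write_outputs(
    replicate: ReplicateSource | str,
    masks: np.ndarray,
    features: pd.DataFrame,
    out_root: str | Path,
    params: Optional[dict] = None,
    intensities: Optional[np.ndarray] = None,
) -> dict:
    """Write one replicate's masks, overlays, feature CSV and parameter echo.

    Layout mirrors the input hierarchy: out_root/<condition>/<replicate>/.
    """
    if len(features) != masks.shape[0]:
        raise ExperimentIOError("features must be indexed by the same frames as masks")
    if isinstance(replicate, ReplicateSource):
        rep_dir = Path(out_root) / replicate.condition / replicate.name
    else:
        rep_dir = Path(out_root) / str(replicate)
    check_writable(rep_dir)
    written = {"masks": write_mask_volume(masks, rep_dir / "masks")}
    written["features"] = write_feature_csv(features, rep_dir / "features.csv")
    if params is not None:
        written["params"] = write_params_csv(params, rep_dir / "parameters.csv")
    if intensities is not None:
        from .report import export_overlay_sequence

        written["overlays"] = export_overlay_sequence(
            masks, intensities, rep_dir / "overlays",
            frame_interval=_infer_interval(features),
        )
    return written


def _infer_interval(features: pd.DataFrame) -> float:
    t = features["time_hours"].to_numpy()
    return float((t[1] - t[0]) * 60.0) if len(t) > 1 else 10.0
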