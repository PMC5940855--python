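"""Synthetic spheroid time-lapse generator with exact ground truth.

Emulates the phenotype spectrum seen in invasion assays of multicellular
tumor spheroids embedded in a 3-D matrix:

* a bright, roughly circular core growing linearly in radius,
* thin chain-like invasive branches elongating quadratically in time,
* occasional single cells detaching and migrating radially outward,
* z-dependent illumination falloff across focal planes,
* gradual photobleaching (exponential intensity decay over hours),
* additive Gaussian sensor noise.

Every stack comes with the exact rasterized truth masks and the analytic
feature series (core radius, invasive radius, branch count, single-cell
count) implied by the generating parameters, so the whole downstream
pipeline — projection, segmentation, morphometry, model fitting — can be
validated without any external data.

Geometry conventions: 0-based (row, col), row increasing downward; the
spheroid center sits at the image center ((rows-1)/2, (cols-1)/2); frame k
corresponds to physical time t_k = k * frame_interval / 60 hours.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage as ndi

#: extra radial clearance (px) inserted between the spheroid surface and a
#: freshly detached cell, so that detached cells are truly disconnected.
DETACH_GAP = 3.0

#: minimum morphological gap (px) enforced between a detached cell and the
#: main mass at every frame.
MIN_CELL_GAP = 2.0

#: intensities are clipped to this range after noise is added.
INTENSITY_RANGE = (0.0, 65535.0)

FEATURE_COLUMNS = [
    "replicate",
    "frame",
    "time_hours",
    "area_px2",
    "perimeter_px",
    "eccentricity",
    "complexity",
    "core_radius_px",
    "invasive_radius_px",
    "branch_count",
    "single_cell_count",
    "intensity_mean",
    "intensity_sd",
]


class SimulationError(ValueError):
    """Raised when simulation parameters describe invalid geometry."""


@dataclass(frozen=True)
class SingleCellEvent:
    """A cell detaching from the spheroid surface and migrating radially.

    After ``detach_time`` (hours) a disk of radius ``cell_radius`` appears at
    distance r(t) + DETACH_GAP + cell_radius from the center along
    ``direction`` and moves outward at ``speed`` px/hour.
    """

    detach_time: float
    direction: float
    speed: float
    cell_radius: float


@dataclass(frozen=True)
class SpheroidSimParams:
    """Full parameterization of one synthetic spheroid recording.

    The core radius grows linearly, r(t) = core_radius_0 +
    core_growth_rate * t; branch i elongates as l_i(t) = q*t^2 + m*t with
    (q, m) = branch_length_coeffs, measured from the core surface to the
    branch tip. Times are hours, lengths pixels.
    """

    core_radius_0: float = 10.0
    core_growth_rate: float = 3.0  # px / hour
    n_branches: int = 0
    branch_angles: Sequence[float] = field(default_factory=tuple)
    branch_length_coeffs: Tuple[float, float] = (0.0, 0.0)  # (quadratic, linear)
    branch_width: float = 4.0
    frame_interval: float = 10.0  # minutes
    n_frames: int = 30
    image_shape: Tuple[int, int] = (128, 128)
    n_z: int = 5
    illumination_profile: Optional[Sequence[float]] = None
    bleach_rate: float = 0.0  # fraction / hour
    noise_sd: float = 0.0
    fg_level: float = 200.0
    bg_level: float = 30.0
    single_cell_events: Sequence[SingleCellEvent] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_radius_0 <= 0:
            raise SimulationError("core_radius_0 must be > 0")
        if self.core_growth_rate < 0:
            raise SimulationError("core_growth_rate must be >= 0")
        if self.n_branches < 0:
            raise SimulationError("n_branches must be >= 0")
        if len(self.branch_angles) != self.n_branches:
            raise SimulationError(
                f"branch_angles has length {len(self.branch_angles)}, "
                f"expected n_branches = {self.n_branches}"
            )
        if self.branch_width <= 0:
            raise SimulationError("branch_width must be > 0")
        if self.frame_interval <= 0:
            raise SimulationError("frame_interval must be > 0 minutes")
        if self.n_frames < 2:
            raise SimulationError("n_frames must be >= 2")
        if self.n_z < 1:
            raise SimulationError("n_z must be >= 1")
        if self.bleach_rate < 0 or self.bleach_rate >= 1:
            raise SimulationError("bleach_rate must lie in [0, 1) per hour")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.fg_level <= self.bg_level:
            raise SimulationError("fg_level must exceed bg_level")
        prof = self.resolved_illumination()
        if len(prof) != self.n_z or np.any(prof <= 0) or np.any(prof > 1):
            raise SimulationError(
                "illumination_profile must have one gain per z-plane, each in (0, 1]"
            )

    # ---- derived quantities -------------------------------------------

    def times_hours(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval / 60.0

    def core_radius_at(self, t: float | np.ndarray) -> float | np.ndarray:
        return self.core_radius_0 + self.core_growth_rate * np.asarray(t, float)

    def branch_length_at(self, t: float | np.ndarray) -> float | np.ndarray:
        q, m = self.branch_length_coeffs
        t = np.asarray(t, float)
        return np.maximum(0.0, q * t * t + m * t)

    def resolved_illumination(self) -> np.ndarray:
        """Per-plane gain; default is a linear ramp 1.0 (mid) -> 0.4 (ends)."""
        if self.illumination_profile is not None:
            return np.asarray(self.illumination_profile, float)
        if self.n_z == 1:
            return np.ones(1)
        if self.n_z == 2:
            # a symmetric ramp would give both planes the same gain, which
            # makes the std projection blind; use a bright and a dim plane
            return np.array([1.0, 0.7])
        mid = (self.n_z - 1) / 2.0
        return 1.0 - 0.6 * np.abs(np.arange(self.n_z) - mid) / mid


@dataclass
class GroundTruth:
    """Exact truth for one simulated recording.

    ``masks`` is the full rasterized foreground (core + branches + detached
    cells) per frame; ``main_masks`` excludes detached cells. ``features``
    is a frame-indexed table using the morphometry output schema; columns
    that have no analytic definition for the generator (perimeter,
    eccentricity, complexity, intensity statistics) are left as NaN.
    """

    masks: np.ndarray  # (T, rows, cols) bool
    main_masks: np.ndarray  # (T, rows, cols) bool
    features: pd.DataFrame
    params: SpheroidSimParams


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _grid(shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return rr.astype(float), cc.astype(float)


def _stadium_mask(
    rr: np.ndarray,
    cc: np.ndarray,
    origin: Tuple[float, float],
    angle: float,
    length: float,
    width: float,
) -> np.ndarray:
    """Pixels within width/2 of the segment from origin to origin + length*u.

    A rectangle capped with a half-disk at the far end: its skeleton is a
    single ray with exactly one terminal endpoint.
    """
    ur, uc = -np.sin(angle), np.cos(angle)
    dr, dc = rr - origin[0], cc - origin[1]
    proj = np.clip(dr * ur + dc * uc, 0.0, length)
    dist2 = (dr - proj * ur) ** 2 + (dc - proj * uc) ** 2
    return dist2 <= (width / 2.0) ** 2


def _cell_center(params: SpheroidSimParams, ev: SingleCellEvent, t: float):
    """Center of a detached cell at time t (hours), or None if not yet detached."""
    if t < ev.detach_time:
        return None
    d = (
        params.core_radius_at(t)
        + DETACH_GAP
        + ev.cell_radius
        + ev.speed * (t - ev.detach_time)
    )
    rows, cols = params.image_shape
    o = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    return (o[0] - d * np.sin(ev.direction), o[1] + d * np.cos(ev.direction)), d


def rasterize_frame(
    params: SpheroidSimParams, t: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Rasterize the truth geometry at time t (hours).

    Returns (main_mass, cells) boolean masks.
    """
    rows, cols = params.image_shape
    rr, cc = _grid(params.image_shape)
    o = ((rows - 1) / 2.0, (cols - 1) / 2.0)

    r = float(params.core_radius_at(t))
    main = (rr - o[0]) ** 2 + (cc - o[1]) ** 2 <= r * r

    l = float(params.branch_length_at(t))
    if l > 0:
        for ang in params.branch_angles:
            seg_len = max(0.0, r + l - params.branch_width / 2.0)
            main |= _stadium_mask(rr, cc, o, ang, seg_len, params.branch_width)

    cells = np.zeros_like(main)
    for ev in params.single_cell_events:
        res = _cell_center(params, ev, t)
        if res is None:
            continue
        (cr, cclr), _ = res
        cells |= (rr - cr) ** 2 + (cc - cclr) ** 2 <= ev.cell_radius**2
    return main, cells


def _validate_frame(
    params: SpheroidSimParams, k: int, t: float, main: np.ndarray, cells: np.ndarray
) -> None:
    rows, cols = params.image_shape
    o = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    r = float(params.core_radius_at(t))
    extent = r + float(params.branch_length_at(t)) if params.n_branches else r
    for ev in params.single_cell_events:
        res = _cell_center(params, ev, t)
        if res is not None:
            extent = max(extent, res[1] + ev.cell_radius)
    margin = 1.0
    if (
        o[0] - extent < margin
        or o[1] - extent < margin
        or o[0] + extent > rows - 1 - margin
        or o[1] + extent > cols - 1 - margin
    ):
        raise SimulationError(
            f"geometry exceeds image bounds at frame {k} (t = {t:.3f} h): "
            f"radial extent {extent:.1f} px does not fit in {params.image_shape}"
        )
    if cells.any():
        # detached cells must stay morphologically disconnected (>= 2 px gap)
        halo = ndi.binary_dilation(main, structure=np.ones((5, 5), bool))
        if (halo & cells).any():
            raise SimulationError(
                f"detached cell touches the main mass at frame {k} "
                f"(gap < {MIN_CELL_GAP} px)"
            )


# ---------------------------------------------------------------------------
# analytic truth features
# ---------------------------------------------------------------------------


def analytic_features(
    params: SpheroidSimParams, origin: str = "truth"
) -> pd.DataFrame:
    """Frame-indexed analytic feature table implied by the parameters.

    Does not rasterize anything; area is filled in by
    :func:`generate_time_lapse` from the exact truth masks.
    """
    t = params.times_hours()
    r = params.core_radius_at(t)
    l = params.branch_length_at(t)
    n_cells = np.array(
        [
            sum(1 for ev in params.single_cell_events if tk >= ev.detach_time)
            for tk in t
        ],
        dtype=int,
    )
    branch_count = np.where(l > 0, params.n_branches, 0).astype(int)
    inv = r + np.where(branch_count > 0, l, 0.0)
    df = pd.DataFrame(
        {
            "replicate": origin,
            "frame": np.arange(params.n_frames),
            "time_hours": t,
            "area_px2": np.nan,
            "perimeter_px": np.nan,
            "eccentricity": np.nan,
            "complexity": np.nan,
            "core_radius_px": r,
            "invasive_radius_px": inv,
            "branch_count": branch_count,
            "single_cell_count": n_cells,
            "intensity_mean": np.nan,
            "intensity_sd": np.nan,
        }
    )
    return df[FEATURE_COLUMNS]


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------


def generate_time_lapse(
    params: SpheroidSimParams,
) -> Tuple[np.ndarray, GroundTruth]:
    """Simulate one spheroid recording.

    Returns a float64 stack of shape (n_frames, n_z, rows, cols) and the
    exact :class:`GroundTruth`. Identical parameters (including seed)
    produce bit-identical output.
    """
    T, Z = params.n_frames, params.n_z
    rows, cols = params.image_shape
    times = params.times_hours()
    gains = params.resolved_illumination()

    main_masks = np.zeros((T, rows, cols), dtype=bool)
    cell_masks = np.zeros((T, rows, cols), dtype=bool)
    for k, t in enumerate(times):
        main, cells = rasterize_frame(params, float(t))
        _validate_frame(params, k, float(t), main, cells)
        main_masks[k] = main
        cell_masks[k] = cells
    masks = main_masks | cell_masks

    # illumination falloff and photobleaching attenuate the fluorescence
    # signal above the detector background; the background level itself is
    # illumination-independent. This is what makes weak planes weak (low
    # signal on an unchanged background) and what the std projection must
    # rescue.
    amplitude = params.fg_level - params.bg_level
    stack = np.empty((T, Z, rows, cols), dtype=np.float64)
    for k, t in enumerate(times):
        decay = (1.0 - params.bleach_rate) ** t
        for z in range(Z):
            stack[k, z] = params.bg_level + np.where(
                masks[k], amplitude * gains[z] * decay, 0.0
            )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        stack += rng.normal(0.0, params.noise_sd, size=stack.shape)
        np.clip(stack, *INTENSITY_RANGE, out=stack)

    features = analytic_features(params)
    features["area_px2"] = main_masks.sum(axis=(1, 2)).astype(float)
    truth = GroundTruth(
        masks=masks, main_masks=main_masks, features=features, params=params
    )
    return stack, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _load_presets() -> dict:
    text = resources.files("spherodyn").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def preset(name: str, **overrides) -> SpheroidSimParams:
    """A fixed parameter set mimicking one of the three phenotype classes.

    ``follower``: compact, no branches, slow linear growth. ``leader``: six
    branches with quadratic elongation and detaching cells. ``parental``:
    intermediate (three branches, moderate rates). Any field can be
    overridden by keyword (e.g. ``preset("leader", noise_sd=0, n_z=1)``).
    """
    presets = _load_presets()
    if name not in presets:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {sorted(presets)}"
        )
    d = dict(presets[name])
    d["branch_angles"] = tuple(d.get("branch_angles") or ())
    d["branch_length_coeffs"] = tuple(d.get("branch_length_coeffs", (0.0, 0.0)))
    d["image_shape"] = tuple(d.get("image_shape", (128, 128)))
    d["single_cell_events"] = tuple(
        SingleCellEvent(*ev) for ev in d.get("single_cell_events") or ()
    )
    d.update(overrides)
    return SpheroidSimParams(**d)


def preset_names() -> list[str]:
    return sorted(_load_presets())


# ---------------------------------------------------------------------------
# disk output
# ---------------------------------------------------------------------------


def write_stack(stack: np.ndarray, path: str | Path) -> Path:
    """Write a (T, Z, rows, cols) stack as a multi-page TIFF, t-major then z."""
    path = Path(path)
    T, Z, r, c = stack.shape
    tifffile.imwrite(path, stack.reshape(T * Z, r, c), photometric="minisblack")
    return path


def write_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    """Write truth masks (8-bit TIFF per frame) and the feature CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for k in range(truth.masks.shape[0]):
        tifffile.imwrite(
            out_dir / f"mask_{k:04d}.tif",
            (truth.masks[k].astype(np.uint8) * 255),
        )
    truth.features.to_csv(out_dir / "truth_features.csv", index=False)


def write_synthetic_experiment(
    root: str | Path,
    conditions: Optional[dict[str, int]] = None,
    seed: int = 0,
    truth_dir: Optional[str | Path] = None,
    **overrides,
) -> Path:
    """Write a condition/replicate folder hierarchy of synthetic recordings.

    ``conditions`` maps preset name -> number of replicates (default: the
    three phenotype presets, 3 replicates each, mirroring a typical
    leader/follower experiment). Each replicate gets its own sub-seed.
    """
    root = Path(root)
    conditions = conditions or {"follower": 3, "leader": 3, "parental": 3}
    for ci, (cond, n_rep) in enumerate(sorted(conditions.items())):
        for i in range(n_rep):
            rep_seed = (seed * 1000 + 131 * ci + i) % (2**31 - 1)
            params = preset(cond, seed=rep_seed, **overrides)
            stack, truth = generate_time_lapse(params)
            rep_dir = root / cond
            rep_dir.mkdir(parents=True, exist_ok=True)
            write_stack(stack, rep_dir / f"rep{i:02d}.tif")
            if truth_dir is not None:
                write_truth(truth, Path(truth_dir) / cond / f"rep{i:02d}")
    return root
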