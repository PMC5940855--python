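"""Per-frame morphometric features of a segmented spheroid.

All shape features are computed on the *main mass* (largest connected
component); the single-cell count uses the full mask. The panel:

* area (px^2), Crofton 4-direction perimeter (px), equivalent-ellipse
  eccentricity, intensity mean/sd over the main mass,
* boundary complexity = Perimeter^2 / (4 pi Area) — 1 for a circle, larger
  for irregular outlines,
* core radius — largest circle inscribed in the mask, centered at the
  centroid (distance-transform value at the centroid),
* invasive radius — radius of the centroid-anchored circle enclosing the
  whole main mass, including invasive branches,
* branch count — terminal endpoints of the pruned topological skeleton,
* single-cell count — small disconnected foreground islands.

The Crofton perimeter estimator is used deliberately: naive pixel-edge
counting overestimates circle perimeters by ~27%, which would break the
"circle has complexity 1" anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology

from .segmentation import main_mass
from .synthetic import FEATURE_COLUMNS

log = logging.getLogger(__name__)


class MorphometryError(ValueError):
    pass


@dataclass(frozen=True)
class MorphometryConfig:
    prune_length: int = 5
    single_cell_min_area: int = 10
    single_cell_max_area: int = 500
    enclosing_mode: str = "centroid"  # or "welzl"


@dataclass
class FeatureRecord:
    """One frame's feature panel; ``valid`` is False for empty masks, in
    which case every other field is None."""

    valid: bool
    area: Optional[float] = None
    perimeter: Optional[float] = None
    eccentricity: Optional[float] = None
    complexity: Optional[float] = None
    core_radius: Optional[float] = None
    invasive_radius: Optional[float] = None
    branch_count: Optional[int] = None
    single_cell_count: Optional[int] = None
    intensity_mean: Optional[float] = None
    intensity_sd: Optional[float] = None
    centroid: Optional[Tuple[float, float]] = None


# ---------------------------------------------------------------------------
# individual features
# ---------------------------------------------------------------------------


def complexity(perimeter: float, area: float) -> float:
    """Boundary complexity P^2 / (4 pi A); equals 1 for a circle."""
    if area <= 0:
        raise MorphometryError("complexity requires area > 0")
    return perimeter**2 / (4.0 * np.pi * area)


def core_radius(mask_frame: np.ndarray) -> float:
    """Radius of the largest inscribed circle centered at the centroid.

    Evaluates the Euclidean distance transform of the main mass at the
    rounded centroid. The raw transform measures to the nearest *background
    pixel center*, half a pixel beyond the mask boundary, so half a pixel is
    subtracted to keep the inscribed radius consistent with the
    pixel-center-based invasive radius (a rasterized disk then satisfies
    invasive >= core). Returns 0 (with a warning) if the centroid falls
    outside the mask, e.g. for annular shapes.
    """
    mm = main_mass(mask_frame)
    if not mm.any():
        raise MorphometryError("core_radius requires a non-empty mask")
    r, c = _centroid(mm)
    ri, ci = int(round(r)), int(round(c))
    if not mm[ri, ci]:
        log.warning("centroid (%.1f, %.1f) lies outside the mask; core radius 0", r, c)
        return 0.0
    edt = ndi.distance_transform_edt(mm)
    return max(0.0, float(edt[ri, ci]) - 0.5)


def invasive_radius(mask_frame: np.ndarray, enclosing_mode: str = "centroid") -> float:
    """Radius of the circle enclosing the entire main mass.

    ``centroid`` mode (default) anchors the circle at the mask centroid and
    returns the maximum centroid-to-pixel distance, matching the convention
    of concentric core/invasive circles. ``welzl`` returns the radius of
    the unanchored minimum enclosing circle, which is never larger.
    """
    mm = main_mass(mask_frame)
    if not mm.any():
        raise MorphometryError("invasive_radius requires a non-empty mask")
    rr, cc = np.nonzero(mm)
    pts = np.column_stack([rr, cc]).astype(float)
    if enclosing_mode == "centroid":
        r, c = _centroid(mm)
        return float(np.sqrt(((pts - [r, c]) ** 2).sum(axis=1)).max())
    if enclosing_mode == "welzl":
        return _min_enclosing_radius(pts)
    raise MorphometryError(f"unknown enclosing_mode {enclosing_mode!r}")


def branch_count(mask_frame: np.ndarray, prune_length: int = 5) -> int:
    """Number of terminal endpoints of the pruned skeleton of the main mass.

    The mask is thinned to a topological skeleton; spurs are pruned by
    ``prune_length`` rounds of endpoint removal (shaving every branch tip by
    one pixel per round, which eliminates spurious spurs shorter than the
    prune length); remaining pixels with exactly one 8-connected skeleton
    neighbor are counted. An empty or single-pixel skeleton yields 0.
    """
    mm = main_mass(mask_frame)
    if not mm.any():
        raise MorphometryError("branch_count requires a non-empty mask")
    skel = morphology.skeletonize(mm)
    for _ in range(max(0, int(prune_length))):
        ends = _endpoints(skel)
        if not ends.any():
            break
        skel &= ~ends
    return int(_endpoints(skel).sum())


def single_cell_count(
    mask_frame: np.ndarray, min_area: int = 10, max_area: int = 500
) -> int:
    """Disconnected foreground islands with area in [min_area, max_area],
    excluding the main mass; sub-threshold specks are treated as noise."""
    mask_frame = np.asarray(mask_frame, dtype=bool)
    if not mask_frame.any():
        return 0
    labels = measure.label(mask_frame, connectivity=2)
    mm = main_mass(mask_frame)
    main_label = labels[mm].flat[0]
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    counts[main_label] = 0
    return int(np.sum((counts >= min_area) & (counts <= max_area)))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _centroid(mask: np.ndarray) -> Tuple[float, float]:
    rr, cc = np.nonzero(mask)
    return float(rr.mean()), float(cc.mean())


def _endpoints(skel: np.ndarray) -> np.ndarray:
    """Skeleton pixels with exactly one 8-connected skeleton neighbor."""
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    nbrs = ndi.convolve(skel.astype(int), kernel, mode="constant")
    return skel & (nbrs == 1)


def _min_enclosing_radius(points: np.ndarray) -> float:
    """Welzl's algorithm on the convex hull (pixel centers)."""
    from scipy.spatial import ConvexHull

    if len(points) == 1:
        return 0.0
    if len(points) > 3:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # collinear point sets
            pass
    rng = np.random.default_rng(0)
    pts = points[rng.permutation(len(points))]

    def circle_two(a, b):
        c = (a + b) / 2.0
        return c, float(np.linalg.norm(a - b) / 2.0)

    def circle_three(a, b, c):
        d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            return None
        ux = (
            (a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])
        ) / d
        uy = (
            (a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])
        ) / d
        center = np.array([ux, uy])
        return center, float(np.linalg.norm(a - center))

    def in_circle(p, circ, eps=1e-9):
        center, r = circ
        return np.linalg.norm(p - center) <= r + eps

    def trivial(boundary):
        if not boundary:
            return np.zeros(2), 0.0
        if len(boundary) == 1:
            return boundary[0], 0.0
        if len(boundary) == 2:
            return circle_two(*boundary)
        circ = circle_three(*boundary)
        if circ is None:
            # collinear boundary: fall back to the widest pair
            best = None
            for i in range(3):
                for j in range(i + 1, 3):
                    cand = circle_two(boundary[i], boundary[j])
                    if best is None or cand[1] > best[1]:
                        best = cand
            return best
        return circ

    # iterative Welzl (move-to-front style, adequate for hull-sized inputs)
    circ = (np.zeros(2), 0.0)
    for i, p in enumerate(pts):
        if in_circle(p, circ):
            continue
        circ = (p, 0.0)
        for j, q in enumerate(pts[: i]):
            if in_circle(q, circ):
                continue
            circ = circle_two(p, q)
            for s in pts[: j]:
                if in_circle(s, circ):
                    continue
                circ = trivial([p, q, s])
    return circ[1]


# ---------------------------------------------------------------------------
# per-frame panel and time series
# ---------------------------------------------------------------------------


def extract_features(
    mask_frame: np.ndarray,
    intensity_frame: np.ndarray,
    config: Optional[MorphometryConfig] = None,
) -> FeatureRecord:
    """Compute the full feature panel for one frame.

    Intensity statistics are taken over main-mass pixels of the *projected*
    (pre-smoothing) intensity frame: smoothing aids segmentation but should
    not alter measurements.
    """
    config = config or MorphometryConfig()
    mask_frame = np.asarray(mask_frame, dtype=bool)
    intensity_frame = np.asarray(intensity_frame, dtype=np.float64)
    if mask_frame.shape != intensity_frame.shape:
        raise MorphometryError("mask and intensity frames must share a shape")
    if not mask_frame.any():
        return FeatureRecord(valid=False)

    mm = main_mass(mask_frame)
    props = measure.regionprops(mm.astype(np.uint8))[0]
    area = float(mm.sum())
    perim = float(props.perimeter_crofton)
    record = FeatureRecord(
        valid=True,
        area=area,
        perimeter=perim,
        eccentricity=float(props.eccentricity),
        complexity=complexity(perim, area),
        core_radius=core_radius(mm),
        invasive_radius=invasive_radius(mm, config.enclosing_mode),
        branch_count=branch_count(mm, config.prune_length),
        single_cell_count=single_cell_count(
            mask_frame, config.single_cell_min_area, config.single_cell_max_area
        ),
        intensity_mean=float(intensity_frame[mm].mean()),
        intensity_sd=float(intensity_frame[mm].std()),
        centroid=_centroid(mm),
    )
    return record


def build_feature_series(
    masks: np.ndarray,
    intensities: np.ndarray,
    frame_interval: float,
    origin: str = "replicate",
    config: Optional[MorphometryConfig] = None,
) -> pd.DataFrame:
    """Feature table over a (t, rows, cols) mask volume.

    One row per frame, including invalid (empty-mask) frames, whose feature
    columns are NaN. ``frame_interval`` is in minutes; ``time_hours`` is
    k * frame_interval / 60.
    """
    if masks.shape != intensities.shape:
        raise MorphometryError("masks and intensities must share a shape")
    rows = []
    for k in range(masks.shape[0]):
        rec = extract_features(masks[k], intensities[k], config)
        rows.append(
            {
                "replicate": origin,
                "frame": k,
                "time_hours": k * frame_interval / 60.0,
                "area_px2": rec.area,
                "perimeter_px": rec.perimeter,
                "eccentricity": rec.eccentricity,
                "complexity": rec.complexity,
                "core_radius_px": rec.core_radius,
                "invasive_radius_px": rec.invasive_radius,
                "branch_count": rec.branch_count,
                "single_cell_count": rec.single_cell_count,
                "intensity_mean": rec.intensity_mean,
                "intensity_sd": rec.intensity_sd,
            }
        )
    df = pd.DataFrame(rows)
    return df[FEATURE_COLUMNS]
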