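"""Spatiotemporal binary segmentation by energy-minimizing graph cuts.

The projected (x, y, t) volume is treated as a 6-connected graph (4 spatial
neighbors within a frame, 2 temporal neighbors across frames). Each voxel i
carries unary costs for the foreground/background labels, derived from a
two-Gaussian intensity model, and each neighbor pair (i, j) carries a
contrast-sensitive smoothness weight

    w(i, j) = exp(-(I_i - I_j)^2 / (2 sigma_c^2)),

scaled by ``lambda_spatial`` for in-frame neighbors and ``lambda_temporal``
for across-frame neighbors. The labeling minimizing

    E(L) = sum_i unary_i(L_i) + sum_(i,j) lambda_(i,j) w(i,j) [L_i != L_j]

is a submodular binary energy, so the exact global optimum is found by a
single min-cut / max-flow computation. For long imaging intervals, where
consecutive frames differ too much for temporal edges to help,
``per_frame_2d`` mode cuts each frame independently.

The flow problem itself is solved by :func:`scipy.sparse.csgraph.maximum_flow`
on integer-quantized capacities; the minimum cut (and hence the labeling) is
recovered by a breadth-first search on the residual graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from skimage import measure, morphology
from skimage.filters import threshold_otsu

log = logging.getLogger(__name__)

#: unary costs (negative log-likelihoods) are clamped to this cap.
UNARY_CAP = 50.0

#: floor on the fitted class standard deviations, in intensity units; keeps
#: the Gaussian log-likelihoods finite (and non-negative) on degenerate,
#: e.g. binary, volumes.
SD_FLOOR = 0.5

#: refuse to build a single flow graph beyond this voxel count.
MAX_VOXELS = 8_000_000

_LOG_2PI = float(np.log(2.0 * np.pi))


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class GraphCutConfig:
    """Parameters of the segmentation energy and its post-processing."""

    lambda_spatial: float = 1.0
    lambda_temporal: float = 1.0
    contrast_sigma: object = "auto"  # "auto" or positive float
    mode: str = "volume_3d"  # or "per_frame_2d"
    fill_holes: bool = True
    min_object_area: int = 4

    def __post_init__(self) -> None:
        if self.lambda_spatial < 0 or self.lambda_temporal < 0:
            raise SegmentationError("lambda weights must be >= 0")
        if self.mode not in ("volume_3d", "per_frame_2d"):
            raise SegmentationError(f"unknown mode {self.mode!r}")
        if self.contrast_sigma != "auto" and (
            not isinstance(self.contrast_sigma, (int, float)) or self.contrast_sigma <= 0
        ):
            raise SegmentationError("contrast_sigma must be 'auto' or > 0")


@dataclass(frozen=True)
class EnergyModel:
    """Two-Gaussian intensity model behind the unary costs."""

    mu_fg: float
    sd_fg: float
    mu_bg: float
    sd_bg: float
    threshold: float
    cap: float = UNARY_CAP


# ---------------------------------------------------------------------------
# unary (data) term
# ---------------------------------------------------------------------------


def estimate_unary(volume: np.ndarray, pooled_sd: bool = True) -> EnergyModel:
    """Fit the two-Gaussian intensity model from a global Otsu split.

    The volume is thresholded by Otsu's method and class means/standard
    deviations are fitted to the two sides. By default both classes share a
    pooled standard deviation (quadratic mean of the side deviations): with
    a common sd the equal-cost level sits at the midpoint of the class
    means, which keeps the recovered boundary on the half-intensity contour
    of a blurred step edge. With ``pooled_sd=False`` the narrower class —
    usually the background — pulls the decision level toward itself and
    systematically dilates the mask. Unary costs are the Gaussian negative
    log-likelihoods, clamped to ``UNARY_CAP``.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if np.ptp(volume) == 0:
        raise SegmentationError("no intensity contrast: volume is constant")
    thr = float(threshold_otsu(volume))
    fg = volume[volume > thr]
    bg = volume[volume <= thr]
    if fg.size == 0 or bg.size == 0:  # pragma: no cover - otsu guarantees both
        raise SegmentationError("no intensity contrast: degenerate Otsu split")
    sd_fg = max(float(fg.std()), SD_FLOOR)
    sd_bg = max(float(bg.std()), SD_FLOOR)
    if pooled_sd:
        sd_fg = sd_bg = float(np.sqrt((sd_fg**2 + sd_bg**2) / 2.0))
    return EnergyModel(
        mu_fg=float(fg.mean()),
        sd_fg=sd_fg,
        mu_bg=float(bg.mean()),
        sd_bg=sd_bg,
        threshold=thr,
    )


def unary_costs(
    volume: np.ndarray, model: EnergyModel
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-voxel (foreground, background) label costs, finite and >= 0."""
    volume = np.asarray(volume, dtype=np.float64)

    def nll(mu: float, sd: float) -> np.ndarray:
        z = (volume - mu) / sd
        return 0.5 * (_LOG_2PI + z * z) + np.log(sd)

    u_fg = np.clip(nll(model.mu_fg, model.sd_fg), 0.0, model.cap)
    u_bg = np.clip(nll(model.mu_bg, model.sd_bg), 0.0, model.cap)
    return u_fg, u_bg


# ---------------------------------------------------------------------------
# pairwise (smoothness) term
# ---------------------------------------------------------------------------


def _neighbor_diffs(volume: np.ndarray):
    """Index pairs and intensity differences for the 6-neighborhood.

    Returns (spatial_i, spatial_j, spatial_d, temporal_i, temporal_j,
    temporal_d) with flat voxel indices.
    """
    T, R, C = volume.shape
    idx = np.arange(volume.size).reshape(T, R, C)
    flat = volume.ravel()

    si = np.concatenate([idx[:, :-1, :].ravel(), idx[:, :, :-1].ravel()])
    sj = np.concatenate([idx[:, 1:, :].ravel(), idx[:, :, 1:].ravel()])
    ti = idx[:-1].ravel()
    tj = idx[1:].ravel()
    return si, sj, flat[si] - flat[sj], ti, tj, flat[ti] - flat[tj]


def resolve_contrast_sigma(volume: np.ndarray, config: GraphCutConfig) -> float:
    """The contrast scale sigma_c: configured value, or the mean absolute
    intensity difference over all 6-neighborhood pairs (``auto``)."""
    if config.contrast_sigma != "auto":
        return float(config.contrast_sigma)
    _, _, sd, _, _, td = _neighbor_diffs(np.asarray(volume, float))
    mad = float(np.mean(np.abs(np.concatenate([sd, td]))))
    return mad if mad > 0 else 1.0


def _contrast_weight(diff: np.ndarray, sigma_c: float) -> np.ndarray:
    return np.exp(-(diff * diff) / (2.0 * sigma_c * sigma_c))


# ---------------------------------------------------------------------------
# max-flow solver
# ---------------------------------------------------------------------------


def _solve_binary_cut(
    u_fg: np.ndarray,
    u_bg: np.ndarray,
    ei: np.ndarray,
    ej: np.ndarray,
    ew: np.ndarray,
) -> np.ndarray:
    """Exact minimizer of a submodular binary energy via min-cut.

    Convention: source side = foreground. Cutting the source->voxel edge
    (capacity u_bg) pays the background cost; cutting voxel->sink (capacity
    u_fg) pays the foreground cost; cutting a pairwise edge pays w.
    Capacities are quantized with an adaptive integer scale.
    """
    n = u_fg.size
    max_w = max(float(u_fg.max(initial=0.0)), float(u_bg.max(initial=0.0)))
    if ew.size:
        max_w = max(max_w, float(ew.max()))
    scale = min(10**7, int(2e9 / max(1.0, max_w)))

    s, t = n, n + 1
    vox = np.arange(n)
    zeros = np.zeros(n, dtype=np.int64)
    qi = np.round(ew * scale).astype(np.int64)

    rows = np.concatenate([ei, ej, np.full(n, s), vox, vox, np.full(n, t)])
    cols = np.concatenate([ej, ei, vox, np.full(n, s), np.full(n, t), vox])
    caps = np.concatenate(
        [
            qi,
            qi,
            np.round(u_bg.ravel() * scale).astype(np.int64),
            zeros,
            np.round(u_fg.ravel() * scale).astype(np.int64),
            zeros,
        ]
    )
    graph = csr_matrix(
        (caps.astype(np.int32), (rows, cols)), shape=(n + 2, n + 2)
    )
    result = maximum_flow(graph, s, t)

    residual = graph.copy()
    residual.data = (graph.data - result.flow.data > 0).astype(np.int32)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    labels = np.zeros(n + 2, dtype=bool)
    labels[order] = True
    return labels[:n]


# ---------------------------------------------------------------------------
# public segmentation API
# ---------------------------------------------------------------------------


def graphcut_segment(
    volume: np.ndarray,
    config: Optional[GraphCutConfig] = None,
    model: Optional[EnergyModel] = None,
) -> np.ndarray:
    """Segment a (t, rows, cols) volume into a boolean foreground mask.

    Solves the spatiotemporal energy exactly by max-flow (``volume_3d``
    mode) or cuts every frame independently (``per_frame_2d``), then
    post-processes each frame (hole filling, removal of components smaller
    than ``min_object_area``). Deterministic.
    """
    config = config or GraphCutConfig()
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise SegmentationError(f"expected (t, rows, cols), got shape {volume.shape}")
    if volume.size > MAX_VOXELS:
        raise SegmentationError(
            f"volume has {volume.size} voxels (> {MAX_VOXELS}); "
            "use mode='per_frame_2d' or tile the input"
        )
    model = model or estimate_unary(volume)
    sigma_c = resolve_contrast_sigma(volume, config)
    u_fg, u_bg = unary_costs(volume, model)

    if config.mode == "volume_3d":
        si, sj, sd, ti, tj, td = _neighbor_diffs(volume)
        ei = np.concatenate([si, ti])
        ej = np.concatenate([sj, tj])
        ew = np.concatenate(
            [
                config.lambda_spatial * _contrast_weight(sd, sigma_c),
                config.lambda_temporal * _contrast_weight(td, sigma_c),
            ]
        )
        labels = _solve_binary_cut(u_fg.ravel(), u_bg.ravel(), ei, ej, ew)
        mask = labels.reshape(volume.shape)
    else:
        T, R, C = volume.shape
        mask = np.empty(volume.shape, dtype=bool)
        for k in range(T):
            frame = volume[k]
            idx = np.arange(frame.size).reshape(R, C)
            fi = np.concatenate([idx[:-1, :].ravel(), idx[:, :-1].ravel()])
            fj = np.concatenate([idx[1:, :].ravel(), idx[:, 1:].ravel()])
            d = frame.ravel()[fi] - frame.ravel()[fj]
            ew = config.lambda_spatial * _contrast_weight(d, sigma_c)
            labels = _solve_binary_cut(
                u_fg[k].ravel(), u_bg[k].ravel(), fi, fj, ew
            )
            mask[k] = labels.reshape(R, C)

    return _postprocess(mask, config)


def _postprocess(mask: np.ndarray, config: GraphCutConfig) -> np.ndarray:
    out = np.empty_like(mask)
    for k in range(mask.shape[0]):
        frame = mask[k]
        if config.fill_holes:
            frame = ndi.binary_fill_holes(frame)
        if config.min_object_area > 0 and frame.any():
            labels = measure.label(frame, connectivity=2)
            counts = np.bincount(labels.ravel())
            keep = counts >= config.min_object_area
            keep[0] = False
            frame = keep[labels]
        out[k] = frame
    return out


def energy_of(
    labeling: np.ndarray,
    volume: np.ndarray,
    config: Optional[GraphCutConfig] = None,
    model: Optional[EnergyModel] = None,
) -> float:
    """Evaluate the segmentation energy E(L) of a given labeling exactly.

    Pure function over the same unary and pairwise terms the solver uses
    (before quantization); serves as the objective oracle in tests.
    """
    config = config or GraphCutConfig()
    labeling = np.asarray(labeling, dtype=bool)
    volume = np.asarray(volume, dtype=np.float64)
    if labeling.shape != volume.shape:
        raise SegmentationError(
            f"labeling shape {labeling.shape} != volume shape {volume.shape}"
        )
    model = model or estimate_unary(volume)
    sigma_c = resolve_contrast_sigma(volume, config)
    u_fg, u_bg = unary_costs(volume, model)
    energy = float(np.where(labeling, u_fg, u_bg).sum())

    lab = labeling.ravel()
    si, sj, sd, ti, tj, td = _neighbor_diffs(volume)
    sw = config.lambda_spatial * _contrast_weight(sd, sigma_c)
    energy += float(sw[lab[si] != lab[sj]].sum())
    if config.mode == "volume_3d":
        tw = config.lambda_temporal * _contrast_weight(td, sigma_c)
        energy += float(tw[lab[ti] != lab[tj]].sum())
    return energy


def main_mass(mask_frame: np.ndarray) -> np.ndarray:
    """Largest 8-connected foreground component of a 2-D mask.

    Ties are broken by the smallest top-left bounding-box corner, then by
    the row-major first foreground pixel. An empty frame yields an empty
    mask (callers record the frame as invalid).
    """
    mask_frame = np.asarray(mask_frame, dtype=bool)
    if mask_frame.ndim != 2:
        raise SegmentationError("main_mass expects a 2-D mask frame")
    if not mask_frame.any():
        return np.zeros_like(mask_frame)
    labels = measure.label(mask_frame, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best_area = counts.max()
    candidates = np.flatnonzero(counts == best_area)
    if len(candidates) > 1:
        def key(lbl: int):
            rr, cc = np.nonzero(labels == lbl)
            return (rr.min(), cc.min(), int(rr[0] * mask_frame.shape[1] + cc[0]))
        candidates = sorted(candidates, key=key)
    return labels == candidates[0]
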