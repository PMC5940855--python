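"""Z-stack projection and spatiotemporal Gaussian smoothing.

Focal planes are collapsed to a single 2-D image per time point with a
per-pixel standard-deviation projection, I_p(x, y, t) = sigma_z[I(x, y, z, t)]
(population standard deviation). Because both foreground and background are
attenuated multiplicatively by uneven illumination across z, the std
projection yields a contrast proportional to the signal itself, rescuing
structure that is weak in individual planes.

The projected (x, y, t) volume is then smoothed with a separable 3-D
Gaussian in space and time before segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoothingConfig:
    """Gaussian sigmas: ``sigma_xy`` in pixels (> 0), ``sigma_t`` in frames
    (>= 0; zero disables temporal smoothing). Boundaries are reflected."""

    sigma_xy: float = 1.5
    sigma_t: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_xy <= 0:
            raise ValueError("sigma_xy must be > 0 px")
        if self.sigma_t < 0:
            raise ValueError("sigma_t must be >= 0 frames")


def std_projection(stack: np.ndarray) -> np.ndarray:
    """Collapse a (t, z, rows, cols) stack to (t, rows, cols) by the
    population standard deviation across z.

    With a single focal plane there is nothing to project; the frames pass
    through unchanged.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 4:
        raise ValueError(f"expected a (t, z, rows, cols) stack, got shape {stack.shape}")
    if stack.shape[1] == 1:
        log.info("single focal plane: std projection bypassed")
        return stack[:, 0].copy()
    return stack.std(axis=1, ddof=0)


def gaussian_smooth_xyt(volume: np.ndarray, config: SmoothingConfig) -> np.ndarray:
    """Separable Gaussian smoothing of a (t, rows, cols) volume with sigmas
    (sigma_t, sigma_xy, sigma_xy) and reflecting boundaries."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError(f"expected a (t, rows, cols) volume, got shape {volume.shape}")
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    sigmas = (config.sigma_t, config.sigma_xy, config.sigma_xy)
    return ndi.gaussian_filter(volume, sigma=sigmas, mode="reflect")
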