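"""Height-map container and per-scanline background flattening."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..errors import FlatteningError

__all__ = ["HeightMap", "flatten_scanlines"]


@dataclass
class HeightMap:
    """AFM topography on a row-major grid, origin at the top-left scanline.

    Heights in nm; ``pixel_size`` is the isotropic nm-per-pixel scale.
    """

    heights: np.ndarray
    pixel_size: float
    label: str = ""
    flattened: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if min(self.heights.shape) < 64:
            raise ValueError("height map must be at least 64x64 pixels")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("height map contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape


def _robust_line_fit(x: np.ndarray, z: np.ndarray, order: int, n_iter: int = 4):
    """Polynomial background fit with one-sided masking of ridge pixels.

    Fibrils only protrude upward, so pixels far above the current fit are
    iteratively excluded using a median + MAD threshold.
    """
    mask = np.ones(len(x), dtype=bool)
    coef = np.polyfit(x, z, order)
    for _ in range(n_iter):
        resid = z - np.polyval(coef, x)
        r_bg = resid[mask]
        med = np.median(r_bg)
        mad = np.median(np.abs(r_bg - med))
        sigma = 1.4826 * mad
        if sigma <= 0:
            # perfectly fit background; exclude anything strictly above it
            new_mask = resid <= med + max(1e-9, 1e-6 * np.ptp(z))
        else:
            new_mask = resid <= med + 2.0 * sigma
        if new_mask.sum() < order + 2:
            break
        if np.array_equal(new_mask, mask):
            mask = new_mask
            break
        mask = new_mask
        coef = np.polyfit(x[mask], z[mask], order)
    if mask.sum() < order + 2:
        raise FlatteningError(
            f"scanline has only {int(mask.sum())} background pixels, "
            f"need >= {order + 2} for order-{order} fit"
        )
    return coef, mask


def flatten_scanlines(hmap: HeightMap, order: int = 2) -> HeightMap:
    """Remove the per-scanline background trend with a polynomial fit.

    Each scanline is corrected independently: an order-``order`` polynomial
    is fitted to background pixels (ridge pixels excluded by robust
    one-sided masking) and subtracted, leaving the background near zero and
    fibril apex heights preserved.
    """
    if order not in (0, 1, 2, 3):
        raise ValueError("order must be in {0, 1, 2, 3}")
    z = hmap.heights
    n_rows, n_cols = z.shape
    x = np.arange(n_cols, dtype=float)
    # normalize abscissa for conditioning
    xn = (x - x.mean()) / max(x.std(), 1.0)
    out = np.empty_like(z)
    for i in range(n_rows):
        coef, _ = _robust_line_fit(xn, z[i], order)
        out[i] = z[i] - np.polyval(coef, xn)
    return replace(hmap, heights=out, flattened=True)
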