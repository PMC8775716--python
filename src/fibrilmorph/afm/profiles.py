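"""Perpendicular cross-section extraction and 4-parameter Gaussian fitting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit

from ..kinetics import pearson
from .heightmap import HeightMap
from .tracing import RidgePath

__all__ = ["CrossSectionProfile", "ProfileFit", "extract_profiles", "fit_profile"]


@dataclass
class CrossSectionProfile:
    """Height profile sampled along the normal through one ridge point.

    Offsets (nm) are symmetric about the ridge point with an odd sample
    count; heights are bilinearly interpolated map values.
    """

    offsets: np.ndarray
    heights: np.ndarray
    normal: np.ndarray
    source_index: int

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        n = len(self.offsets)
        if n != len(self.heights):
            raise ValueError("offsets and heights must have equal length")
        if n % 2 != 1:
            raise ValueError("sample count must be odd")
        if not np.allclose(self.offsets, -self.offsets[::-1]):
            raise ValueError("offsets must be symmetric about zero")


@dataclass
class ProfileFit:
    """4-parameter Gaussian fit of one cross-section.

    Ridge height is the ``amplitude`` (apex above the fitted local
    baseline).  A fit is accepted when the correlation coefficient is at
    least ``r_min`` and the peak lies in the central third of the window.
    """

    peak_position: float
    peak_width: float
    amplitude: float
    baseline: float
    r: float
    accepted: bool

    def __post_init__(self):
        if self.accepted and not self.amplitude > 0:
            raise ValueError("accepted fits must have positive amplitude")


def _gaussian(x, position, width, amplitude, baseline):
    return baseline + amplitude * np.exp(-0.5 * ((x - position) / width) ** 2)


def extract_profiles(
    path: RidgePath,
    normals: np.ndarray,
    hmap: HeightMap,
    half_width: float,
    step: float | None = None,
    skip_excluded: bool = True,
) -> list[CrossSectionProfile]:
    """Sample cross-sections along per-point normals by bilinear interpolation.

    ``half_width`` is the nm half-extent of the symmetric window and must
    be at least 3 pixel sizes.  Profiles at excluded (crossing) points or
    whose window exits the image are skipped; the caller can recover the
    skip count as ``len(path) - len(result)``.
    """
    px = hmap.pixel_size
    if half_width < 3 * px:
        raise ValueError("half_width must be >= 3 x pixel_size")
    if step is None:
        step = px / 2.0
    n_half = int(np.ceil(half_width / step))
    offsets = np.arange(-n_half, n_half + 1, dtype=float) * step  # nm, odd count

    z = hmap.heights
    profiles: list[CrossSectionProfile] = []
    for i, (pt, nrm) in enumerate(zip(path.points, normals)):
        if skip_excluded and path.excluded[i]:
            continue
        coords = pt[None, :] + (offsets / px)[:, None] * nrm[None, :]
        r, c = coords[:, 0], coords[:, 1]
        if r.min() < 0 or c.min() < 0 or r.max() > z.shape[0] - 1 or c.max() > z.shape[1] - 1:
            continue  # window exits the image
        vals = map_coordinates(z, [r, c], order=1, mode="constant", cval=np.nan)
        if not np.all(np.isfinite(vals)):
            continue
        profiles.append(
            CrossSectionProfile(offsets=offsets.copy(), heights=vals, normal=nrm.copy(), source_index=i)
        )
    return profiles


def fit_profile(
    profile: CrossSectionProfile,
    r_min: float = 0.95,
    max_nfev: int = 5000,
) -> ProfileFit:
    """Least-squares 4-parameter Gaussian fit of a cross-section.

    Non-convergence yields a rejected (not raised) fit so the caller can
    count failures.
    """
    x, y = profile.offsets, profile.heights
    if len(x) < 7:
        raise ValueError("profile must have at least 7 samples")
    span = x[-1] - x[0]
    baseline0 = float(np.median(np.concatenate([y[: len(y) // 4], y[-len(y) // 4:]])))
    amp0 = float(y.max() - baseline0)
    pos0 = float(x[np.argmax(y)])
    width0 = span / 8.0
    try:
        popt, _ = curve_fit(
            _gaussian,
            x,
            y,
            p0=[pos0, width0, max(amp0, 1e-6), baseline0],
            bounds=([x[0], span / 100.0, 0.0, -np.inf], [x[-1], span, np.inf, np.inf]),
            maxfev=max_nfev,
        )
    except (RuntimeError, ValueError):
        return ProfileFit(
            peak_position=np.nan, peak_width=np.nan, amplitude=np.nan,
            baseline=np.nan, r=-1.0, accepted=False,
        )
    pos, width, amp, base = (float(v) for v in popt)
    r = pearson(y, _gaussian(x, *popt))
    central = abs(pos) <= span / 6.0  # central third of the window
    accepted = bool(r >= r_min and central and amp > 0)
    return ProfileFit(
        peak_position=pos, peak_width=width, amplitude=amp,
        baseline=base, r=r, accepted=accepted,
    )
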