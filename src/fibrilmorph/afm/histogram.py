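"""Ridge-height histograms and multi-peak normal-mixture regression.

The histogram of accepted ridge heights is fitted with a sum of normal
components (maximal count, mean, SD per component) by weighted least
squares; when the component count is not given, 1..6 components are tried
and the small-sample-corrected information criterion picks the best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from ..errors import FitFailureError
from .profiles import ProfileFit

__all__ = ["HeightHistogram", "PeakMixtureFit", "build_histogram", "fit_multipeak"]


@dataclass
class HeightHistogram:
    """Binned distribution of accepted ridge heights (nm)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_profiles: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if int(self.counts.sum()) != self.n_profiles:
            raise ValueError("counts must sum to n_profiles")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PeakMixtureFit:
    """Normal-mixture decomposition of a height histogram.

    ``peaks`` holds (maximal count, mean nm, SD nm) triples sorted by mean;
    ``gof`` is the R-squared of the count fit.
    """

    peaks: list[tuple[float, float, float]]
    n_peaks: int
    gof: float
    aicc: float

    def __post_init__(self):
        means = [p[1] for p in self.peaks]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("component means must be strictly increasing")
        if any(p[2] <= 0 or p[0] <= 0 for p in self.peaks):
            raise ValueError("amplitudes and SDs must be positive")

    @property
    def means(self) -> list[float]:
        return [p[1] for p in self.peaks]


def build_histogram(
    fits: list[ProfileFit],
    bin_width: float = 0.25,
) -> HeightHistogram:
    """Histogram the amplitudes of accepted profile fits."""
    heights = np.array([f.amplitude for f in fits if f.accepted], dtype=float)
    if len(heights) == 0:
        raise FitFailureError("no accepted profile fits to histogram")
    if len(heights) < 100:
        warnings.warn(
            f"only {len(heights)} accepted fits; >= 100 recommended for a stable histogram"
        )
    lo = np.floor(heights.min() / bin_width) * bin_width
    hi = np.ceil(heights.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(heights, bins=edges)
    return HeightHistogram(bin_edges=edges, counts=counts, n_profiles=len(heights))


def _mixture(x, params):
    n = len(params) // 3
    y = np.zeros_like(x)
    for k in range(n):
        a, mu, sd = params[3 * k: 3 * k + 3]
        y = y + a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def _params_from_locs(x, y, locs, sds):
    params = []
    for mu, sd in zip(locs, sds):
        a0 = max(float(np.interp(mu, x, y)), 1.0)
        params.extend([a0, float(mu), float(sd)])
    return np.array(params)


def _initial_guesses(x, y, n_peaks, bin_width):
    """Candidate starting points: visible peaks of the smoothed histogram,
    k-means partitions of the underlying values, and count quantiles.

    The fit is restarted from each candidate and the best (lowest weighted
    RSS) solution wins; with a lumpy histogram a single initialization is
    unreliable.
    """
    guesses = []
    span = x[-1] - x[0]
    default_sd = max(span / (4.0 * n_peaks), bin_width)

    for win in (3, 7):
        smooth = np.convolve(y.astype(float), np.ones(win) / win, mode="same")
        idx, props = find_peaks(smooth, prominence=0.02 * max(smooth.max(), 1.0))
        if len(idx) >= n_peaks:
            order = np.argsort(props["prominences"])[::-1]
            locs = sorted(x[idx[order[:n_peaks]]])
            guesses.append(_params_from_locs(x, y, locs, [default_sd] * n_peaks))

    # pseudo-sample reconstructed from bin counts for k-means / quantiles
    vals = np.repeat(x, np.maximum(y, 0).astype(int))
    if len(vals) >= n_peaks * 2:
        from scipy.cluster.vq import kmeans2

        for km_seed in range(4):
            try:
                cent, lab = kmeans2(vals, n_peaks, seed=km_seed, minit="++")
            except Exception:
                continue
            order = np.argsort(cent.ravel())
            locs, sds = [], []
            for ci in order:
                locs.append(float(cent.ravel()[ci]))
                members = vals[lab == ci]
                sds.append(max(float(np.std(members)) if len(members) > 1 else default_sd,
                               bin_width))
            guesses.append(_params_from_locs(x, y, locs, sds))
        qs = np.quantile(vals, np.linspace(0.5 / n_peaks, 1 - 0.5 / n_peaks, n_peaks))
        guesses.append(_params_from_locs(x, y, qs, [default_sd] * n_peaks))
    if not guesses:
        locs = np.linspace(x[0] + span / 4, x[-1] - span / 4, n_peaks)
        guesses.append(_params_from_locs(x, y, locs, [default_sd] * n_peaks))
    return guesses


def _fit_n(x, y, w, n_peaks, bin_width):
    span = x[-1] - x[0]
    lb, ub = [], []
    for _ in range(n_peaks):
        lb.extend([1e-6, x[0], bin_width / 2.0])
        ub.extend([np.inf, x[-1], span / 3.0])
    best = None
    for p0 in _initial_guesses(x, y, n_peaks, bin_width):
        p0 = np.clip(p0, lb, ub)
        try:
            res = least_squares(
                lambda p: (_mixture(x, p) - y) * w,
                p0,
                bounds=(lb, ub),
                xtol=1e-12,
                ftol=1e-12,
                max_nfev=20_000,
            )
        except Exception:
            continue
        rss = float(np.sum(((_mixture(x, res.x) - y) * w) ** 2))
        if best is None or rss < best[1]:
            best = (res.x, rss)
    if best is None:
        raise FitFailureError(f"mixture fit with {n_peaks} components failed")
    return best


def fit_multipeak(
    hist: HeightHistogram,
    n_peaks: int | None = None,
    max_peaks: int = 6,
) -> PeakMixtureFit:
    """Fit a sum of normal components to histogram counts.

    Counts are weighted by 1/sqrt(count) (Poisson-motivated).  With
    ``n_peaks`` unset, 1..``max_peaks`` components are tried and the AICc
    selects the model.  Components whose means fall within half the larger
    SD of each other are merged with a warning.
    """
    x = hist.centers
    y = hist.counts.astype(float)
    if np.count_nonzero(y) < 5:
        raise FitFailureError("histogram must have at least 5 occupied bins")
    bin_width = float(np.diff(hist.bin_edges).mean())
    w = 1.0 / np.sqrt(np.maximum(y, 1.0))

    candidates = [n_peaks] if n_peaks is not None else list(range(1, max_peaks + 1))
    best = None
    n_pts = len(x)
    for n in candidates:
        if 3 * n >= n_pts:
            continue
        try:
            params, rss = _fit_n(x, y, w, n, bin_width)
        except Exception:
            continue
        k = 3 * n
        aicc = n_pts * np.log(max(rss, 1e-12) / n_pts) + 2 * k
        if n_pts - k - 1 > 0:
            aicc += 2 * k * (k + 1) / (n_pts - k - 1)
        else:
            aicc = np.inf
        if best is None or aicc < best[2]:
            best = (n, params, aicc, rss)
    if best is None:
        raise FitFailureError("multi-peak fit failed for every component count")

    n, params, aicc, rss = best
    comps = sorted(
        [(float(params[3 * k]), float(params[3 * k + 1]), float(params[3 * k + 2]))
         for k in range(n)],
        key=lambda c: c[1],
    )
    comps = _merge_degenerate(comps)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    gof = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    return PeakMixtureFit(peaks=comps, n_peaks=len(comps), gof=gof, aicc=float(aicc))


def _merge_degenerate(comps):
    """Merge components whose means are closer than half the larger SD."""
    merged = list(comps)
    changed = True
    while changed and len(merged) > 1:
        changed = False
        for i in range(len(merged) - 1):
            a1, m1, s1 = merged[i]
            a2, m2, s2 = merged[i + 1]
            if abs(m2 - m1) < 0.5 * max(s1, s2):
                warnings.warn(
                    f"merging degenerate components at {m1:.2f} and {m2:.2f} nm"
                )
                wsum = a1 * s1 + a2 * s2  # area-proportional weights
                mu = (m1 * a1 * s1 + m2 * a2 * s2) / wsum
                sd = max(s1, s2)
                merged[i] = (a1 + a2, mu, sd)
                del merged[i + 1]
                changed = True
                break
    return merged
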