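"""End-to-end AFM morphometry: flatten -> trace -> profiles -> histogram."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .afm import (
    AssemblyModel,
    HeightMap,
    assign_fibril_types,
    build_histogram,
    estimate_normals,
    extract_profiles,
    fit_multipeak,
    fit_profile,
    flatten_scanlines,
    trace_ridges,
)

__all__ = ["AfmAnalysis", "analyze_heightmap"]


@dataclass
class AfmAnalysis:
    """All intermediate and final products of one AFM morphometry run."""

    heightmap: HeightMap
    paths: list
    profiles: list
    fits: list
    histogram: object
    mixture: object
    assignments: list
    warnings: list[str] = field(default_factory=list)

    @property
    def accepted_fits(self):
        return [f for f in self.fits if f.accepted]

    def summary(self) -> dict:
        acc = self.accepted_fits
        return {
            "n_paths": len(self.paths),
            "n_profiles": len(self.profiles),
            "n_accepted": len(acc),
            "median_r": float(np.median([f.r for f in acc])) if acc else None,
            "peaks": [
                {"amplitude": a, "mean_nm": m, "sd_nm": s}
                for a, m, s in self.mixture.peaks
            ] if self.mixture else [],
            "assignments": [
                {"peak_mean_nm": a.peak_mean, "labels": a.labels, "predicted_nm": a.predicted}
                for a in self.assignments
            ],
        }


def analyze_heightmap(
    hmap: HeightMap,
    flatten_order: int = 2,
    seeds=None,
    half_width: float | None = None,
    bin_width: float = 0.25,
    n_peaks: int | None = None,
    rule: str = "sqrt_n",
    h1: float | None = None,
    profile_stride: int = 3,
    min_path_length: int = 12,
    exclusion_radius: float | None = None,
) -> AfmAnalysis:
    """Run the full morphometry pipeline on one topography.

    ``profile_stride`` subsamples ridge points before profiling (adjacent
    cross-sections are nearly redundant); ``h1`` calibrates the assembly
    model and defaults to the lowest resolved peak mean.
    """
    if not hmap.flattened:
        hmap = flatten_scanlines(hmap, order=flatten_order)
    if half_width is None:
        half_width = 12.0 * hmap.pixel_size

    paths = trace_ridges(
        hmap, seeds=seeds, min_length=min_path_length,
        exclusion_radius=exclusion_radius,
    )
    profiles = []
    for path in paths:
        if len(path) < 5:
            continue
        normals = estimate_normals(path)
        sub = extract_profiles(path, normals, hmap, half_width=half_width)
        profiles.extend(sub[::profile_stride])
    fits = [fit_profile(p) for p in profiles]
    accepted = [f for f in fits if f.accepted]
    if not accepted:
        return AfmAnalysis(hmap, paths, profiles, fits, None, None, [],
                           warnings=["no accepted profile fits"])
    hist = build_histogram(fits, bin_width=bin_width)
    mixture = fit_multipeak(hist, n_peaks=n_peaks)
    model = AssemblyModel(h1=h1 if h1 is not None else mixture.means[0], rule=rule)
    assignments = assign_fibril_types(mixture, model)
    return AfmAnalysis(hmap, paths, profiles, fits, hist, mixture, assignments)
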