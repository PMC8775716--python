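"""Ground-truth-labelled synthetic inputs for all three pipelines.

Generates noisy sigmoidal aggregation traces, two-state excess-heat-capacity
thermograms with independent calorimetric and van't Hoff enthalpies, and AFM
topographies containing curved non-crossing fibrils whose ridge heights are
drawn from a normal mixture, on a rough tilted background.  Every generator
is bit-reproducible for a fixed seed, and ground truth is attached for
recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.spatial import cKDTree

from .afm.heightmap import HeightMap
from .afm.tracing import RidgePath
from .dsc import Thermogram, excess_cp_model
from .errors import InvalidSpecError, PlacementError
from .kinetics import KineticTrace, boltzmann

__all__ = [
    "KineticSimSpec",
    "ThermogramSimSpec",
    "AfmBackground",
    "AfmSimSpec",
    "gen_kinetic_trace",
    "gen_thermogram",
    "gen_afm_image",
    "write_trace_csv",
    "write_thermogram_csv",
    "write_heightmap_tiff",
    "write_heightmap_ascii",
    "write_ground_truth_json",
]


# --------------------------------------------------------------------------
# kinetics

@dataclass(frozen=True)
class KineticSimSpec:
    """Parameters of a noisy Boltzmann-sigmoid trace."""

    y1: float
    y2: float
    t_lag: float
    t_half: float
    t_grid: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "t_grid", np.asarray(self.t_grid, dtype=float))
        if not self.t_half > self.t_lag:
            raise InvalidSpecError("t_half must exceed t_lag")
        if self.t_lag < 0:
            raise InvalidSpecError("t_lag must be non-negative")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        if len(self.t_grid) < 5 or not np.all(np.diff(self.t_grid) > 0):
            raise InvalidSpecError("t_grid must be strictly increasing with >= 5 points")


def gen_kinetic_trace(spec: KineticSimSpec) -> KineticTrace:
    """Noisy sigmoid evaluated on the spec grid; truth attached."""
    rng = np.random.default_rng(spec.seed)
    y = boltzmann(spec.t_grid, spec.y1, spec.y2, spec.t_half, spec.t_lag)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=len(y))
    truth = {
        "y1": spec.y1, "y2": spec.y2,
        "t_lag": spec.t_lag, "t_half": spec.t_half,
        "k_agg": 2.0 / (spec.t_half - spec.t_lag),
        "noise_sd": spec.noise_sd, "seed": spec.seed,
    }
    return KineticTrace(t=spec.t_grid.copy(), y=y, label="synthetic", truth=truth)


# --------------------------------------------------------------------------
# DSC

@dataclass(frozen=True)
class ThermogramSimSpec:
    """Parameters of a synthetic two-state thermogram.

    ``baseline_coeffs`` are ascending polynomial coefficients in
    (T - T_d) degC, giving the instrumental baseline in kJ/mol/degC.
    """

    T_d: float
    dH_cal: float
    dH_vH: float
    T_grid: np.ndarray
    baseline_coeffs: tuple = (0.0,)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "T_grid", np.asarray(self.T_grid, dtype=float))
        if self.dH_cal <= 0 or self.dH_vH <= 0:
            raise InvalidSpecError("enthalpies must be positive")
        if len(self.T_grid) < 20 or not np.all(np.diff(self.T_grid) > 0):
            raise InvalidSpecError("T_grid must be strictly increasing with >= 20 points")
        if self.T_grid[0] > self.T_d - 15 or self.T_grid[-1] < self.T_d + 15:
            raise InvalidSpecError("T_grid must bracket T_d by >= 15 degC on each side")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")


def gen_thermogram(spec: ThermogramSimSpec, scan_index: int = 1, scale: float = 1.0) -> Thermogram:
    """Baseline + two-state excess heat capacity + Gaussian noise.

    ``scale`` multiplies the excess term only (used to emulate partial
    reversibility in a rescan).
    """
    rng = np.random.default_rng(spec.seed + (scan_index - 1))
    T = spec.T_grid
    base = np.polynomial.polynomial.polyval(T - spec.T_d, spec.baseline_coeffs)
    cp = base + scale * excess_cp_model(T, spec.T_d, spec.dH_cal, spec.dH_vH)
    if spec.noise_sd > 0:
        cp = cp + rng.normal(0.0, spec.noise_sd, size=len(T))
    truth = {
        "T_d": spec.T_d, "dH_cal": spec.dH_cal * scale, "dH_vH": spec.dH_vH,
        "ratio": spec.dH_vH / spec.dH_cal, "noise_sd": spec.noise_sd, "seed": spec.seed,
    }
    return Thermogram(T=T.copy(), Cp=cp, scan_index=scan_index, label="synthetic", truth=truth)


# --------------------------------------------------------------------------
# AFM topography

@dataclass(frozen=True)
class AfmBackground:
    """Background model: tilt plane + per-scanline bow + white roughness.

    ``tilt`` is (nm per row, nm per col); ``bow_amplitude`` is the SD of the
    per-scanline second-order bow coefficient (nm at the line edges);
    ``roughness_sd`` is the white-noise SD in nm.
    """

    tilt: tuple[float, float] = (0.0, 0.0)
    bow_amplitude: float = 0.0
    roughness_sd: float = 0.0


@dataclass(frozen=True)
class AfmSimSpec:
    """Parameters of a synthetic fibril topography.

    ``populations`` is a list of (mean ridge height nm, SD nm, count);
    ``fibril_width`` gives (mean, SD) of the transverse Gaussian sigma in
    nm; ``length_range`` bounds fibril arc length in nm; ``min_separation``
    is the minimum nm distance between any two centerlines (no crossing).
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 4.0
    populations: tuple = ((2.6, 0.4, 20), (3.7, 0.8, 20), (6.1, 1.1, 20))
    fibril_width: tuple[float, float] = (10.0, 1.0)
    background: AfmBackground = field(default_factory=AfmBackground)
    min_separation: float = 30.0
    length_range: tuple[float, float] = (250.0, 550.0)
    n_waypoints: tuple[int, int] = (4, 8)
    seed: int = 0
    max_tries: int = 300

    def __post_init__(self):
        if min(self.image_shape) < 64:
            raise InvalidSpecError("image must be at least 64x64")
        if self.pixel_size <= 0:
            raise InvalidSpecError("pixel_size must be positive")
        for mean, sd, count in self.populations:
            if mean <= 0 or sd < 0:
                raise InvalidSpecError("population heights must be positive, SDs >= 0")
            if count < 1:
                raise InvalidSpecError("population counts must be >= 1")
        if self.fibril_width[0] <= 0:
            raise InvalidSpecError("fibril width must be positive")


def _fibril_centerline(rng, spec: AfmSimSpec):
    """Cubic spline through jittered waypoints; dense points in pixel units."""
    rows, cols = spec.image_shape
    px = spec.pixel_size
    margin = 4.0 * spec.fibril_width[0] / px + 2.0
    length_nm = rng.uniform(*spec.length_range)
    length_px = length_nm / px
    n_wp = int(rng.integers(spec.n_waypoints[0], spec.n_waypoints[1] + 1))

    r0 = rng.uniform(margin, rows - margin)
    c0 = rng.uniform(margin, cols - margin)
    theta = rng.uniform(0, 2 * np.pi)
    # gentle curvature: small random heading changes between waypoints
    s = np.linspace(0.0, length_px, n_wp)
    headings = theta + np.cumsum(rng.normal(0.0, 0.25, size=n_wp))
    dr = np.cos(headings) * np.gradient(s)
    dc = np.sin(headings) * np.gradient(s)
    wp = np.column_stack([r0 + np.cumsum(dr), c0 + np.cumsum(dc)])
    if (wp[:, 0].min() < margin or wp[:, 0].max() > rows - margin
            or wp[:, 1].min() < margin or wp[:, 1].max() > cols - margin):
        return None
    t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(wp, axis=0), axis=1))])
    if t[-1] <= 0:
        return None
    spl = make_interp_spline(t, wp, k=min(3, n_wp - 1))
    raw = spl(np.arange(0.0, t[-1], 0.25))
    # re-parameterize by true arclength so dense points are ~0.5 px apart
    seg = np.linalg.norm(np.diff(raw, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 1.0:
        return None
    s_uniform = np.arange(0.0, arc[-1], 0.5)
    return np.column_stack([
        np.interp(s_uniform, arc, raw[:, 0]),
        np.interp(s_uniform, arc, raw[:, 1]),
    ])


def _render_fibril(canvas, dense, height, sigma_px):
    """Max-combine a Gaussian-profile fibril into the canvas."""
    rows, cols = canvas.shape
    pad = int(np.ceil(4 * sigma_px)) + 1
    r_lo = max(int(dense[:, 0].min()) - pad, 0)
    r_hi = min(int(dense[:, 0].max()) + pad + 1, rows)
    c_lo = max(int(dense[:, 1].min()) - pad, 0)
    c_hi = min(int(dense[:, 1].max()) + pad + 1, cols)
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    tree = cKDTree(dense)
    d, _ = tree.query(pts, distance_upper_bound=4 * sigma_px)
    finite = np.isfinite(d)
    contrib = np.zeros(len(pts))
    contrib[finite] = height * np.exp(-0.5 * (d[finite] / sigma_px) ** 2)
    patch = contrib.reshape(rr.shape)
    region = canvas[r_lo:r_hi, c_lo:c_hi]
    np.maximum(region, patch, out=region)


def gen_afm_image(spec: AfmSimSpec) -> tuple[HeightMap, list[dict]]:
    """Render non-crossing fibrils on a tilted, bowed, rough background.

    Returns the height map and a ground-truth list with one entry per
    fibril: the drawn ridge height, transverse sigma, population index and
    the true centerline as a :class:`RidgePath`.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape
    px = spec.pixel_size
    canvas = np.zeros((rows, cols), dtype=float)

    # draw heights per population first so counts are exact
    draws = []
    for p_idx, (mean, sd, count) in enumerate(spec.populations):
        for _ in range(count):
            h = -1.0
            while h <= 0:
                h = rng.normal(mean, sd) if sd > 0 else mean
            draws.append((p_idx, h))

    min_sep_px = spec.min_separation / px
    placed_points: list[np.ndarray] = []
    tree = None
    truth = []
    for p_idx, height in draws:
        sigma_nm = -1.0
        while sigma_nm <= 0.3 * spec.fibril_width[0]:
            sigma_nm = (rng.normal(*spec.fibril_width)
                        if spec.fibril_width[1] > 0 else spec.fibril_width[0])
        sigma_px = sigma_nm / px
        dense = None
        for _ in range(spec.max_tries):
            cand = _fibril_centerline(rng, spec)
            if cand is None:
                continue
            if min_sep_px > 0 and tree is not None:
                d, _ = tree.query(cand, distance_upper_bound=min_sep_px)
                if np.any(np.isfinite(d)):
                    continue
            dense = cand
            break
        if dense is None:
            raise PlacementError(p_idx)
        _render_fibril(canvas, dense, height, sigma_px)
        placed_points.append(dense)
        tree = cKDTree(np.vstack(placed_points))
        # centerline subsampled to <= 2 px steps for the RidgePath invariant
        path = RidgePath(dense[:: max(1, int(1.5 / 0.5))])
        truth.append({
            "population": p_idx,
            "height": float(height),
            "sigma_nm": float(sigma_nm),
            "path": path,
        })

    bg = spec.background
    r_idx = np.arange(rows, dtype=float)[:, None]
    c_idx = np.arange(cols, dtype=float)[None, :]
    canvas += bg.tilt[0] * r_idx + bg.tilt[1] * c_idx
    if bg.bow_amplitude > 0:
        xn = (c_idx[0] - (cols - 1) / 2.0) / ((cols - 1) / 2.0)
        bow_coef = rng.normal(0.0, bg.bow_amplitude, size=rows)
        canvas += bow_coef[:, None] * xn[None, :] ** 2
    if bg.roughness_sd > 0:
        canvas += rng.normal(0.0, bg.roughness_sd, size=canvas.shape)

    hmap = HeightMap(
        heights=canvas, pixel_size=px, label="synthetic",
        metadata={"seed": spec.seed, "n_fibrils": len(truth)},
    )
    return hmap, truth


# --------------------------------------------------------------------------
# writers (plain-text first; TIFF for interoperability)

def write_trace_csv(trace: KineticTrace, path: str | Path) -> None:
    header = "t_min,signal_au"
    np.savetxt(path, np.column_stack([trace.t, trace.y]),
               delimiter=",", header=header, comments="")


def write_thermogram_csv(tg: Thermogram, path: str | Path) -> None:
    header = "T_degC,Cp_kJ_per_mol_degC"
    np.savetxt(path, np.column_stack([tg.T, tg.Cp]),
               delimiter=",", header=header, comments="")


def _write_sidecar(path: Path, pixel_size: float) -> None:
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"pixel_size_nm": pixel_size}))


def write_heightmap_tiff(hmap: HeightMap, path: str | Path) -> None:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, hmap.heights.astype(np.float32))
    _write_sidecar(path, hmap.pixel_size)


def write_heightmap_ascii(hmap: HeightMap, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, hmap.heights, fmt="%.6f")
    _write_sidecar(path, hmap.pixel_size)


def write_ground_truth_json(truth: list[dict], path: str | Path) -> None:
    payload = [
        {
            "population": t["population"],
            "height_nm": t["height"],
            "sigma_nm": t["sigma_nm"],
            "centerline_px": t["path"].points.tolist(),
        }
        for t in truth
    ]
    Path(path).write_text(json.dumps(payload))
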