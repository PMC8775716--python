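"""Aggregation-kinetics analysis.

Normalizes fluorescence / ellipticity traces and fits the Boltzmann sigmoid

    y(t) = y1 + (y2 - y1) / (1 + exp(-2 (t - t_half) / (t_half - t_lag)))

to extract the lag time ``t_lag``, half-time ``t_half`` and the apparent
aggregation rate constant ``k_agg = 2 / (t_half - t_lag)``.  The same code
path serves thioflavin-T fluorescence kinetics and normalized CD
ellipticity kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateTraceError, FitFailureError

__all__ = [
    "KineticTrace",
    "BoltzmannFit",
    "boltzmann",
    "normalize_trace",
    "fit_boltzmann",
    "compute_kagg",
    "fit_quality",
]


@dataclass
class KineticTrace:
    """A timestamped aggregation signal.

    Parameters
    ----------
    t : array
        Sampling times in minutes, strictly increasing, length >= 5.
    y : array
        Signal values (arbitrary units or mean-residue ellipticity).
    label : str
        Free-text description.
    normalized : str or None
        Normalization state: ``None`` (raw), ``"minmax"`` or
        ``"percent-of-max"``.
    truth : dict or None
        Ground-truth generating parameters when the trace is synthetic.
    """

    t: np.ndarray
    y: np.ndarray
    label: str = ""
    normalized: str | None = None
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.ndim != 1 or len(self.t) != len(self.y):
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(self.t) < 5:
            raise ValueError("a kinetic trace needs at least 5 points")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class BoltzmannFit:
    """Result of a Boltzmann-sigmoid least-squares fit.

    ``k_agg`` is always derived from the fitted times as
    ``2 / (t_half - t_lag)``; ``r`` is the Pearson correlation between the
    data and the fitted model.
    """

    y1: float
    y2: float
    t_half: float
    t_lag: float
    k_agg: float
    r: float
    stderr: dict[str, float]
    covariance: np.ndarray = field(repr=False)

    def __post_init__(self):
        if not self.t_half > self.t_lag:
            raise FitFailureError(
                f"fitted t_half ({self.t_half:g}) must exceed t_lag ({self.t_lag:g})"
            )
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation coefficient outside [-1, 1]")

    def predict(self, t: np.ndarray) -> np.ndarray:
        return boltzmann(np.asarray(t, float), self.y1, self.y2, self.t_half, self.t_lag)

    def as_dict(self) -> dict:
        return {
            "y1": self.y1,
            "y2": self.y2,
            "t_half": self.t_half,
            "t_lag": self.t_lag,
            "k_agg": self.k_agg,
            "r": self.r,
            "stderr": dict(self.stderr),
        }


def boltzmann(t, y1: float, y2: float, t_half: float, t_lag: float):
    """Boltzmann sigmoid parameterized by lag and half times."""
    t = np.asarray(t, dtype=float)
    delta = t_half - t_lag
    if delta <= 0:
        raise ValueError("t_half must exceed t_lag")
    return y1 + (y2 - y1) / (1.0 + np.exp(-2.0 * (t - t_half) / delta))


def normalize_trace(trace: KineticTrace, mode: str = "minmax") -> KineticTrace:
    """Normalize a trace.

    ``minmax`` maps y to [0, 1] via (y - y_min)/(y_max - y_min); this is the
    normalization applied to CD ellipticity kinetics.  ``percent-of-max``
    maps y to y / y_max * 100, as used for ThT fluorescence relative to the
    mature-aggregate plateau.
    """
    y = trace.y
    if mode == "minmax":
        ymin, ymax = float(np.min(y)), float(np.max(y))
        if ymax == ymin:
            raise DegenerateTraceError("constant trace cannot be minmax-normalized")
        ynew = (y - ymin) / (ymax - ymin)
    elif mode == "percent-of-max":
        ymax = float(np.max(y))
        if ymax == 0:
            raise DegenerateTraceError("trace maximum is zero")
        ynew = y / ymax * 100.0
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(trace, y=ynew, normalized=mode)


def compute_kagg(t_lag: float, t_half: float) -> float:
    """Aggregation rate constant ``2 / (t_half - t_lag)`` in 1/min."""
    if not t_half > t_lag:
        raise ValueError(f"t_half ({t_half:g}) must exceed t_lag ({t_lag:g})")
    return 2.0 / (t_half - t_lag)


def fit_quality(trace: KineticTrace, fit: BoltzmannFit) -> float:
    """Pearson correlation between observed y and the model prediction."""
    pred = fit.predict(trace.t)
    return pearson(trace.y, pred)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0 if np.allclose(a - a.mean(), b - b.mean()) else 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return min(max(r, -1.0), 1.0)


def fit_boltzmann(
    trace: KineticTrace,
    max_nfev: int = 10_000,
    tol: float = 1e-10,
) -> BoltzmannFit:
    """Fit the Boltzmann sigmoid to a trace by bounded least squares.

    The geometric constraint ``t_half > t_lag`` is enforced by fitting
    ``log(t_half - t_lag)`` instead of ``t_lag`` directly; starting values
    are data-driven (extrema and mid-signal crossing).
    """
    t, y = trace.t, trace.y
    if np.ptp(y) <= 0:
        raise FitFailureError("signal has zero range; nothing to fit")

    # data-driven initialization
    y1_0 = float(np.min(y))
    y2_0 = float(np.max(y))
    mid = 0.5 * (y1_0 + y2_0)
    t_half_0 = float(t[np.argmin(np.abs(y - mid))])
    delta_0 = float(np.ptp(t)) / 10.0
    if delta_0 <= 0:
        delta_0 = 1.0
    p0 = np.array([y1_0, y2_0, t_half_0, np.log(delta_0)])

    def residuals(p):
        y1, y2, t_half, logd = p
        delta = np.exp(logd)
        return y1 + (y2 - y1) / (1.0 + np.exp(-2.0 * (t - t_half) / delta)) - y

    result = least_squares(
        residuals,
        p0,
        method="trf",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_nfev,
    )
    if not result.success:
        raise FitFailureError(f"Boltzmann fit did not converge: {result.message}")

    y1, y2, t_half, logd = result.x
    delta = float(np.exp(logd))
    t_lag = float(t_half - delta)
    if t_lag < -1e-9 * max(1.0, abs(t_half)):
        # lag times are physical times; a slightly negative estimate from
        # noise is clamped, a grossly negative one is a failed fit
        if t_lag < -0.05 * np.ptp(t):
            raise FitFailureError(f"fitted t_lag is negative ({t_lag:g} min)")

    # covariance via the Jacobian at the solution; transform the log-delta
    # coordinate back to (t_half, t_lag) by the delta method
    dof = max(len(t) - 4, 1)
    resid = result.fun
    s_sq = float(resid @ resid) / dof
    try:
        jtj_inv = np.linalg.pinv(result.jac.T @ result.jac)
    except np.linalg.LinAlgError:  # pragma: no cover
        jtj_inv = np.full((4, 4), np.nan)
    cov_internal = s_sq * jtj_inv
    # parameters (y1, y2, t_half, t_lag): t_lag = t_half - exp(logd)
    J = np.eye(4)
    J[3, 3] = -delta  # d t_lag / d logd
    J[3, 2] = 1.0     # d t_lag / d t_half
    cov = J @ cov_internal @ J.T
    err = np.sqrt(np.clip(np.diag(cov), 0, None))
    stderr = {"y1": err[0], "y2": err[1], "t_half": err[2], "t_lag": err[3]}

    model_y = y + resid
    fit = BoltzmannFit(
        y1=float(y1),
        y2=float(y2),
        t_half=float(t_half),
        t_lag=t_lag,
        k_agg=compute_kagg(t_lag, t_half),
        r=pearson(y, model_y),
        stderr=stderr,
        covariance=cov,
    )
    return fit
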