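"""Two-state analysis of differential scanning calorimetry thermograms.

The excess heat capacity of a two-state transition with independent
calorimetric and van't Hoff enthalpies (the MicroCal "non-two-state" model)
is

    Cp_exc(T) = dH_cal * dH_vH / (R T^2) * K / (1 + K)^2
    K(T)      = exp(-(dH_vH / R) * (1/T - 1/T_m))

with T in Kelvin, T_m the transition midpoint and R the molar gas constant.
The transition progress is alpha = K/(1+K), so Cp_exc = dH_cal * d(alpha)/dT
and the integral of Cp_exc over the full transition equals dH_cal exactly.
All public I/O uses degrees Celsius; Kelvin is internal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import BaselineError, FitFailureError
from .kinetics import pearson

__all__ = [
    "R_GAS",
    "Thermogram",
    "TwoStateFit",
    "excess_cp_model",
    "subtract_baseline",
    "integrate_enthalpy",
    "fit_two_state",
    "reversibility",
    "enthalpy_ratio",
]

#: molar gas constant, kJ/(mol K)
R_GAS = 8.31446261815324e-3

_KELVIN = 273.15


@dataclass
class Thermogram:
    """Temperature--heat-capacity series.

    T in degrees Celsius (strictly increasing, >= 20 points), Cp in
    kJ/mol/degC.  ``scan_index`` distinguishes the first heating (1) from
    the rescan (2) used for reversibility.
    """

    T: np.ndarray
    Cp: np.ndarray
    scan_index: int = 1
    label: str = ""
    baseline_subtracted: bool = False
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.Cp = np.asarray(self.Cp, dtype=float)
        if self.T.ndim != 1 or len(self.T) != len(self.Cp):
            raise ValueError("T and Cp must be 1-D arrays of equal length")
        if len(self.T) < 20:
            raise ValueError("a thermogram needs at least 20 points")
        if not np.all(np.diff(self.T) > 0):
            raise ValueError("T must be strictly increasing")

    def __len__(self) -> int:
        return len(self.T)


@dataclass
class TwoStateFit:
    """Fitted two-state parameters and derived quantities."""

    T_d: float            # degC
    dH_cal: float         # kJ/mol, from integration
    dH_vH: float          # kJ/mol, from transition sharpness
    ratio: float          # dH_vH / dH_cal
    stderr: dict[str, float]
    r: float
    reversibility: float | None = None  # percent, set when a rescan is analyzed

    def __post_init__(self):
        if self.dH_cal <= 0 or self.dH_vH <= 0:
            raise FitFailureError("fitted enthalpies must be positive")
        if self.reversibility is not None and not 0 <= self.reversibility <= 110:
            raise ValueError("reversibility outside the plausible 0-110% range")

    def as_dict(self) -> dict:
        d = {
            "T_d": self.T_d,
            "dH_cal": self.dH_cal,
            "dH_vH": self.dH_vH,
            "ratio": self.ratio,
            "r": self.r,
            "stderr": dict(self.stderr),
        }
        if self.reversibility is not None:
            d["reversibility"] = self.reversibility
        return d


def excess_cp_model(T, T_d: float, dH_cal: float, dH_vH: float):
    """Excess heat capacity (kJ/mol/degC) at temperature(s) T in degC."""
    if T_d <= -_KELVIN:
        raise ValueError("T_d below absolute zero")
    if dH_cal <= 0 or dH_vH <= 0:
        raise ValueError("enthalpies must be positive")
    TK = np.asarray(T, dtype=float) + _KELVIN
    Tm = T_d + _KELVIN
    lnK = -(dH_vH / R_GAS) * (1.0 / TK - 1.0 / Tm)
    # K/(1+K)^2 = 0.25 sech^2(lnK/2); overflow-safe sech via exp(-|x|)
    e = np.exp(-np.abs(0.5 * lnK))
    sech_half = 2.0 * e / (1.0 + e * e)
    return dH_cal * dH_vH / (R_GAS * TK**2) * 0.25 * sech_half**2


def _flanking_windows(T, Cp, min_pts: int = 3, n_iter: int = 12):
    """Flat pre- and post-transition windows by robust one-sided masking.

    A line is fitted iteratively with points far above it (the endotherm
    is an upward excursion) excluded via a median + MAD threshold; the
    surviving points split at the peak give the flanking windows.
    """
    Tn = (T - T.mean()) / max(T.std(), 1.0)
    mask = np.ones(len(T), dtype=bool)
    coef = np.polyfit(Tn, Cp, 1)
    for _ in range(n_iter):
        resid = Cp - np.polyval(coef, Tn)
        r_bg = resid[mask]
        med = np.median(r_bg)
        sigma = 1.4826 * np.median(np.abs(r_bg - med))
        if sigma <= 0:
            new_mask = resid <= med + max(1e-12, 1e-9 * np.ptp(Cp))
        else:
            new_mask = resid <= med + 2.5 * sigma
        if new_mask.sum() < 2 * min_pts:
            break
        if np.array_equal(new_mask, mask):
            mask = new_mask
            break
        mask = new_mask
        coef = np.polyfit(Tn[mask], Cp[mask], 1)
    peak = int(np.argmax(Cp - np.polyval(coef, Tn)))
    idx = np.arange(len(T))
    left = mask & (idx < peak)
    right = mask & (idx > peak)
    if left.sum() < min_pts or right.sum() < min_pts:
        raise BaselineError(
            f"no flat flanking regions found (left {int(left.sum())} pts, "
            f"right {int(right.sum())} pts, need >= {min_pts} each)"
        )
    return left, right


def subtract_baseline(tg: Thermogram, method: str = "progress") -> Thermogram:
    """Subtract the instrumental baseline from a thermogram.

    ``linear`` subtracts the least-squares line through the flat pre- and
    post-transition windows.  ``progress`` (default) interpolates between
    the separately fitted pre- and post-baseline lines with the transition
    progress (cumulative fraction of the excess heat) as the weight.
    """
    T, Cp = tg.T, tg.Cp
    if np.ptp(Cp) == 0:
        # flat input (e.g. all zero): baseline is the constant itself
        return replace(tg, Cp=Cp - Cp[0], baseline_subtracted=True)
    left, right = _flanking_windows(T, Cp)

    if method == "linear":
        both = left | right
        coef = np.polyfit(T[both], Cp[both], 1)
        base = np.polyval(coef, T)
    elif method == "progress":
        pre = np.polyval(np.polyfit(T[left], Cp[left], 1), T)
        post = np.polyval(np.polyfit(T[right], Cp[right], 1), T)
        # first-pass excess over the chord between window midpoints
        both = left | right
        chord = np.polyval(np.polyfit(T[both], Cp[both], 1), T)
        excess = np.clip(Cp - chord, 0.0, None)
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (excess[1:] + excess[:-1]) * np.diff(T))]
        )
        total = cum[-1]
        alpha = cum / total if total > 0 else np.zeros_like(cum)
        base = (1.0 - alpha) * pre + alpha * post
    else:
        raise ValueError(f"unknown baseline method {method!r}")

    return replace(tg, Cp=Cp - base, baseline_subtracted=True)


def integrate_enthalpy(tg: Thermogram) -> float:
    """Calorimetric enthalpy (kJ/mol): trapezoidal integral of Cp over T."""
    return float(np.trapezoid(tg.Cp, tg.T))


def enthalpy_ratio(dH_cal: float, dH_vH: float) -> float:
    """Cooperativity ratio dH_vH / dH_cal."""
    if dH_cal <= 0 or dH_vH <= 0:
        raise ValueError("enthalpies must be positive")
    return dH_vH / dH_cal


def reversibility(first: Thermogram, second: Thermogram) -> float:
    """Percent reversibility: 100 x dH_cal(rescan) / dH_cal(first scan)."""
    h1 = integrate_enthalpy(first)
    h2 = integrate_enthalpy(second)
    if h1 <= 0:
        raise ValueError("first-scan enthalpy must be positive")
    return 100.0 * h2 / h1


def fit_two_state(
    tg: Thermogram,
    rescan: Thermogram | None = None,
    max_nfev: int = 10_000,
) -> TwoStateFit:
    """Fit the independent-enthalpies two-state model to a thermogram.

    The input must be baseline-subtracted.  dH_cal is reported from the
    trapezoidal integral (the calorimetric route); the non-linear fit
    supplies T_d and dH_vH.  When ``rescan`` is given, reversibility is
    computed from the ratio of integrated enthalpies.
    """
    if not tg.baseline_subtracted:
        warnings.warn("thermogram not marked baseline-subtracted; fitting anyway")
    T, Cp = tg.T, tg.Cp

    dH_cal0 = integrate_enthalpy(tg)
    if dH_cal0 <= 0:
        raise FitFailureError("integrated enthalpy is non-positive")
    i_pk = int(np.argmax(Cp))
    T_d0 = float(T[i_pk])
    Cp_pk = float(Cp[i_pk])
    # at T = T_d the model gives Cp = dH_cal dH_vH / (4 R Tm^2)
    dH_vH0 = max(4.0 * R_GAS * (T_d0 + _KELVIN) ** 2 * Cp_pk / dH_cal0, 10.0)

    def residuals(p):
        T_d, dH_cal, dH_vH = p
        return excess_cp_model(T, T_d, dH_cal, dH_vH) - Cp

    lb = [T[0], 1e-6, 1e-6]
    ub = [T[-1], np.inf, np.inf]
    res = least_squares(
        residuals,
        [T_d0, dH_cal0, dH_vH0],
        bounds=(lb, ub),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    if not res.success:
        raise FitFailureError(f"two-state fit did not converge: {res.message}")
    T_d, dH_cal_fit, dH_vH = res.x

    model = Cp + res.fun
    r = pearson(Cp, model)
    if r < 0.9:
        raise FitFailureError(
            f"residual structure too large for a single two-state transition (r={r:.3f})"
        )

    dof = max(len(T) - 3, 1)
    s_sq = float(res.fun @ res.fun) / dof
    cov = s_sq * np.linalg.pinv(res.jac.T @ res.jac)
    err = np.sqrt(np.clip(np.diag(cov), 0, None))
    stderr = {"T_d": err[0], "dH_cal": err[1], "dH_vH": err[2]}

    rev = None
    if rescan is not None:
        rev = reversibility(tg, rescan)

    return TwoStateFit(
        T_d=float(T_d),
        dH_cal=dH_cal0,
        dH_vH=float(dH_vH),
        ratio=enthalpy_ratio(dH_cal0, float(dH_vH)),
        stderr=stderr,
        r=r,
        reversibility=rev,
    )
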