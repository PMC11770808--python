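"""Classical enzymology fits.

Progress-curve extraction of the initial velocity under product inhibition,
Michaelis-Menten fits of v0 vs substrate, 1:1 binding isotherms, and
fold-change utilities.

The product-inhibited progress curve is modeled as the exponential-saturation
form

    [P](t) = v0 (1 - exp(-eta t)) / eta,

whose initial slope is v0 and whose nonlinearity factor eta quantifies the
product inhibition ([P] -> v0/eta as t -> inf; eta -> 0 recovers the
uninhibited line v0 t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synth import progress_curve


@dataclass
class ProgressFit:
    v0: float
    eta: float
    v0_se: float
    eta_se: float
    residual_norm: float


@dataclass
class MMFit:
    v_max: float
    k_m: float
    v_max_se: float
    k_m_se: float
    identifiable: bool = True


@dataclass
class BindingFit:
    kd: float
    kd_se: float
    saturated: bool = True


def _progress_model(t, v0, eta):
    return progress_curve(t, v0, max(eta, 0.0))


def fit_progress_curve(tc: pd.DataFrame) -> ProgressFit:
    """Fit [P](t) for (v0, eta) by nonlinear least squares.

    Expects columns ``t`` and ``P`` with [P](0) ~ 0 and at least five
    points.  The fitted initial slope equals v0; the uninhibited
    extrapolation is the line v0*t.
    """
    t = tc["t"].to_numpy(dtype=float)
    p = tc["P"].to_numpy(dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    slope = np.polyfit(t, p, 1)[0]
    if np.any(np.diff(p) < -5 * max(1e-12, np.std(np.diff(p)))):
        warnings.warn("progress curve strongly non-monotonic; check the data")
    p0 = (max(slope, 1e-12), 1e-3 / max(t[-1], 1e-12))
    try:
        popt, pcov = curve_fit(
            _progress_model, t, p, p0=p0,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20_000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"progress-curve fit did not converge: {err}") from err
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    resid = p - _progress_model(t, *popt)
    return ProgressFit(float(popt[0]), float(popt[1]), float(se[0]), float(se[1]),
                       float(np.linalg.norm(resid)))


def michaelis_menten(s, v_max, k_m):
    s = np.asarray(s, dtype=float)
    return v_max * s / (k_m + s)


def fit_michaelis_menten(data: pd.DataFrame, substrate: str = "s", velocity: str = "v0",
                         sem: str | None = None) -> MMFit:
    """Weighted nonlinear least squares of v = v_max S / (K_M + S).

    Flags the fit as unidentifiable when the design has no curvature (all
    substrate levels far below or far above the fitted K_M).
    """
    s = data[substrate].to_numpy(dtype=float)
    v = data[velocity].to_numpy(dtype=float)
    if len(s) < 4:
        raise ValueError("need at least 4 substrate levels")
    sigma = data[sem].to_numpy(dtype=float) if sem else None
    p0 = (v.max(), np.median(s))
    popt, pcov = curve_fit(michaelis_menten, s, v, p0=p0, sigma=sigma,
                           bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20_000)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    identifiable = bool(s.min() < popt[1] < s.max())
    return MMFit(float(popt[0]), float(popt[1]), float(se[0]), float(se[1]), identifiable)


def binding_isotherm(ligand, kd):
    ligand = np.asarray(ligand, dtype=float)
    return ligand / (kd + ligand)


def fit_binding(data: pd.DataFrame, ligand: str = "ligand_um",
                fraction: str = "fraction_bound") -> BindingFit:
    """Least squares of the ligand-excess 1:1 isotherm f = L / (Kd + L)."""
    L = data[ligand].to_numpy(dtype=float)
    f = data[fraction].to_numpy(dtype=float)
    popt, pcov = curve_fit(binding_isotherm, L, f, p0=(np.median(L),),
                           bounds=(1e-12, np.inf), maxfev=20_000)
    kd = float(popt[0])
    kd_se = float(np.sqrt(max(pcov[0, 0], 0.0)))
    saturated = bool(L.max() >= 2 * kd)
    if not saturated:
        warnings.warn("isotherm does not reach saturation; Kd poorly constrained")
    return BindingFit(kd, kd_se, saturated)


def fold_change(kd_b: float, kd_a: float) -> float:
    """Ratio kd_b / kd_a (e.g. Kd at 0.8 M urea over Kd at 0 M)."""
    if kd_b <= 0 or kd_a <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_b / kd_a
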