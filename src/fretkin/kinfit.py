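"""Global chi-square fitting of the turnover model to velocity data.

The free parameters {k_cat, k_r_T, k_r_M} are shared across urea
concentrations (the shielded active site makes them urea-invariant), while
the dissociation constants and the per-species conformational rates are
fixed inputs per urea level (measured by MST and smFRET respectively).
Rates are fitted on a log10 scale because they span decades; the bounded
least-squares minimization is restarted from a deterministic log grid.
Confidence intervals come from profile likelihood: each parameter is
stepped over a grid, the others re-optimized, and the interval is read off
where the chi-square increase crosses the one-parameter threshold
(Delta chi2 = 1 for 68%, 3.84 for 95%).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinscheme import KineticScheme, velocity

FREE_PARAMS = ("k_cat", "k_r_T", "k_r_M")
LOG_BOUNDS = (-1.0, 7.0)  # log10 of rate in 1/s


@dataclass
class FitResult:
    params: dict  # fitted {k_cat, k_r_T, k_r_M} in 1/s
    chi2: float
    chi2_red: float
    n_obs: int
    n_free: int
    fixed_schemes: dict  # urea -> KineticScheme template (free params overwritten)
    datasets: pd.DataFrame
    starts: list = field(default_factory=list)  # (start, chi2) log10 audit trail
    profiles: dict = field(default_factory=dict)
    conf_intervals: dict = field(default_factory=dict)
    seed: int | None = None


def _scheme_with(template: KineticScheme, params: dict) -> KineticScheme:
    return replace(template, **params)


def model_velocities(params: dict, data: pd.DataFrame, fixed_schemes: dict) -> np.ndarray:
    """Model velocities row by row (urea selects the fixed-input scheme)."""
    out = np.empty(len(data))
    cache = {}
    for k, (urea, atp, amp) in enumerate(zip(data["urea_m"], data["atp_um"], data["amp_um"])):
        key = (urea, atp, amp)
        if key not in cache:
            scheme = _scheme_with(fixed_schemes[urea], params)
            cache[key] = velocity(scheme, atp, amp)
        out[k] = cache[key]
    return out


def chi2(params: dict, data: pd.DataFrame, fixed_schemes: dict):
    """Weighted chi-square and reduced chi-square of the model vs the data."""
    sem = data["sem"].to_numpy(dtype=float)
    if np.any(sem <= 0):
        raise ValueError("every velocity point needs SEM > 0; supply weights")
    resid = (model_velocities(params, data, fixed_schemes) - data["v_obs"].to_numpy()) / sem
    c2 = float(np.sum(resid**2))
    dof = len(data) - len(FREE_PARAMS)
    return c2, c2 / dof if dof > 0 else np.nan


def _residuals(logx: np.ndarray, data, fixed_schemes, free_names) -> np.ndarray:
    params = {name: 10.0**v for name, v in zip(free_names, logx)}
    sem = data["sem"].to_numpy(dtype=float)
    return (model_velocities(params, data, fixed_schemes) - data["v_obs"].to_numpy()) / sem


def global_fit(
    data: pd.DataFrame,
    fixed_schemes: dict,
    free: tuple = FREE_PARAMS,
    starts: list | None = None,
    seed: int | None = None,
) -> FitResult:
    """Multi-start bounded least-squares fit of the shared rate constants.

    ``data`` must carry columns atp_um, amp_um, urea_m, v_obs, sem;
    ``fixed_schemes`` maps each urea level to a scheme holding that level's
    fixed inputs.  All starts are logged in the result.
    """
    if np.any(data["sem"].to_numpy(dtype=float) <= 0):
        raise ValueError("every velocity point needs SEM > 0; supply weights")
    missing = set(data["urea_m"]) - set(fixed_schemes)
    if missing:
        raise ValueError(f"no fixed inputs for urea levels {sorted(missing)}")
    if starts is None:
        starts = [np.array(s) for s in itertools.product((2.0, 4.0), repeat=len(free))]
    best = None
    trail = []
    for x0 in starts:
        sol = least_squares(
            _residuals, x0, bounds=LOG_BOUNDS, args=(data, fixed_schemes, free),
            xtol=1e-10, ftol=1e-12, method="trf",
        )
        trail.append((list(map(float, x0)), float(sol.cost * 2)))
        if best is None or sol.cost < best.cost:
            best = sol
    params = {name: 10.0**v for name, v in zip(free, best.x)}
    c2, c2r = chi2(params, data, fixed_schemes)
    return FitResult(
        params=params, chi2=c2, chi2_red=c2r, n_obs=len(data), n_free=len(free),
        fixed_schemes=fixed_schemes, datasets=data, starts=trail, seed=seed,
    )


def profile_confidence(
    fit: FitResult,
    param: str,
    grid: np.ndarray | None = None,
    delta_chi2: float = 1.0,
    span: float = 0.3,
    n_grid: int = 13,
    max_extend: int = 4,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Profile likelihood of one parameter with re-optimized nuisances.

    Returns the profile table and the confidence interval where the
    chi-square increase crosses ``delta_chi2``; an unidentifiable side is
    reported as -inf/+inf (one-sided profile).
    """
    others = [p for p in FREE_PARAMS if p != param]
    data, schemes = fit.datasets, fit.fixed_schemes
    center = np.log10(fit.params[param])
    if grid is None:
        grid = np.linspace(center - span, center + span, n_grid)
    grid = np.sort(np.asarray(grid, dtype=float))

    def profile_point(logv, x0):
        def resid(logx):
            params = {param: 10.0**logv}
            params.update({n: 10.0**v for n, v in zip(others, logx)})
            sem = data["sem"].to_numpy(dtype=float)
            return (model_velocities(params, data, schemes) - data["v_obs"].to_numpy()) / sem

        sol = least_squares(resid, x0, bounds=LOG_BOUNDS, xtol=1e-10, ftol=1e-12)
        return 2 * sol.cost, sol.x

    x_start = np.array([np.log10(fit.params[p]) for p in others])
    rows = {}
    lo_bound, hi_bound = -np.inf, np.inf
    target = fit.chi2 + delta_chi2
    for _ in range(max_extend + 1):
        x0 = x_start
        for logv in grid:
            if logv in rows:
                continue
            c2, x0 = profile_point(logv, x0)
            rows[logv] = c2
        xs = np.array(sorted(rows))
        ys = np.array([rows[x] for x in xs])
        # warn-and-extend if the profile minimum sits at the grid edge
        imin = int(np.argmin(ys))
        if imin in (0, len(xs) - 1) and len(xs) > 2:
            step = xs[1] - xs[0]
            ext = xs[0] - step * np.arange(1, 4) if imin == 0 else xs[-1] + step * np.arange(1, 4)
            grid = ext
            continue
        lo_bound = _crossing(xs[: imin + 1], ys[: imin + 1], target, side="lo")
        hi_bound = _crossing(xs[imin:], ys[imin:], target, side="hi")
        need_lo = lo_bound is None
        need_hi = hi_bound is None
        if not need_lo and not need_hi:
            break
        step = xs[1] - xs[0] if len(xs) > 1 else span / n_grid
        ext = []
        if need_lo and xs[0] > LOG_BOUNDS[0]:
            ext.extend(np.maximum(xs[0] - step * np.arange(1, 4), LOG_BOUNDS[0]))
        if need_hi and xs[-1] < LOG_BOUNDS[1]:
            ext.extend(np.minimum(xs[-1] + step * np.arange(1, 4), LOG_BOUNDS[1]))
        if not ext:
            break
        grid = np.unique(ext)
    xs = np.array(sorted(rows))
    ys = np.array([rows[x] for x in xs])
    table = pd.DataFrame({param: 10.0**xs, "chi2": ys})
    lo = 10.0**lo_bound if lo_bound is not None else -np.inf
    hi = 10.0**hi_bound if hi_bound is not None else np.inf
    ci = (float(lo) if np.isfinite(lo) else -np.inf, float(hi) if np.isfinite(hi) else np.inf)
    fit.profiles[param] = table
    fit.conf_intervals[param] = ci
    return table, ci


def _crossing(xs, ys, target, side):
    """Interpolated crossing of chi2(x) with ``target`` on one flank.

    Interpolates on sqrt(Delta chi2), which is linear in x for a quadratic
    chi-square surface, so coarse profile grids still give accurate
    intervals.
    """
    if len(xs) < 2:
        return None
    base = float(np.min(ys))
    z = np.sqrt(np.clip(ys - base, 0.0, None))
    zt = np.sqrt(max(target - base, 0.0))
    above = z >= zt
    if side == "lo":
        idx = np.flatnonzero(above[:-1] & ~above[1:])
        if len(idx) == 0:
            return None
        i = idx[-1]
    else:
        idx = np.flatnonzero(~above[:-1] & above[1:])
        if len(idx) == 0:
            return None
        i = idx[0]
    x0, x1, z0, z1 = xs[i], xs[i + 1], z[i], z[i + 1]
    if z1 == z0:
        return float(x0)
    return float(x0 + (zt - z0) * (x1 - x0) / (z1 - z0))
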