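"""Consistency checks for the photon-by-photon HMM fit.

Three complementary procedures:

* **recoloring** — photon arrival times are kept and colors are redrawn
  from the fitted model (fresh state path per burst); if the model captures
  the dynamics, the recolored FRET histogram is statistically
  indistinguishable from the observed one;
* **dwell-time analysis** — dwell durations from the Viterbi paths,
  censored first/last dwells excluded, fitted by maximum-likelihood
  exponentials and compared with the model rates;
* **burst-variance analysis (BVA)** — the standard deviation of the FRET
  efficiency over consecutive n-photon windows within each burst, compared
  with the shot-noise envelope sqrt(E(1-E)/n); excess SD indicates
  within-burst dynamics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .h2mm import H2MMModel
from .photons import BurstPhotons
from .synth import simulate_state_path


# ---------------------------------------------------------------------------
# recoloring


def _burst_mean_e(bursts: list[BurstPhotons]) -> np.ndarray:
    return np.array([b.color.mean() for b in bursts if len(b) > 0])


def recolor_bursts(
    model: H2MMModel, bursts: list[BurstPhotons], clock_period: float,
    seed: int | np.random.Generator = 0,
) -> list[BurstPhotons]:
    """Redraw photon colors from the model at fixed arrival times."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p_acc = model.E  # per-state acceptor probability
    out = []
    for b in bursts:
        if len(b) == 0:
            out.append(BurstPhotons(b.ticks.copy(), b.color.copy()))
            continue
        t = (b.ticks - b.ticks[0]) * clock_period
        duration = max(t[-1], clock_period)
        if model.n_states == 2:
            path = simulate_state_path(model.Q[1, 0], model.Q[0, 1], duration * (1 + 1e-9), rng)
            edges = np.r_[0.0, path.boundaries]
            states = path.states[np.clip(np.searchsorted(edges, t, side="right") - 1,
                                         0, len(path.states) - 1)]
        else:  # general N: per-photon sampling via the gap propagators
            from scipy.linalg import expm

            states = np.empty(len(t), dtype=np.int8)
            p = model.start_distribution()
            states[0] = rng.choice(model.n_states, p=p)
            for i in range(1, len(t)):
                P = expm(model.Q * (t[i] - t[i - 1]))
                states[i] = rng.choice(model.n_states, p=P[states[i - 1]])
        colors = (rng.random(len(t)) < p_acc[states]).astype(np.uint8)
        out.append(BurstPhotons(b.ticks.copy(), colors))
    return out


def histogram_distance(
    bursts_a: list[BurstPhotons], bursts_b: list[BurstPhotons],
    bins: int = 40, metric: str = "l2",
) -> float:
    """Distance between per-burst mean-E histograms.

    ``l2``: sum of squared density differences x bin width; ``ks``:
    Kolmogorov-Smirnov statistic of the per-burst mean-E samples.
    """
    ea, eb = _burst_mean_e(bursts_a), _burst_mean_e(bursts_b)
    if metric == "ks":
        from scipy.stats import ks_2samp

        return float(ks_2samp(ea, eb).statistic)
    edges = np.linspace(0.0, 1.0, bins + 1)
    da, _ = np.histogram(ea, bins=edges, density=True)
    db, _ = np.histogram(eb, bins=edges, density=True)
    return float(np.sum((da - db) ** 2) * (edges[1] - edges[0]))


def recolor(
    model: H2MMModel, bursts: list[BurstPhotons], clock_period: float,
    seed: int = 0, bins: int = 40, metric: str = "l2",
) -> tuple[list[BurstPhotons], float]:
    """Recolor the dataset and report the histogram distance to the data."""
    recolored = recolor_bursts(model, bursts, clock_period, seed)
    return recolored, histogram_distance(bursts, recolored, bins=bins, metric=metric)


def recolor_null(
    model: H2MMModel, bursts: list[BurstPhotons], clock_period: float,
    n_draws: int = 20, seed: int = 0, bins: int = 40, metric: str = "l2",
) -> np.ndarray:
    """Null distribution of the distance: recolorings compared pairwise.

    Distances between independent recolorings of the same arrival times
    calibrate how large a data/model distance is expected when the model is
    exact.
    """
    rng = np.random.default_rng(seed)
    draws = [recolor_bursts(model, bursts, clock_period, rng) for _ in range(n_draws + 1)]
    return np.array([
        histogram_distance(draws[0], draws[i], bins=bins, metric=metric)
        for i in range(1, n_draws + 1)
    ])


# ---------------------------------------------------------------------------
# dwell-time analysis


def dwells_from_paths(
    paths: list[np.ndarray], bursts: list[BurstPhotons], clock_period: float
) -> pd.DataFrame:
    """Dwell segments from per-photon Viterbi paths.

    Transition times are placed midway between the two photons flanking a
    state change; the first and last dwell of every burst are marked
    censored (their true extent is cut by the burst boundaries).
    """
    rows = []
    for ib, (states, b) in enumerate(zip(paths, bursts)):
        if len(states) == 0:
            continue
        t = b.ticks * clock_period
        change = np.flatnonzero(states[1:] != states[:-1])
        bounds = np.r_[t[0], (t[change] + t[change + 1]) / 2.0, t[-1]]
        seg_states = states[np.r_[0, change + 1]]
        n_seg = len(seg_states)
        for k in range(n_seg):
            rows.append({
                "burst": ib,
                "state": int(seg_states[k]),
                "duration_s": float(bounds[k + 1] - bounds[k]),
                "censored": k == 0 or k == n_seg - 1,
            })
    return pd.DataFrame(rows, columns=["burst", "state", "duration_s", "censored"])


def dwell_time_analysis(
    dwells: pd.DataFrame, model: H2MMModel | None = None, min_dwells: int = 10,
    include_censored: bool = False,
) -> pd.DataFrame:
    """Maximum-likelihood exponential rate per state from uncensored dwells.

    The ML exit rate of an exponential sample is 1/mean with standard error
    rate/sqrt(n).  Including the censored first/last dwells biases the rate
    estimate and is off by default.
    """
    if not include_censored:
        dwells = dwells[~dwells["censored"]]
    if len(dwells) == 0:
        raise ValueError("no uncensored dwells available for the rate fit")
    rows = []
    for state, grp in dwells.groupby("state"):
        n = len(grp)
        if n < min_dwells:
            raise ValueError(
                f"only {n} uncensored dwells in state {state}; need >= {min_dwells}"
            )
        rate = 1.0 / grp["duration_s"].mean()
        row = {"state": int(state), "n_dwells": n, "rate": rate,
               "rate_se": rate / np.sqrt(n)}
        if model is not None:
            row["model_rate"] = float(-model.Q[state, state])
            row["ratio"] = rate / row["model_rate"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# burst-variance analysis


def burst_variance_analysis(
    bursts: list[BurstPhotons], n: int = 5, clock_period: float | None = None,
) -> pd.DataFrame:
    """Per-burst SD of consecutive n-photon window FRET vs burst mean FRET.

    Windows are consecutive blocks of exactly ``n`` donor-excitation
    photons; bursts yielding fewer than two windows are skipped (count in
    ``attrs['n_skipped']``).  The per-burst SD uses the n-1 denominator so
    its square is unbiased for the window variance.  The static shot-noise
    expectation for a burst of mean efficiency E is sqrt(E(1-E)/n)
    (``static_envelope``).  When a clock period is given, the mean window
    duration is recorded to support the time-resolved variant (binning
    windows by duration).
    """
    if n < 2:
        raise ValueError("window size n must be >= 2")
    rows, skipped = [], 0
    for ib, b in enumerate(bursts):
        m = len(b) // n
        if m < 2:
            skipped += 1
            continue
        windows = b.color[: m * n].reshape(m, n).mean(axis=1)
        row = {
            "burst": ib,
            "mean_E": float(b.color.mean()),
            "sd_E": float(np.std(windows, ddof=1)),
            "n_windows": m,
        }
        if clock_period is not None:
            ticks = b.ticks[: m * n].reshape(m, n)
            row["mean_window_s"] = float((ticks[:, -1] - ticks[:, 0]).mean() * clock_period)
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table["static_envelope"] = np.sqrt(table["mean_E"] * (1 - table["mean_E"]) / n)
    table.attrs["n"] = n
    table.attrs["n_skipped"] = skipped
    return table


def static_envelope(e: np.ndarray, n: int) -> np.ndarray:
    """Shot-noise SD of the mean of n Bernoulli(E) photons."""
    e = np.asarray(e, dtype=float)
    return np.sqrt(e * (1 - e) / n)
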