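"""Burst search, raw FRET/stoichiometry, and channel-contamination corrections.

Bursts are located by smoothing the inter-photon interval trace with a
centered moving mean over a fixed photon window (default 15 photons) and
thresholding it at a cut-off time (default 5 us); runs shorter than the
minimum photon count (default 50) are discarded.

Per burst, photon counts are split by (excitation, detection) channel into
N_DD, N_DA, N_AA.  The raw FRET efficiency uses donor-excitation photons
only, E_raw = N_DA / (N_DD + N_DA); the raw stoichiometry uses all photons,
S_raw = (N_DD + N_DA) / (N_DD + N_DA + N_AA).  Leakage and direct-excitation
factors are estimated from the donor-only (S near 1) and acceptor-only
(S near 0) populations of the E/S histogram, and applied as
F_DA = N_DA - l*N_DD - d*N_AA, E_corr = F_DA / (gamma*N_DD + F_DA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .photons import ACCEPTOR, DONOR, BurstPhotons, PhotonDataset, PhotonStream


@dataclass
class BurstSearchParams:
    window: int = 15  # photons in the moving mean
    max_gap: float = 5e-6  # s, smoothed inter-photon interval cut-off
    min_photons: int = 50

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if self.min_photons < 1:
            raise ValueError("min_photons must be >= 1")


@dataclass
class CorrectionFactors:
    leakage: float = 0.0
    direct_excitation: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.leakage < 0 or self.direct_excitation < 0:
            raise ValueError("leakage and direct_excitation must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def find_bursts(stream: PhotonStream, params: BurstSearchParams | None = None) -> pd.DataFrame:
    """Locate photon bursts in a stream.

    Returns a burst table with one row per burst: photon index range
    (``i0``..``i1`` inclusive), start/stop ticks, channel counts and raw
    E/S values.  Bursts are disjoint and ordered; the search is
    deterministic and idempotent.
    """
    params = params or BurstSearchParams()
    stream.validate()
    n = len(stream)
    if n == 0:
        return _empty_table(params)
    max_gap_ticks = int(round(params.max_gap / stream.clock_period))
    gaps = np.diff(stream.timestamps)  # n-1 intervals
    if n < 2:
        return _empty_table(params)
    w = min(params.window, len(gaps))
    kernel = np.ones(w) / w
    smoothed = np.convolve(gaps, kernel, mode="same")  # centered moving mean
    # photon i is "in a burst" if an adjacent smoothed interval passes
    in_burst = np.zeros(n, dtype=bool)
    ok = smoothed < max_gap_ticks
    in_burst[:-1] |= ok
    in_burst[1:] |= ok
    # maximal runs of in-burst photons
    edges = np.diff(in_burst.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1)
    if in_burst[0]:
        starts = np.r_[0, starts]
    if in_burst[-1]:
        stops = np.r_[stops, n - 1]
    rows = []
    for i0, i1 in zip(starts, stops):
        if i1 - i0 + 1 < params.min_photons:
            continue
        rows.append(_burst_row(stream, int(i0), int(i1)))
    if not rows:
        return _empty_table(params)
    table = pd.DataFrame(rows)
    table.attrs["params"] = params
    table.attrs["clock_period"] = stream.clock_period
    return table


def _empty_table(params: BurstSearchParams) -> pd.DataFrame:
    cols = ["i0", "i1", "start_tick", "stop_tick", "n_dd", "n_da", "n_aa",
            "E_raw", "S_raw"]
    table = pd.DataFrame(columns=cols)
    table.attrs["params"] = params
    return table


def _burst_row(stream: PhotonStream, i0: int, i1: int) -> dict:
    exc = stream.excitation[i0 : i1 + 1]
    det = stream.detection[i0 : i1 + 1]
    n_dd = int(np.sum((exc == DONOR) & (det == DONOR)))
    n_da = int(np.sum((exc == DONOR) & (det == ACCEPTOR)))
    n_aa = int(np.sum(exc == ACCEPTOR))
    e, s = raw_e_s(n_dd, n_da, n_aa)
    return {
        "i0": i0, "i1": i1,
        "start_tick": int(stream.timestamps[i0]),
        "stop_tick": int(stream.timestamps[i1]),
        "n_dd": n_dd, "n_da": n_da, "n_aa": n_aa,
        "E_raw": e, "S_raw": s,
    }


def raw_e_s(n_dd: int, n_da: int, n_aa: int):
    """Raw FRET efficiency and stoichiometry from channel counts.

    E_raw is NaN (flagged) when no donor-excitation photons are present.
    """
    ndx = n_dd + n_da
    e = n_da / ndx if ndx > 0 else np.nan
    tot = ndx + n_aa
    s = ndx / tot if tot > 0 else np.nan
    return e, s


def estimate_corrections(
    table: pd.DataFrame,
    donor_only_s_min: float = 0.9,
    acceptor_only_s_max: float = 0.2,
    min_bursts: int = 10,
    gamma: float = 1.0,
) -> CorrectionFactors:
    """Leakage and direct excitation from the E/S histogram's single-label wings.

    l = E/(1-E) of the donor-only population's mean raw E;
    d = S/(1-S) of the acceptor-only population's mean raw S.
    """
    donor_only = table[table["S_raw"] >= donor_only_s_min]
    acceptor_only = table[table["S_raw"] <= acceptor_only_s_max]
    if len(donor_only) < min_bursts or len(acceptor_only) < min_bursts:
        raise ValueError(
            f"too few single-label bursts (donor-only {len(donor_only)}, "
            f"acceptor-only {len(acceptor_only)}; need >= {min_bursts} each)"
        )
    # pool counts so bright bursts carry their photon weight
    e_bar = donor_only["n_da"].sum() / (donor_only["n_dd"].sum() + donor_only["n_da"].sum())
    ndx = acceptor_only["n_dd"].sum() + acceptor_only["n_da"].sum()
    s_bar = ndx / (ndx + acceptor_only["n_aa"].sum())
    return CorrectionFactors(
        leakage=float(e_bar / (1 - e_bar)),
        direct_excitation=float(s_bar / (1 - s_bar)),
        gamma=gamma,
    )


def apply_corrections(table: pd.DataFrame, factors: CorrectionFactors) -> pd.DataFrame:
    """Add corrected acceptor counts and corrected FRET efficiency.

    ``F_DA = N_DA - l N_DD - d N_AA``; ``E_corr = F_DA/(gamma N_DD + F_DA)``.
    Bursts whose corrected count falls below zero are flagged, not clipped.
    """
    out = table.copy()
    f_da = out["n_da"] - factors.leakage * out["n_dd"] - factors.direct_excitation * out["n_aa"]
    out["f_da"] = f_da
    out["E_corr"] = f_da / (factors.gamma * out["n_dd"] + f_da)
    out["corr_flag"] = f_da < 0
    out.attrs.update(table.attrs)
    out.attrs["corrections"] = factors
    return out


def select_dual_labeled(table: pd.DataFrame, s_window=(0.3, 0.8)) -> pd.DataFrame:
    """Keep bursts whose raw stoichiometry falls inside ``s_window``."""
    low, high = s_window
    out = table[(table["S_raw"] >= low) & (table["S_raw"] <= high)].copy()
    out.attrs.update(table.attrs)
    out.attrs["s_window"] = (low, high)
    if len(out) == 0:
        import warnings

        warnings.warn("stoichiometry selection returned no bursts")
    return out


def efficiency_histogram(table: pd.DataFrame, bins: int = 40, column: str = "E_corr"):
    """Normalized FRET efficiency histogram over [0, 1].

    Returns ``(density, edges)``; an empty table yields an all-zero histogram.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    edges = np.linspace(0.0, 1.0, bins + 1)
    if len(table) == 0:
        return np.zeros(bins), edges
    vals = table[column].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    density, _ = np.histogram(np.clip(vals, 0.0, 1.0), bins=edges, density=True)
    return density, edges


def extract_burst_photons(
    dataset: PhotonDataset, table: pd.DataFrame, donor_excitation_only: bool = True
) -> list[BurstPhotons]:
    """Pull per-burst photon records (for the photon-by-photon HMM)."""
    stream = dataset.stream
    out = []
    for i0, i1 in zip(table["i0"].astype(int), table["i1"].astype(int)):
        sl = slice(i0, i1 + 1)
        ticks = stream.timestamps[sl]
        exc = stream.excitation[sl]
        det = stream.detection[sl]
        if donor_excitation_only:
            keep = exc == DONOR
            ticks, det = ticks[keep], det[keep]
        out.append(BurstPhotons(ticks.copy(), det.astype(np.uint8).copy()))
    return out
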