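"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the study conditions of a diffusion-based smFRET
measurement on a two-state (open/closed) interconverting enzyme, plus the
classical-enzymology data types: steady-state velocity tables with AMP
substrate inhibition, product-inhibited progress curves and 1:1 binding
isotherms.

Photon bursts are generated as fixed-rate photon windows with exponentially
distributed durations (no diffusion simulation): burst-level statistics, not
focal geometry, are what downstream inference consumes.  Pulsed-interleaved
excitation is simulated at the label level — each photon carries its
excitation source (donor/acceptor) and detection channel.

Contamination model
-------------------
For a dual-labeled emitter in state *s* with FRET efficiency ``E_s`` and
donor-excitation photon rate *r*:

* donor channel (DD): Poisson rate ``r (1 - E_s)``
* acceptor channel after donor excitation (DA): FRET photons at ``r E_s``
  plus leakage at ``l * r (1 - E_s)`` plus direct excitation at
  ``d * r_AA``
* acceptor channel after acceptor excitation (AA): Poisson rate ``r_AA``

With these rates the burst-correction algebra
``F_DA = N_DA - l N_DD - d N_AA`` is unbiased for the FRET photons, so
simulate -> correct is an identity in expectation at gamma = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .photons import (
    ACCEPTOR,
    DEFAULT_CLOCK_PERIOD,
    DONOR,
    PhotonDataset,
    PhotonStream,
    SimulationTruth,
)

OPEN, CLOSED = 0, 1


@dataclass
class DwellPath:
    """A realization of the two-state open/closed dynamics.

    ``states`` and ``durations`` describe ordered dwell segments; adjacent
    segments differ in state, durations are positive and sum to
    ``total_duration``.
    """

    states: np.ndarray  # int8, 0 open / 1 closed
    durations: np.ndarray  # seconds
    total_duration: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.durations = np.asarray(self.durations, dtype=float)
        if np.any(self.durations <= 0):
            raise ValueError("dwell durations must be positive")
        if not np.isclose(self.durations.sum(), self.total_duration, rtol=1e-9):
            raise ValueError("segment durations must sum to total_duration")
        if np.any(self.states[1:] == self.states[:-1]):
            raise ValueError("adjacent segments must differ in state")

    @property
    def boundaries(self) -> np.ndarray:
        """Segment end times (seconds), length = number of segments."""
        return np.cumsum(self.durations)

    def fraction_closed(self) -> float:
        return float(self.durations[self.states == CLOSED].sum() / self.total_duration)


@dataclass
class SimConfig:
    """Parameters of the photon-burst generator.

    Defaults reproduce the study conditions: state FRET efficiencies
    0.37 / 0.72, microsecond interconversion, ~100 photons per burst,
    10,000 bursts per measurement, 40 MHz clock.
    """

    k_open: float = 4e4  # closed -> open rate, 1/s
    k_close: float = 4e4  # open -> closed rate, 1/s
    E_open: float = 0.37
    E_closed: float = 0.72
    photon_rate: float = 2.5e5  # donor-excitation photons/s during a burst
    aa_photon_rate: float = 2.5e5  # acceptor-excitation photons/s during a burst
    burst_duration_mean: float = 5e-4  # s
    burst_duration_dist: str = "exponential"  # or "fixed"
    n_bursts: int = 10_000
    leakage: float = 0.0
    direct_excitation: float = 0.0
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (DD, DA, AA) counts/s
    clock_period: float = DEFAULT_CLOCK_PERIOD
    donor_only_frac: float = 0.0
    acceptor_only_frac: float = 0.0
    interburst_gap: float = 10e-3  # s between consecutive bursts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_open < 0 or self.k_close < 0:
            raise ValueError("rates must be non-negative")
        for e in (self.E_open, self.E_closed):
            if not 0.0 <= e <= 1.0:
                raise ValueError("efficiencies must lie in [0, 1]")
        if self.n_bursts < 1:
            raise ValueError("n_bursts must be >= 1")
        if self.clock_period <= 0:
            raise ValueError("clock_period must be positive")
        if not (0.0 <= self.leakage < 1.0 and 0.0 <= self.direct_excitation < 1.0):
            raise ValueError("leakage and direct_excitation must lie in [0, 1)")
        if self.photon_rate <= 0:
            raise ValueError("photon_rate must be positive")
        if self.donor_only_frac + self.acceptor_only_frac > 1.0:
            raise ValueError("single-label fractions exceed 1")

    @property
    def e_by_state(self) -> np.ndarray:
        return np.array([self.E_open, self.E_closed])


def simulate_state_path(
    k_open: float, k_close: float, duration: float, seed: int | np.random.Generator
) -> DwellPath:
    """Continuous-time Markov chain realization of the open/closed dynamics.

    The initial state is drawn from the stationary distribution
    (P(closed) = k_close / (k_open + k_close)); dwell times are exponential
    with exit rates ``k_close`` (open) and ``k_open`` (closed).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if k_open < 0 or k_close < 0:
        raise ValueError("rates must be non-negative")
    if k_open == 0 and k_close == 0:
        raise ValueError("both rates zero: equilibrium undefined")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p_closed = k_close / (k_open + k_close)
    state = CLOSED if rng.random() < p_closed else OPEN
    exit_rate = (k_close, k_open)  # exit rate of (open, closed)
    states, durations = [], []
    t = 0.0
    while t < duration:
        rate = exit_rate[state]
        dwell = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        dwell = min(dwell, duration - t)
        states.append(state)
        durations.append(dwell)
        t += dwell
        state = 1 - state
    return DwellPath(np.array(states), np.array(durations), duration)


def _poisson_times(rng: np.random.Generator, rate: float, t0: float, t1: float) -> np.ndarray:
    """Uniform-order-statistics sampling of a Poisson process on [t0, t1)."""
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def simulate_burst_photons(
    path: DwellPath, cfg: SimConfig, seed: int | np.random.Generator
) -> PhotonStream:
    """Photon stream of a single burst from a dual-labeled emitter.

    Photons form Poisson processes over the dwell path with the
    state-dependent channel rates described in the module docstring;
    timestamps are quantized to the clock period.  The conformational state
    at each photon's arrival is returned in the stream's ``state`` attribute.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    l, d = cfg.leakage, cfg.direct_excitation
    times, exc, det, st = [], [], [], []
    t0 = 0.0
    for s, dur in zip(path.states, path.durations):
        e = cfg.e_by_state[s]
        for rate, (x, c) in (
            (cfg.photon_rate * (1 - e), (DONOR, DONOR)),
            (cfg.photon_rate * (e + l * (1 - e)), (DONOR, ACCEPTOR)),
        ):
            tt = _poisson_times(rng, rate, t0, t0 + dur)
            times.append(tt)
            exc.append(np.full(len(tt), x, dtype=np.uint8))
            det.append(np.full(len(tt), c, dtype=np.uint8))
            st.append(np.full(len(tt), s, dtype=np.int8))
        t0 += dur
    T = path.total_duration
    for rate, (x, c) in (
        (d * cfg.aa_photon_rate, (DONOR, ACCEPTOR)),  # direct excitation
        (cfg.aa_photon_rate, (ACCEPTOR, ACCEPTOR)),
    ):
        tt = _poisson_times(rng, rate, 0.0, T)
        times.append(tt)
        exc.append(np.full(len(tt), x, dtype=np.uint8))
        det.append(np.full(len(tt), c, dtype=np.uint8))
        st.append(np.full(len(tt), -1, dtype=np.int8))
    times = np.concatenate(times)
    order = np.argsort(times, kind="stable")
    ticks = np.round(times[order] / cfg.clock_period).astype(np.int64)
    stream = PhotonStream(
        ticks, np.concatenate(exc)[order], np.concatenate(det)[order], cfg.clock_period
    )
    stream.state = np.concatenate(st)[order]  # type: ignore[attr-defined]
    return stream


def _single_label_burst(
    cfg: SimConfig, duration: float, label: str, rng: np.random.Generator
) -> PhotonStream:
    """Burst from a donor-only or acceptor-only molecule (for S-based sorting)."""
    if label == "donor_only":
        rates = [
            (cfg.photon_rate, (DONOR, DONOR)),
            (cfg.leakage * cfg.photon_rate, (DONOR, ACCEPTOR)),
        ]
    else:  # acceptor_only
        rates = [
            (cfg.direct_excitation * cfg.aa_photon_rate, (DONOR, ACCEPTOR)),
            (cfg.aa_photon_rate, (ACCEPTOR, ACCEPTOR)),
        ]
    times, exc, det = [], [], []
    for rate, (x, c) in rates:
        tt = _poisson_times(rng, rate, 0.0, duration)
        times.append(tt)
        exc.append(np.full(len(tt), x, dtype=np.uint8))
        det.append(np.full(len(tt), c, dtype=np.uint8))
    times = np.concatenate(times)
    order = np.argsort(times, kind="stable")
    ticks = np.round(times[order] / cfg.clock_period).astype(np.int64)
    stream = PhotonStream(
        ticks, np.concatenate(exc)[order], np.concatenate(det)[order], cfg.clock_period
    )
    stream.state = np.full(len(ticks), -1, dtype=np.int8)  # type: ignore[attr-defined]
    return stream


def simulate_dataset(cfg: SimConfig) -> PhotonDataset:
    """Full measurement: ``cfg.n_bursts`` independent bursts with wide gaps.

    Each burst draws a fresh dwell path; inter-burst gaps (default 10 ms)
    are long enough that burst search separates the bursts.  Optional
    donor-only / acceptor-only bursts are interleaved for correction-factor
    estimation.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    gap_ticks = int(round(cfg.interburst_gap / cfg.clock_period))
    all_ticks, all_exc, all_det, all_state = [], [], [], []
    bounds, labels, paths = [], [], []
    offset = gap_ticks
    for _ in range(cfg.n_bursts):
        if cfg.burst_duration_dist == "fixed":
            duration = cfg.burst_duration_mean
        else:
            duration = rng.exponential(cfg.burst_duration_mean)
        duration = max(duration, 5 * cfg.clock_period)
        u = rng.random()
        if u < cfg.donor_only_frac:
            label, path = "donor_only", None
            stream = _single_label_burst(cfg, duration, label, rng)
        elif u < cfg.donor_only_frac + cfg.acceptor_only_frac:
            label, path = "acceptor_only", None
            stream = _single_label_burst(cfg, duration, label, rng)
        else:
            label = "dual"
            path = simulate_state_path(cfg.k_open, cfg.k_close, duration, rng)
            stream = simulate_burst_photons(path, cfg, rng)
        ticks = stream.timestamps + offset
        all_ticks.append(ticks)
        all_exc.append(stream.excitation)
        all_det.append(stream.detection)
        all_state.append(stream.state)  # type: ignore[attr-defined]
        if len(ticks):
            bounds.append((ticks[0], ticks[-1]))
        else:
            bounds.append((offset, offset))
        labels.append(label)
        paths.append(path)
        offset += int(round(duration / cfg.clock_period)) + gap_ticks
    ticks = np.concatenate(all_ticks)
    exc = np.concatenate(all_exc)
    det = np.concatenate(all_det)
    state = np.concatenate(all_state)
    # uniform background over the full acquisition
    bg_specs = [(cfg.background[0], DONOR, DONOR), (cfg.background[1], DONOR, ACCEPTOR),
                (cfg.background[2], ACCEPTOR, ACCEPTOR)]
    total_s = offset * cfg.clock_period
    for rate, x, c in bg_specs:
        if rate <= 0:
            continue
        tt = _poisson_times(rng, rate, 0.0, total_s)
        bt = np.round(tt / cfg.clock_period).astype(np.int64)
        ticks = np.concatenate([ticks, bt])
        exc = np.concatenate([exc, np.full(len(bt), x, dtype=np.uint8)])
        det = np.concatenate([det, np.full(len(bt), c, dtype=np.uint8)])
        state = np.concatenate([state, np.full(len(bt), -1, dtype=np.int8)])
    order = np.argsort(ticks, kind="stable")
    stream = PhotonStream(ticks[order], exc[order], det[order], cfg.clock_period)
    truth = SimulationTruth(np.array(bounds, dtype=np.int64), labels, state[order], paths)
    meta = {"seed": cfg.seed, "n_bursts": cfg.n_bursts, "clock_period": cfg.clock_period}
    return PhotonDataset(stream, meta=meta, truth=truth)


# ---------------------------------------------------------------------------
# enzymology fixtures


def simulate_velocity_data(scheme, grid, sem, n_rep=3, seed=0, atp=1000.0, urea=0.0):
    """Velocity table ``v0(amp)`` from a kinetic scheme plus Gaussian noise.

    ``grid`` is a list of AMP concentrations (uM) at fixed ``atp`` (uM,
    default 1 mM as in the activity assays).  ``sem`` is the standard error
    applied to each replicate mean; replicate scatter is ``sem * sqrt(n_rep)``
    so the recorded SEM of the mean equals ``sem``.
    """
    from .kinscheme import velocity

    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty concentration grid")
    if sem < 0:
        raise ValueError("sem must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for amp in grid:
        v = velocity(scheme, atp, amp)
        reps = v + rng.normal(0.0, sem * np.sqrt(n_rep), size=n_rep) if sem > 0 else np.full(n_rep, v)
        rows.append((atp, amp, urea, float(np.mean(reps)), float(sem) if sem > 0 else 1.0, v))
    return pd.DataFrame(
        rows, columns=["atp_um", "amp_um", "urea_m", "v_obs", "sem", "v_true"]
    )


def progress_curve(t, v0, eta):
    """Product concentration under product inhibition.

    [P](t) = v0 (1 - exp(-eta t)) / eta, reducing to v0*t as eta -> 0.
    """
    t = np.asarray(t, dtype=float)
    if eta == 0:
        return v0 * t
    return v0 * (-np.expm1(-eta * t)) / eta


def simulate_progress_curve(v0, eta, t_grid, noise_sd=0.0, seed=0):
    """Progress curve [P](t) plus Gaussian noise; [P](0) = 0 exactly."""
    if v0 < 0 or eta < 0:
        raise ValueError("v0 and eta must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.asarray(t_grid, dtype=float)
    p = progress_curve(t, v0, eta)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0.0, noise_sd, size=t.shape)
        p[t == 0] = 0.0
    return pd.DataFrame({"t": t, "P": p})


def simulate_binding_isotherm(kd, ligand_grid, noise_sd=0.0, seed=0):
    """1:1 binding isotherm f = L/(Kd + L) plus noise, clipped to [0, 1]."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    L = np.asarray(ligand_grid, dtype=float)
    f = L / (kd + L)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = np.clip(f + rng.normal(0.0, noise_sd, size=L.shape), 0.0, 1.0)
    return pd.DataFrame({"ligand_um": L, "fraction_bound": f})
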