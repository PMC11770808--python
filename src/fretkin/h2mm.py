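"""Photon-by-photon hidden-Markov inference of conformational dynamics.

A two-state (open/closed) emitter interconverting on the microsecond time
scale is inferred from the colors and arrival times of the donor-excitation
photons of each burst: maximum-likelihood estimation of the per-state FRET
efficiencies and of the transition rate matrix by Baum-Welch EM with
continuous-time propagators evaluated on the clock-quantized inter-photon
gaps, Viterbi state assignment, global fitting with efficiencies shared
across measurements, and the closed/open occupancy ratio K_C.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from . import _kernels
from .photons import BurstPhotons

#: inter-photon gaps longer than this many ticks are propagated with the
#: capped power (the chain is at stationarity long before this on the rate
#: scales considered here)
GAP_CAP = 1 << 16


@dataclass
class H2MMModel:
    """N-state model: FRET efficiency per state + transition rate matrix.

    ``Q`` is a generator in 1/s (off-diagonals >= 0, rows sum to zero);
    ``pi0`` is the distribution at burst start, ``None`` meaning the
    stationary distribution of ``Q`` (molecules enter the focus at
    equilibrium).
    """

    E: np.ndarray
    Q: np.ndarray
    pi0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.E = np.atleast_1d(np.asarray(self.E, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.validate()

    def validate(self) -> None:
        n = self.n_states
        if self.Q.shape != (n, n):
            raise ValueError("Q shape does not match number of states")
        if np.any((self.E < 0) | (self.E > 1)):
            raise ValueError("efficiencies must lie in [0, 1]")
        off = self.Q - np.diag(np.diag(self.Q))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.any(np.abs(self.Q.sum(axis=1)) > 1e-9 * max(1.0, np.abs(self.Q).max())):
            raise ValueError("rows of Q must sum to zero")
        if self.pi0 is not None:
            self.pi0 = np.asarray(self.pi0, dtype=float)
            if not np.isclose(self.pi0.sum(), 1.0):
                raise ValueError("pi0 must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.E)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of Q."""
        n = self.n_states
        if n == 1:
            return np.array([1.0])
        a = np.vstack([self.Q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def start_distribution(self) -> np.ndarray:
        return self.stationary() if self.pi0 is None else self.pi0

    def transition_matrix(self, clock_period: float) -> np.ndarray:
        """Per-tick transition matrix A = expm(Q * clock_period)."""
        return expm(self.Q * clock_period)

    def to_json(self, **extra) -> str:
        payload = {
            "E": self.E.tolist(),
            "Q_per_s": self.Q.tolist(),
            "pi0": None if self.pi0 is None else self.pi0.tolist(),
        }
        payload.update(extra)
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "H2MMModel":
        d = json.loads(text)
        return cls(np.array(d["E"]), np.array(d["Q_per_s"]),
                   None if d.get("pi0") is None else np.array(d["pi0"]))


@dataclass
class FitRecord:
    loglik_trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    tol: float = 0.0
    seed: int | None = None

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else np.nan


def pack_bursts(bursts: list[BurstPhotons]):
    """Concatenate bursts into flat arrays for the kernels.

    Returns (colors, gaps, burst_ptr); ``gaps[t]`` is the tick separation
    from the previous photon in the same burst (0 at burst start), clipped
    to ``GAP_CAP``.
    """
    colors = np.concatenate([b.color for b in bursts]).astype(np.uint8)
    gaps = np.concatenate(
        [np.r_[0, np.diff(b.ticks)] for b in bursts]
    ).astype(np.int64)
    if np.any(gaps < 0):
        raise ValueError("photon timestamps within a burst must be sorted")
    np.minimum(gaps, GAP_CAP, out=gaps)
    burst_ptr = np.r_[0, np.cumsum([len(b) for b in bursts])].astype(np.int64)
    return colors, gaps, burst_ptr


def _per_tick_matrix(model: H2MMModel, clock_period: float) -> np.ndarray:
    A = model.transition_matrix(clock_period)
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite per-tick propagator; check Q")
    return A


def forward_loglik(
    model: H2MMModel, bursts: list[BurstPhotons], clock_period: float
) -> float:
    """Log-likelihood of photon colors and arrival times under the model.

    Sum over bursts of log P(colors, gaps | model), with the start
    distribution applied at each burst start.
    """
    if len(bursts) == 0:
        return 0.0
    colors, gaps, ptr = pack_bursts(bursts)
    A = _per_tick_matrix(model, clock_period)
    P = _kernels.build_powers(A, int(gaps.max()))
    return float(
        _kernels.forward_loglik_kernel(
            colors, gaps, ptr, P, model.E, model.start_distribution()
        )
    )


def _a_to_q(A: np.ndarray, dt: float) -> np.ndarray:
    """Matrix logarithm of a per-tick stochastic matrix, as a generator in 1/s."""
    n = A.shape[0]
    if n == 2:
        a, b = A[0, 1], A[1, 0]
        lam = 1.0 - a - b
        if lam <= 0:  # pathological: faster than the clock resolves
            coef = 1.0
        elif a + b == 0:
            return np.zeros((2, 2))
        else:
            coef = -np.log(lam) / (a + b)
        return coef / dt * np.array([[-a, a], [b, -b]])
    from scipy.linalg import logm

    Q = np.real(logm(A)) / dt
    Q = np.where(np.eye(n, dtype=bool), Q, np.clip(Q, 0.0, None))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _m_step(trans, init, acc_w, tot_w, dt, E_old, free_pi0, fix_E):
    row = trans.sum(axis=1)
    A_new = np.empty_like(trans)
    n = trans.shape[0]
    for i in range(n):
        A_new[i] = trans[i] / row[i] if row[i] > 0 else np.eye(n)[i]
    Q_new = _a_to_q(A_new, dt)
    if fix_E:
        E_new = E_old.copy()
    else:
        E_new = np.where(tot_w > 0, acc_w / np.maximum(tot_w, 1e-300), E_old)
        E_new = np.clip(E_new, 1e-6, 1 - 1e-6)
    pi0 = init / init.sum() if free_pi0 else None
    return E_new, Q_new, pi0


def _e_step(model: H2MMModel, colors, gaps, ptr, clock_period):
    A = _per_tick_matrix(model, clock_period)
    P, G = _kernels.build_tables(A, int(gaps.max()))
    return _kernels.forward_backward_kernel(
        colors, gaps, ptr, P, G, model.E, model.start_distribution()
    )


def em_fit(
    init: H2MMModel,
    bursts: list[BurstPhotons],
    clock_period: float,
    tol: float = 1e-6,
    max_iter: int = 3000,
    free_pi0: bool = False,
    fix_E: bool = False,
) -> tuple[H2MMModel, FitRecord]:
    """Baum-Welch EM until |dloglik| < tol per photon or ``max_iter``.

    The log-likelihood is monotone; ``pi0`` follows the stationary
    distribution of Q unless ``free_pi0``.  Identical initial state
    efficiencies are perturbed to break the symmetry.
    """
    if len(bursts) == 0:
        raise ValueError("empty dataset")
    E = init.E.copy()
    if len(np.unique(np.round(E, 12))) < len(E):
        E = E + np.linspace(-0.05, 0.05, len(E))
        E = np.clip(E, 1e-3, 1 - 1e-3)
    model = H2MMModel(E, init.Q.copy(), init.pi0)
    colors, gaps, ptr = pack_bursts(bursts)
    n_photons = len(colors)
    record = FitRecord(tol=tol)
    ll_prev = -np.inf
    for it in range(max_iter):
        ll, trans, init_w, acc_w, tot_w = _e_step(model, colors, gaps, ptr, clock_period)
        record.loglik_trace.append(float(ll))
        record.n_iter = it + 1
        if ll < ll_prev - 1e-9 * max(1.0, abs(ll_prev)):
            # generalized-EM safeguard (stationary-pi0 coupling): stop at the
            # previous, better model rather than accept a decrease
            record.loglik_trace.pop()
            record.converged = True
            break
        if abs(ll - ll_prev) < tol * n_photons:
            record.converged = True
            break
        ll_prev = ll
        E_new, Q_new, pi0_new = _m_step(
            trans, init_w, acc_w, tot_w, clock_period, model.E, free_pi0, fix_E
        )
        prev = model
        model = H2MMModel(E_new, Q_new, pi0_new)
    else:
        record.converged = False
    if record.converged and record.loglik_trace and ll < ll_prev:
        model = prev  # type: ignore[possibly-undefined]
    return model, record


#: deterministic initialization grid: E pairs x symmetric rate decades
INIT_E_PAIRS = ((0.2, 0.8), (0.3, 0.7), (0.4, 0.6))
INIT_RATES = (1e3, 1e4, 1e5)


def fit_two_state(
    bursts: list[BurstPhotons],
    clock_period: float,
    tol: float = 1e-6,
    max_iter: int = 3000,
    n_burnin: int = 20,
    burnin_subset: int = 1000,
    **kwargs,
) -> tuple[H2MMModel, FitRecord]:
    """Two-state fit from the deterministic initialization grid.

    Each grid point (three E pairs x three symmetric rate decades) is run
    for ``n_burnin`` EM iterations on an evenly thinned subset of at most
    ``burnin_subset`` bursts; the best-likelihood candidate is then iterated
    to convergence on the full dataset.
    """
    stride = max(1, len(bursts) // burnin_subset)
    sub = bursts[::stride]
    best = None
    for e_pair in INIT_E_PAIRS:
        for k in INIT_RATES:
            init = H2MMModel(np.array(e_pair), np.array([[-k, k], [k, -k]]))
            m, r = em_fit(init, sub, clock_period, tol=tol,
                          max_iter=n_burnin, **kwargs)
            if best is None or r.loglik > best[1].loglik:
                best = (m, r)
    model, record = em_fit(best[0], bursts, clock_period, tol=tol,
                           max_iter=max_iter, **kwargs)
    return model, record


def global_fit(
    datasets: list[list[BurstPhotons]],
    clock_period: float,
    share_E: bool = True,
    fix_E: np.ndarray | None = None,
    init: H2MMModel | None = None,
    tol: float = 1e-6,
    max_iter: int = 3000,
) -> tuple[list[H2MMModel], FitRecord]:
    """Joint EM across measurements with shared state efficiencies.

    The efficiencies are optimized globally across all datasets (pooled
    emission statistics) while the transition rates are optimized for each
    dataset individually.  ``fix_E`` freezes the efficiencies to given
    values and optimizes only the rates.
    """
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    if init is None:
        init = H2MMModel(np.array([0.3, 0.7]), np.array([[-1e4, 1e4], [1e4, -1e4]]))
    n = init.n_states
    E = fix_E.copy() if fix_E is not None else init.E.copy()
    models = [H2MMModel(E, init.Q.copy()) for _ in datasets]
    packed = [pack_bursts(b) for b in datasets]
    n_photons = sum(len(p[0]) for p in packed)
    record = FitRecord(tol=tol)
    ll_prev = -np.inf
    for it in range(max_iter):
        ll_tot = 0.0
        acc_all = np.zeros(n)
        tot_all = np.zeros(n)
        stats = []
        for model, (colors, gaps, ptr) in zip(models, packed):
            ll, trans, init_w, acc_w, tot_w = _e_step(model, colors, gaps, ptr, clock_period)
            ll_tot += ll
            acc_all += acc_w
            tot_all += tot_w
            stats.append((trans, init_w, acc_w, tot_w))
        record.loglik_trace.append(float(ll_tot))
        record.n_iter = it + 1
        if ll_tot < ll_prev - 1e-9 * max(1.0, abs(ll_prev)):
            record.loglik_trace.pop()
            record.converged = True
            models = prev_models  # type: ignore[possibly-undefined]
            break
        if abs(ll_tot - ll_prev) < tol * n_photons:
            record.converged = True
            break
        ll_prev = ll_tot
        if fix_E is None and share_E:
            E = np.clip(acc_all / np.maximum(tot_all, 1e-300), 1e-6, 1 - 1e-6)
        prev_models = models
        new_models = []
        for model, (trans, init_w, acc_w, tot_w) in zip(models, stats):
            _, Q_new, _ = _m_step(trans, init_w, acc_w, tot_w, clock_period,
                                  model.E, False, True)
            if fix_E is not None or share_E:
                e_i = E
            else:
                e_i = np.clip(acc_w / np.maximum(tot_w, 1e-300), 1e-6, 1 - 1e-6)
            new_models.append(H2MMModel(e_i, Q_new))
        models = new_models
    else:
        record.converged = False
    return models, record


def viterbi(
    model: H2MMModel, bursts: list[BurstPhotons], clock_period: float
) -> tuple[list[np.ndarray], np.ndarray]:
    """Most-probable state sequence per burst.

    Returns (per-burst int8 state arrays, per-burst path log-probability);
    the propagator/emission semantics match ``forward_loglik``.
    """
    colors, gaps, ptr = pack_bursts(bursts)
    A = _per_tick_matrix(model, clock_period)
    P = _kernels.build_powers(A, int(gaps.max()))
    with np.errstate(divide="ignore"):
        logP = np.log(P)
        logE = np.log(model.E)
        log1mE = np.log(1.0 - model.E)
        logpi0 = np.log(model.start_distribution())
    states, path_ll = _kernels.viterbi_kernel(colors, gaps, ptr, logP, logE, log1mE, logpi0)
    out = [states[ptr[i]: ptr[i + 1]] for i in range(len(bursts))]
    return out, path_ll


def populations_kc(model: H2MMModel, method: str = "rates"):
    """Open/closed populations and the equilibrium coefficient K_C.

    The open state is the lower-efficiency state.  With ``method='rates'``
    (default) the populations come from the stationary distribution of Q,
    so K_C = P_closed / P_open = k_close / k_open exactly for two states.
    """
    if model.n_states != 2:
        raise ValueError("K_C is defined for the two-state model")
    if model.E[0] == model.E[1]:
        raise ValueError("states not orderable by efficiency")
    open_idx = int(np.argmin(model.E))
    closed_idx = 1 - open_idx
    pi = model.stationary()
    p_open, p_closed = float(pi[open_idx]), float(pi[closed_idx])
    if p_open == 0:
        raise ValueError("open state unoccupied; K_C undefined")
    return p_open, p_closed, p_closed / p_open


def kc_from_paths(paths: list[np.ndarray], model: H2MMModel) -> float:
    """K_C from Viterbi dwell fractions (photon-weighted occupancies)."""
    open_idx = int(np.argmin(model.E))
    counts = np.bincount(np.concatenate(paths), minlength=model.n_states)
    n_open = counts[open_idx]
    n_closed = counts.sum() - n_open
    if n_open == 0:
        raise ValueError("no photons assigned to the open state")
    return float(n_closed / n_open)
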