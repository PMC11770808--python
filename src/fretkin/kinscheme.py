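"""Conformationally gated kinetic model of adenylate kinase turnover.

Six enzyme species — apo (E), ATP-bound (ET), AMP-bound (EM), the two
mis-posed ternary complexes (ETMi from the "ATP first" pathway, EMTi from
the "AMP first" pathway) and the catalytically competent ternary complex
(ETM) — each existing in an open and a closed conformation: a 12-state
continuous-time Markov chain.  Substrate binding/unbinding and the
rearrangement of a mis-posed ternary complex into ETM occur only in the
open conformation (the closed active site is shielded from solvent);
phosphotransfer proceeds from the closed ETM and, in the initial-velocity
regime, recycles the enzyme to the open apo state.

Substrate inhibition by AMP emerges from the pathway structure: when the
"AMP first" rearrangement rate k_r_M is much smaller than k_cat, high AMP
funnels the enzyme through the slow pathway and the steady-state velocity
becomes non-monotonic in AMP.

Units: concentrations in uM, first-order rates in 1/s, association rate
constant k_on in 1/(uM s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

SPECIES = ("E", "ET", "EM", "ETMi", "EMTi", "ETM")
N_SPECIES = 6
N_STATES = 12  # 6 species x {open, closed}

# state index helpers: open state of species s is 2*s, closed is 2*s + 1
_S = {name: i for i, name in enumerate(SPECIES)}


def state_index(species: str, conf: str) -> int:
    return 2 * _S[species] + (0 if conf == "open" else 1)


IDX_E_OPEN = state_index("E", "open")
IDX_ETM_OPEN = state_index("ETM", "open")
IDX_ETM_CLOSED = state_index("ETM", "closed")
IDX_ETMI_OPEN = state_index("ETMi", "open")
IDX_EMTI_OPEN = state_index("EMTi", "open")

#: species whose conformational rates carry bound ATP (Fig-5c-style scans)
ATP_BOUND = ("ET", "ETMi", "EMTi", "ETM")
SUBSTRATE_BOUND = ("ET", "EM", "ETMi", "EMTi", "ETM")


@dataclass
class KineticScheme:
    """Parameters of the 12-state turnover model.

    ``k_close`` / ``k_open`` map each species to its closing/opening rate;
    rearrangement (``k_r_T``, ``k_r_M``) is irreversible by default and
    catalysis lumps phosphotransfer with product release (no product
    rebinding).  A single association rate constant ``k_on`` is shared by
    all binding steps (rapid-equilibrium regime: results are insensitive to
    ``k_on`` once dissociation is much faster than turnover).
    """

    k_close: dict = field(default_factory=dict)  # species -> 1/s (open -> closed)
    k_open: dict = field(default_factory=dict)  # species -> 1/s (closed -> open)
    kd_atp: float = 159.0  # uM
    kd_amp: float = 332.0  # uM
    k_on: float = 10.0  # 1/(uM s)
    k_r_T: float = 4880.0  # "ATP first" rearrangement, 1/s
    k_r_M: float = 260.0  # "AMP first" rearrangement, 1/s
    k_cat: float = 2620.0  # phosphotransfer, 1/s
    allow_unbinding_from_etm: bool = False
    rearrangement_reversible: bool = False

    def __post_init__(self) -> None:
        for name in SPECIES:
            self.k_close.setdefault(name, 0.0)
            self.k_open.setdefault(name, 0.0)
        rates = [*self.k_close.values(), *self.k_open.values(),
                 self.k_r_T, self.k_r_M, self.k_cat, self.k_on]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        if self.kd_atp <= 0 or self.kd_amp <= 0:
            raise ValueError("dissociation constants must be positive")

    def conf_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        kc = np.array([self.k_close[s] for s in SPECIES])
        ko = np.array([self.k_open[s] for s in SPECIES])
        return kc, ko

    def scale_conf(self, species, f_close: float = 1.0, f_open: float = 1.0) -> "KineticScheme":
        """New scheme with conformational rates of ``species`` scaled."""
        kc = dict(self.k_close)
        ko = dict(self.k_open)
        for s in species:
            kc[s] = kc[s] * f_close
            ko[s] = ko[s] * f_open
        return replace(self, k_close=kc, k_open=ko)


#: per-species closed/open ratios implied by the measured occupancies
#: (apo and AMP-only 0.16; 1 mM ATP 1.28; ATP+AMP ternary 1.65; with
#: 0.8 M urea 0.86 and 1.10) — 0.4 M urea interpolated linearly
_KC_BY_UREA = {
    0.0: {"E": 0.16, "ET": 1.28, "EM": 0.16, "ETMi": 1.65, "EMTi": 1.65, "ETM": 1.65},
    0.4: {"E": 0.16, "ET": 1.07, "EM": 0.16, "ETMi": 1.375, "EMTi": 1.375, "ETM": 1.375},
    0.8: {"E": 0.16, "ET": 0.86, "EM": 0.16, "ETMi": 1.10, "EMTi": 1.10, "ETM": 1.10},
}
_KD_BY_UREA = {0.0: (159.0, 332.0), 0.4: (170.0, 522.0), 0.8: (183.0, 758.0)}

#: common opening rate: microsecond-scale domain dynamics, two orders of
#: magnitude faster than the maximal turnover
DEFAULT_K_OPEN = 2e4


def wild_type_scheme(urea: float = 0.0, k_open: float = DEFAULT_K_OPEN, **overrides) -> KineticScheme:
    """Wild-type-like scheme at a given urea concentration (0, 0.4 or 0.8 M)."""
    if urea not in _KC_BY_UREA:
        raise ValueError(f"urea must be one of {sorted(_KC_BY_UREA)} M")
    kc_ratio = _KC_BY_UREA[urea]
    kd_atp, kd_amp = _KD_BY_UREA[urea]
    params = dict(
        k_close={s: kc_ratio[s] * k_open for s in SPECIES},
        k_open={s: k_open for s in SPECIES},
        kd_atp=kd_atp, kd_amp=kd_amp,
        k_r_T=4880.0, k_r_M=260.0, k_cat=2620.0,
    )
    params.update(overrides)
    return KineticScheme(**params)


def build_generator(scheme: KineticScheme, atp: float, amp: float) -> np.ndarray:
    """12x12 rate matrix at the given substrate concentrations (uM)."""
    if atp < 0 or amp < 0:
        raise ValueError("concentrations must be non-negative")
    G = np.zeros((N_STATES, N_STATES))

    def add(i, j, rate):
        G[i, j] += rate

    kc, ko = scheme.conf_arrays()
    for s in range(N_SPECIES):
        add(2 * s, 2 * s + 1, kc[s])
        add(2 * s + 1, 2 * s, ko[s])
    kon = scheme.k_on
    on_atp, off_atp = kon * atp, kon * scheme.kd_atp
    on_amp, off_amp = kon * amp, kon * scheme.kd_amp
    pairs = [  # binding steps between open states
        ("E", "ET", on_atp, off_atp),
        ("E", "EM", on_amp, off_amp),
        ("ET", "ETMi", on_amp, off_amp),
        ("EM", "EMTi", on_atp, off_atp),
    ]
    for a, b, on, off in pairs:
        add(state_index(a, "open"), state_index(b, "open"), on)
        add(state_index(b, "open"), state_index(a, "open"), off)
    if scheme.allow_unbinding_from_etm:
        add(IDX_ETM_OPEN, state_index("ET", "open"), off_amp)
        add(IDX_ETM_OPEN, state_index("EM", "open"), off_atp)
    add(IDX_ETMI_OPEN, IDX_ETM_OPEN, scheme.k_r_T)
    add(IDX_EMTI_OPEN, IDX_ETM_OPEN, scheme.k_r_M)
    if scheme.rearrangement_reversible:
        add(IDX_ETM_OPEN, IDX_ETMI_OPEN, scheme.k_r_T)
        add(IDX_ETM_OPEN, IDX_EMTI_OPEN, scheme.k_r_M)
    add(IDX_ETM_CLOSED, IDX_E_OPEN, scheme.k_cat)
    np.fill_diagonal(G, 0.0)
    np.fill_diagonal(G, -G.sum(axis=1))
    return G


def _communicating_class(G: np.ndarray, start: int) -> np.ndarray:
    """States mutually reachable with ``start`` over nonzero off-diagonals."""
    adj = (G > 0) & ~np.eye(len(G), dtype=bool)

    def reach(a):
        seen = np.zeros(len(G), dtype=bool)
        seen[start] = True
        frontier = [start]
        while frontier:
            i = frontier.pop()
            for j in np.flatnonzero(a[i]):
                if not seen[j]:
                    seen[j] = True
                    frontier.append(j)
        return seen

    return reach(adj) & reach(adj.T)


def steady_state(G: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator matrix.

    Solves the null space of G^T with normalization.  If the chain is
    reducible (zero concentrations isolate states), the solution is
    restricted to the communicating class containing the open apo state.
    """
    n = len(G)
    keep = _communicating_class(G, IDX_E_OPEN)
    idx = np.flatnonzero(keep)
    Gs = G[np.ix_(idx, idx)]
    m = len(idx)
    a = np.vstack([Gs.T, np.ones(m)])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    p_sub, *_ = np.linalg.lstsq(a, b, rcond=None)
    p = np.zeros(n)
    p[idx] = np.clip(p_sub, 0.0, None)
    return p / p.sum()


def steady_state_ode(G: np.ndarray, t_end: float = 1.0, rtol: float = 1e-10,
                     atol: float = 1e-12, max_t: float = 1e4,
                     method: str = "LSODA") -> np.ndarray:
    """Stationary distribution by stiff ODE integration from the apo start.

    Integrates dp/dt = G^T p with an implicit stiff solver.  The horizon is
    stretched to ~45 relaxation times of the slowest nonzero mode so the
    transient has fully decayed.  Serves as an independent cross-check of
    the linear solve.
    """
    p0 = np.zeros(len(G))
    p0[IDX_E_OPEN] = 1.0
    GT = G.T
    ev = np.linalg.eigvals(GT)
    scale = max(np.abs(G).max(), 1.0)
    nonzero = ev[np.abs(ev) > 1e-10 * scale]
    if len(nonzero):
        slowest = np.abs(nonzero.real).min()
        if slowest > 0:
            t_end = min(max(t_end, 45.0 / slowest), max_t)
    sol = solve_ivp(
        lambda _, y: GT @ y, (0.0, t_end), p0, method=method,
        jac=lambda _, y: GT, rtol=rtol, atol=atol, t_eval=[t_end],
    )
    if not sol.success:
        raise RuntimeError(f"stiff integration failed: {sol.message}")
    p = np.clip(sol.y[:, -1], 0.0, None)
    return p / p.sum()


def velocity(scheme: KineticScheme, atp: float, amp: float) -> float:
    """Steady-state turnover rate per enzyme, v = k_cat * p(ETM_closed)."""
    p = steady_state(build_generator(scheme, atp, amp))
    return float(scheme.k_cat * p[IDX_ETM_CLOSED])


def pathway_flux(scheme: KineticScheme, atp: float, amp: float):
    """Net steady-state flux through the two rearrangement steps (1/s).

    J_Tpath + J_Mpath equals the velocity (stationarity of ETM).
    """
    p = steady_state(build_generator(scheme, atp, amp))
    j_t = scheme.k_r_T * p[IDX_ETMI_OPEN]
    j_m = scheme.k_r_M * p[IDX_EMTI_OPEN]
    if scheme.rearrangement_reversible:
        j_t -= scheme.k_r_T * p[IDX_ETM_OPEN]
        j_m -= scheme.k_r_M * p[IDX_ETM_OPEN]
    return float(j_t), float(j_m)


def apparent_conf_rates(scheme: KineticScheme, atp: float, amp: float):
    """Ensemble-apparent closing and opening rates.

    The closing (opening) rate observable in a bulk single-molecule
    measurement is the occupancy-weighted mean of the per-species rates over
    the open (closed) states.
    """
    p = steady_state(build_generator(scheme, atp, amp))
    kc, ko = scheme.conf_arrays()
    p_open = p[0::2]
    p_closed = p[1::2]
    if p_open.sum() <= 0 or p_closed.sum() <= 0:
        raise ValueError("apparent rates undefined: one conformation unoccupied")
    k_close_app = float(np.dot(p_open, kc) / p_open.sum())
    k_open_app = float(np.dot(p_closed, ko) / p_closed.sum())
    return k_close_app, k_open_app


def scan_common_scaling(
    scheme: KineticScheme, factors, atp: float = 1000.0, amp: float = 10_000.0,
    which: str = "both",
) -> np.ndarray:
    """Velocity as the conformational rates of the ATP-bound species scale.

    ``which`` selects whether the factor applies to opening rates, closing
    rates, or both together (the latter preserves every K_C).
    """
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("scaling factors must be positive")
    if which not in ("opening", "closing", "both"):
        raise ValueError("which must be 'opening', 'closing' or 'both'")
    out = np.empty(len(factors))
    for i, f in enumerate(factors):
        fo = f if which in ("opening", "both") else 1.0
        fc = f if which in ("closing", "both") else 1.0
        out[i] = velocity(scheme.scale_conf(ATP_BOUND, f_close=fc, f_open=fo), atp, amp)
    return out


def isolate_urea_effect(
    scheme_0m: KineticScheme, scheme_08m: KineticScheme, mode: str,
    amp_grid, atp: float = 1000.0,
) -> np.ndarray:
    """Velocity curve of a hybrid scheme isolating one urea effect.

    ``affinity_only`` takes the dissociation constants from the urea scheme
    and the conformational rates from the reference; ``dynamics_only`` the
    converse; ``both`` reproduces the urea scheme.  Schemes must agree in
    the urea-invariant parameters (k_cat, k_r_T, k_r_M).
    """
    for attr in ("k_cat", "k_r_T", "k_r_M"):
        if getattr(scheme_0m, attr) != getattr(scheme_08m, attr):
            raise ValueError(f"schemes differ in urea-invariant parameter {attr}")
    if mode == "affinity_only":
        hybrid = replace(scheme_0m, kd_atp=scheme_08m.kd_atp, kd_amp=scheme_08m.kd_amp)
    elif mode == "dynamics_only":
        hybrid = replace(scheme_0m, k_close=dict(scheme_08m.k_close),
                         k_open=dict(scheme_08m.k_open))
    elif mode == "both":
        hybrid = scheme_08m
    else:
        raise ValueError("mode must be 'affinity_only', 'dynamics_only' or 'both'")
    return np.array([velocity(hybrid, atp, amp) for amp in np.asarray(amp_grid, dtype=float)])


def optimal_kc_scan(
    scheme: KineticScheme, atp: float = 5000.0, amp: float = 300.0,
    factors=None,
):
    """Scan the closing rates of the substrate-bound species for peak velocity.

    Physiological default concentrations (~5 mM ATP, 300 uM AMP).  Returns
    (best factor, K_C of the ternary complex at the optimum, velocity grid).
    """
    if factors is None:
        factors = np.logspace(-2, 2, 41)
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("factors must be positive")
    v = np.array([
        velocity(scheme.scale_conf(SUBSTRATE_BOUND, f_close=f), atp, amp) for f in factors
    ])
    best = int(np.argmax(v))
    kc_opt = factors[best] * scheme.k_close["ETM"] / scheme.k_open["ETM"]
    return float(factors[best]), float(kc_opt), v


def random_scheme(rng: np.random.Generator) -> KineticScheme:
    """Random valid scheme (log-uniform rates), for property checks."""
    def lu(lo, hi, size=None):
        return 10 ** rng.uniform(np.log10(lo), np.log10(hi), size)

    return KineticScheme(
        k_close={s: lu(1e2, 1e5) for s in SPECIES},
        k_open={s: lu(1e2, 1e5) for s in SPECIES},
        kd_atp=lu(10, 1e3), kd_amp=lu(10, 1e3), k_on=lu(1, 100),
        k_r_T=lu(1e2, 1e4), k_r_M=lu(1e2, 1e4), k_cat=lu(1e2, 1e4),
    )
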