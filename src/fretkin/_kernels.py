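"""Numba kernels for the photon-by-photon HMM.

The hidden chain is a discrete-time Markov chain on the acquisition clock
(one step per clock tick, transition matrix ``A = expm(Q * clock_period)``).
Between consecutive photons separated by ``n`` ticks the chain propagates by
``A**n``; each photon contributes an emission factor ``E_i`` (acceptor) or
``1 - E_i`` (donor).  Tables of ``A**n`` and of the expected tick-transition
count matrices

    G[n, i, j, a, b] = E[# i->j tick steps | X_0 = a, X_n = b] * (A**n)[a, b]

are built by the joint recurrence ``P[n] = P[n-1] A`` and
``G[n,i,j] = G[n-1,i,j] A + P[n-1] C_ij`` with ``C_ij = e_i A_ij e_j^T``,
so the Baum-Welch E-step accumulates exact expected tick-level transition
counts for arbitrary inter-photon gaps.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def build_tables(A, max_gap):
    """Propagator powers P[n] = A**n and count tensors G[n] for n = 0..max_gap."""
    N = A.shape[0]
    P = np.empty((max_gap + 1, N, N))
    G = np.zeros((max_gap + 1, N, N, N, N))
    P[0] = np.eye(N)
    for n in range(1, max_gap + 1):
        P[n] = P[n - 1] @ A
        for i in range(N):
            for j in range(N):
                G[n, i, j] = G[n - 1, i, j] @ A
                for a in range(N):
                    G[n, i, j, a, j] += P[n - 1, a, i] * A[i, j]
    return P, G


@njit(cache=True)
def build_powers(A, max_gap):
    """Propagator powers only (forward likelihood / Viterbi)."""
    N = A.shape[0]
    P = np.empty((max_gap + 1, N, N))
    P[0] = np.eye(N)
    for n in range(1, max_gap + 1):
        P[n] = P[n - 1] @ A
    return P


@njit(cache=True)
def forward_loglik_kernel(colors, gaps, burst_ptr, P, E, pi0):
    """Scaled forward recursion; returns the total log-likelihood."""
    N = E.shape[0]
    ll = 0.0
    alpha = np.empty(N)
    tmp = np.empty(N)
    for b in range(burst_ptr.shape[0] - 1):
        lo, hi = burst_ptr[b], burst_ptr[b + 1]
        if hi <= lo:
            continue
        for i in range(N):
            emis = E[i] if colors[lo] == 1 else 1.0 - E[i]
            alpha[i] = pi0[i] * emis
        c = alpha.sum()
        ll += np.log(c)
        alpha /= c
        for t in range(lo + 1, hi):
            g = gaps[t]
            for j in range(N):
                s = 0.0
                for i in range(N):
                    s += alpha[i] * P[g, i, j]
                emis = E[j] if colors[t] == 1 else 1.0 - E[j]
                tmp[j] = s * emis
            c = tmp.sum()
            ll += np.log(c)
            for j in range(N):
                alpha[j] = tmp[j] / c
    return ll


@njit(cache=True)
def forward_backward_kernel(colors, gaps, burst_ptr, P, G, E, pi0):
    """Baum-Welch E-step over all bursts.

    Returns (loglik, trans_counts[N,N], init_counts[N], acc_w[N], tot_w[N]):
    expected tick-level transition counts, expected burst-start occupancies
    and expected acceptor / total photon weights per state.
    """
    N = E.shape[0]
    ll = 0.0
    trans = np.zeros((N, N))
    init = np.zeros(N)
    acc_w = np.zeros(N)
    tot_w = np.zeros(N)
    max_T = 0
    for b in range(burst_ptr.shape[0] - 1):
        T = burst_ptr[b + 1] - burst_ptr[b]
        if T > max_T:
            max_T = T
    alpha = np.empty((max_T, N))
    beta = np.empty((max_T, N))
    cs = np.empty(max_T)
    W = np.zeros((P.shape[0], N, N))  # endpoint-pair weights per gap length
    for b in range(burst_ptr.shape[0] - 1):
        lo, hi = burst_ptr[b], burst_ptr[b + 1]
        T = hi - lo
        if T <= 0:
            continue
        # forward
        for i in range(N):
            emis = E[i] if colors[lo] == 1 else 1.0 - E[i]
            alpha[0, i] = pi0[i] * emis
        c = alpha[0].sum()
        cs[0] = c
        ll += np.log(c)
        alpha[0] /= c
        for t in range(1, T):
            g = gaps[lo + t]
            for j in range(N):
                s = 0.0
                for i in range(N):
                    s += alpha[t - 1, i] * P[g, i, j]
                emis = E[j] if colors[lo + t] == 1 else 1.0 - E[j]
                alpha[t, j] = s * emis
            c = alpha[t].sum()
            cs[t] = c
            ll += np.log(c)
            alpha[t] /= c
        # backward
        for i in range(N):
            beta[T - 1, i] = 1.0
        for t in range(T - 2, -1, -1):
            g = gaps[lo + t + 1]
            for i in range(N):
                s = 0.0
                for j in range(N):
                    emis = E[j] if colors[lo + t + 1] == 1 else 1.0 - E[j]
                    s += P[g, i, j] * emis * beta[t + 1, j]
                beta[t, i] = s / cs[t + 1]
        # occupancies and emission statistics
        for t in range(T):
            is_acc = colors[lo + t] == 1
            for i in range(N):
                gam = alpha[t, i] * beta[t, i]
                tot_w[i] += gam
                if is_acc:
                    acc_w[i] += gam
                if t == 0:
                    init[i] += gam
        # endpoint-pair weights per gap length (contracted with G below)
        for t in range(T - 1):
            g = gaps[lo + t + 1]
            inv_c = 1.0 / cs[t + 1]
            for bb in range(N):
                emis = E[bb] if colors[lo + t + 1] == 1 else 1.0 - E[bb]
                wb = emis * beta[t + 1, bb] * inv_c
                for a in range(N):
                    W[g, a, bb] += alpha[t, a] * wb
    for g in range(W.shape[0]):
        used = False
        for a in range(N):
            for bb in range(N):
                if W[g, a, bb] != 0.0:
                    used = True
        if not used:
            continue
        for i in range(N):
            for j in range(N):
                s = 0.0
                for a in range(N):
                    for bb in range(N):
                        s += W[g, a, bb] * G[g, i, j, a, bb]
                trans[i, j] += s
    return ll, trans, init, acc_w, tot_w


@njit(cache=True)
def viterbi_kernel(colors, gaps, burst_ptr, logP, logE, log1mE, logpi0):
    """Most-probable state per photon (max-product in log space)."""
    n_photons = colors.shape[0]
    N = logE.shape[0]
    states = np.empty(n_photons, dtype=np.int8)
    path_ll = np.zeros(burst_ptr.shape[0] - 1)
    max_T = 0
    for b in range(burst_ptr.shape[0] - 1):
        T = burst_ptr[b + 1] - burst_ptr[b]
        if T > max_T:
            max_T = T
    delta = np.empty((max_T, N))
    psi = np.empty((max_T, N), dtype=np.int8)
    for b in range(burst_ptr.shape[0] - 1):
        lo, hi = burst_ptr[b], burst_ptr[b + 1]
        T = hi - lo
        if T <= 0:
            continue
        for i in range(N):
            emis = logE[i] if colors[lo] == 1 else log1mE[i]
            delta[0, i] = logpi0[i] + emis
        for t in range(1, T):
            g = gaps[lo + t]
            for j in range(N):
                best = -np.inf
                arg = 0
                for i in range(N):
                    v = delta[t - 1, i] + logP[g, i, j]
                    if v > best:
                        best = v
                        arg = i
                emis = logE[j] if colors[lo + t] == 1 else log1mE[j]
                delta[t, j] = best + emis
                psi[t, j] = arg
        best = -np.inf
        arg = 0
        for i in range(N):
            if delta[T - 1, i] > best:
                best = delta[T - 1, i]
                arg = i
        path_ll[b] = best
        states[lo + T - 1] = arg
        for t in range(T - 2, -1, -1):
            arg = psi[t + 1, states[lo + t + 1]]
            states[lo + t] = arg
    return states, path_ll
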