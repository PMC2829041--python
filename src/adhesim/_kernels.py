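"""Compiled event loops for the model's reaction network.

The generic engines in :mod:`adhesim.ssa` accept arbitrary reaction networks;
these numba kernels specialize the 18-channel model network for speed.  All
randomness comes from an explicit splitmix64 counter generator so that every
run is reproducible from its integer seed and, in the spatial kernel, each
subvolume owns an independent stream derived from the master seed (adding
subvolumes does not perturb the streams of existing ones).
"""
from __future__ import annotations

import numpy as np
from numba import njit, uint64

__all__ = ["pack_params", "frm_kernel", "nrm_kernel", "nsm_kernel",
           "MODEL_STOICH"]

# channel order must match adhesim.ssa.compile_reactions
MODEL_STOICH = np.array([
    (1, 0, 0, 0, 0, 0),
    (-1, 0, 0, 0, 0, 0),
    (-1, 0, 0, -1, 0, 0),
    (-1, 0, 0, -1, 0, -1),
    (-1, 1, 0, 0, 0, 0),
    (-1, 1, 0, -1, 0, 0),
    (-1, 1, 0, -1, 0, -1),
    (0, -1, 0, 0, 0, 0),
    (0, -1, 0, 0, 0, 0),
    (0, 0, 1, 0, 0, 0),
    (0, 0, -1, 0, 0, 0),
    (0, 0, 0, 1, 0, 0),
    (0, 0, 0, -1, 0, 0),
    (0, 0, 0, -1, 0, -1),
    (0, 0, 0, 0, 1, 0),
    (0, 0, 0, 0, -1, 0),
    (0, 0, 0, 0, 0, 1),
    (0, 0, 0, 0, 0, -1),
], dtype=np.int64)

_NCHAN = MODEL_STOICH.shape[0]


def pack_params(params, scaling) -> np.ndarray:
    """Flatten ModelParameters + ScalingSpec into the kernel parameter vector."""
    ns = float(scaling.n_star)
    return np.array([
        params.k_ecm, params.k_d("n"), params.k_a("s"), params.k_d("s"),
        params.k_d("m"), scaling.K_m * params.k_d("m"),
        params.k_a("x"), params.k_d("x"),
        scaling.K_r * params.k_d("r"), params.k_d("r"),
        params.k_a("p"), params.k_d("p"),
        params.E_s, params.I_n, params.C_s, params.p0, params.v0,
        ns, scaling.K_m * ns, scaling.K_r * ns,
    ], dtype=np.float64)


@njit(inline="always", cache=True)
def _mix64(z):
    z = (z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)
    return z ^ (z >> uint64(31))


@njit(inline="always", cache=True)
def _next_u64(state, i):
    state[i] += uint64(0x9E3779B97F4A7C15)
    return _mix64(state[i])


@njit(inline="always", cache=True)
def _uniform(state, i):
    # in (0, 1]; never 0 so it is safe inside log()
    return (np.float64(_next_u64(state, i) >> uint64(11)) + 1.0) * (2.0 ** -53)


@njit(inline="always", cache=True)
def _exponential(state, i):
    return -np.log(_uniform(state, i))


@njit(cache=True)
def _propensities(c, pv, a):
    kb, k_dn, k_as, k_ds, k_dm, k_am = pv[0], pv[1], pv[2], pv[3], pv[4], pv[5]
    k_ax, k_dx, k_ar, k_dr, k_ap, k_dp = pv[6], pv[7], pv[8], pv[9], pv[10], pv[11]
    Es, In, Cs, p0, v0 = pv[12], pv[13], pv[14], pv[15], pv[16]
    ns, Km_ns, Kr_ns = pv[17], pv[18], pv[19]
    N, S, M, X, R, P = c[0], c[1], c[2], c[3], c[4], c[5]
    drive = R / Kr_ns + v0
    v = drive / (1.0 + drive) / (1.0 + In * (S / ns))
    f = 1.0 + Es * (M / Km_ns)
    a[0] = kb * v * ns
    a[1] = k_dn * v * (N - X)
    a[2] = k_dn * v * (X - P)
    a[3] = k_dn * v * P
    a[4] = k_as * f * (N - X)
    a[5] = k_as * f * (X - P)
    a[6] = k_as * f * P
    a[7] = k_ds * S
    a[8] = k_ds * Cs * v * S
    a[9] = k_am * S
    a[10] = k_dm * M
    a[11] = k_ax * (P / ns + p0) * (N - X)
    a[12] = k_dx * (X - P)
    a[13] = k_dx * P
    a[14] = k_ar * X
    a[15] = k_dr * R
    a[16] = k_ap * (R / Kr_ns) * (X - P)
    a[17] = k_dp * P
    return v


@njit(cache=True)
def frm_kernel(pv, stoich, c0, t_end, seed, grid, max_events):
    c = c0.copy()
    rec = np.zeros((grid.size, 6), dtype=np.int64)
    state = np.empty(1, dtype=np.uint64)
    state[0] = _mix64(uint64(seed) + uint64(0x243F6A8885A308D3))
    a = np.empty(_NCHAN)
    t = 0.0
    g = 0
    nev = 0
    while nev < max_events:
        _propensities(c, pv, a)
        best = np.inf
        j = -1
        for k in range(_NCHAN):
            if a[k] > 0.0:
                tau = _exponential(state, 0) / a[k]
                if tau < best:
                    best = tau
                    j = k
        if j < 0:
            break
        t_next = t + best
        if t_next > t_end:
            break
        while g < grid.size and grid[g] < t_next:
            rec[g] = c
            g += 1
        for sp in range(6):
            c[sp] += stoich[j, sp]
        t = t_next
        nev += 1
    while g < grid.size:
        rec[g] = c
        g += 1
    return rec, nev


@njit(cache=True)
def nrm_kernel(pv, stoich, c0, t_end, seed, grid, max_events):
    c = c0.copy()
    rec = np.zeros((grid.size, 6), dtype=np.int64)
    state = np.empty(1, dtype=np.uint64)
    state[0] = _mix64(uint64(seed) + uint64(0x452821E638D01377))
    a = np.empty(_NCHAN)
    a_new = np.empty(_NCHAN)
    tau = np.full(_NCHAN, np.inf)
    _propensities(c, pv, a)
    for k in range(_NCHAN):
        if a[k] > 0.0:
            tau[k] = _exponential(state, 0) / a[k]
    t = 0.0
    g = 0
    nev = 0
    while nev < max_events:
        best = np.inf
        i = -1
        for k in range(_NCHAN):
            if tau[k] < best:
                best = tau[k]
                i = k
        if i < 0 or best > t_end:
            break
        while g < grid.size and grid[g] < best:
            rec[g] = c
            g += 1
        t = best
        for sp in range(6):
            c[sp] += stoich[i, sp]
        nev += 1
        _propensities(c, pv, a_new)
        for k in range(_NCHAN):
            if k == i:
                tau[k] = t + _exponential(state, 0) / a_new[k] if a_new[k] > 0.0 else np.inf
            elif a_new[k] <= 0.0:
                tau[k] = np.inf
            elif a[k] <= 0.0 or not np.isfinite(tau[k]):
                tau[k] = t + _exponential(state, 0) / a_new[k]
            elif a_new[k] != a[k]:
                tau[k] = t + (a[k] / a_new[k]) * (tau[k] - t)
            a[k] = a_new[k]
    while g < grid.size:
        rec[g] = c
        g += 1
    return rec, nev


@njit(cache=True)
def nsm_kernel(pv, stoich, counts0, hop, t_end, seed, grid, max_events):
    nsub = counts0.shape[0]
    counts = counts0.copy()
    rec = np.zeros((grid.size, nsub, 6), dtype=np.int64)
    # one independent stream per subvolume, derived from the master seed
    state = np.empty(nsub, dtype=np.uint64)
    for k in range(nsub):
        state[k] = _mix64(uint64(seed) * uint64(0x9E3779B97F4A7C15)
                          + uint64(k) + uint64(1))
    a_rxn = np.empty((nsub, _NCHAN))
    a_tot = np.empty(nsub)
    t_next = np.full(nsub, np.inf)
    for k in range(nsub):
        _propensities(counts[k], pv, a_rxn[k])
        a_tot[k] = a_rxn[k].sum() + 2.0 * hop * counts[k, 4]
        if a_tot[k] > 0.0:
            t_next[k] = _exponential(state, k) / a_tot[k]
    t = 0.0
    g = 0
    nev = 0
    while nev < max_events:
        best = np.inf
        k = -1
        for i in range(nsub):
            if t_next[i] < best:
                best = t_next[i]
                k = i
        if k < 0 or best > t_end:
            break
        while g < grid.size and grid[g] < best:
            rec[g] = counts
            g += 1
        t = best
        a_diff = 2.0 * hop * counts[k, 4]
        u = _uniform(state, k) * (a_tot[k] - 0.0)
        nb = -1
        if u < a_diff:
            # one active-Rac molecule hops to a uniformly chosen neighbor
            if _uniform(state, k) < 0.5:
                nb = (k - 1) % nsub
            else:
                nb = (k + 1) % nsub
            counts[k, 4] -= 1
            counts[nb, 4] += 1
        else:
            u -= a_diff
            acc = 0.0
            j = _NCHAN - 1
            for cch in range(_NCHAN):
                acc += a_rxn[k, cch]
                if u <= acc:
                    j = cch
                    break
            for sp in range(6):
                counts[k, sp] += stoich[j, sp]
        nev += 1
        _propensities(counts[k], pv, a_rxn[k])
        a_tot[k] = a_rxn[k].sum() + 2.0 * hop * counts[k, 4]
        t_next[k] = t + _exponential(state, k) / a_tot[k] if a_tot[k] > 0.0 else np.inf
        if nb >= 0 and nb != k:
            _propensities(counts[nb], pv, a_rxn[nb])
            a_tot[nb] = a_rxn[nb].sum() + 2.0 * hop * counts[nb, 4]
            t_next[nb] = t + _exponential(state, nb) / a_tot[nb] if a_tot[nb] > 0.0 else np.inf
    while g < grid.size:
        rec[g] = counts
        g += 1
    return rec, nev
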