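"""Exact stochastic simulation of the one-compartment molecule-number model.

Dimensionless densities are converted to molecule counts with a number-density
scale ``N*`` shared by the adhesion-type species (N, S, X, P), while myosin and
Rac counts are amplified relative to their activators: M* = K_m N*, R* = K_r N*
(so m = M/(K_m N*), r = R/(K_r N*)).  Every additive term of the mean-field
equations becomes one reaction channel; channels that remove nascent adhesions
are split over the phosphorylation sub-populations (N-X, X-P, P) so that the
subset invariants X <= N and P <= X hold after every event while the summed
drift matches the scaled deterministic right-hand side exactly.

Two statistically exact samplers of the resulting jump process are provided:
the First Reaction Method (per event, one exponential candidate time per
channel, earliest fires; ties break to the lowest channel index) and the Next
Reaction Method (absolute candidate firing times kept in an indexed priority
queue and rescaled when propensities change).  The protrusion velocity v is a
deterministic function of the current counts, recomputed from the velocity law
at every recorded sample; it is never itself a stochastic species.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .params import ModelParameters, ScalingSpec
from . import _kernels

__all__ = ["DiscreteState", "ReactionChannel", "ReactionNetwork",
           "compile_reactions", "simulate_frm", "simulate_nrm",
           "StochasticTrajectory", "run_phenotype_matrix"]

SPECIES = ("N", "S", "M", "X", "R", "P")


@dataclass(frozen=True)
class DiscreteState:
    """Integer molecule counts with the subset invariants enforced."""

    N: int = 0
    S: int = 0
    M: int = 0
    X: int = 0
    R: int = 0
    P: int = 0

    def __post_init__(self) -> None:
        for sp in SPECIES:
            if getattr(self, sp) < 0:
                raise ValueError(f"count {sp} must be non-negative")
        if self.X > self.N:
            raise ValueError("X cannot exceed N")
        if self.P > self.X:
            raise ValueError("P cannot exceed X")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, sp) for sp in SPECIES], dtype=np.int64)


@dataclass(frozen=True)
class ReactionChannel:
    """One elementary reaction: a stoichiometry vector and a propensity law."""

    name: str
    stoich: tuple[int, ...]                      # over (N, S, M, X, R, P)
    propensity: Callable[[np.ndarray], float]    # counts -> rate (min^-1)
    depends_on: tuple[int, ...] = (0, 1, 2, 3, 4, 5)


class ReactionNetwork:
    """A set of reaction channels plus an optional derived-velocity law."""

    def __init__(self, channels: Sequence[ReactionChannel],
                 velocity: Callable[[np.ndarray], float] | None = None):
        self.channels = list(channels)
        self.stoich = np.array([c.stoich for c in self.channels], dtype=np.int64)
        self.velocity = velocity
        self._fast: Callable[[np.ndarray], np.ndarray] | None = None
        self._packed: np.ndarray | None = None   # kernel parameter vector

    def __len__(self) -> int:
        return len(self.channels)

    def propensities(self, counts: np.ndarray) -> np.ndarray:
        if self._fast is not None:
            return self._fast(counts)
        return np.array([c.propensity(counts) for c in self.channels])


def compile_reactions(params: ModelParameters, scaling: ScalingSpec) -> ReactionNetwork:
    """Decompose the model into reaction channels at a given count scaling.

    Each channel's propensity equals the changed species' count scale times
    the dimensionless term rate evaluated at the mapped densities; the myosin
    and Rac formation channels therefore read k_a,m S and k_a,r X with
    k_a,m = K_m k_d,m and k_a,r = K_r k_d,r, which amplifies the M and R
    counts relative to their activators S and X.
    """
    ns = float(scaling.n_star)
    kb = params.k_ecm
    k_dn = params.k_d("n")
    k_as, k_ds = params.k_a("s"), params.k_d("s")
    k_dm = params.k_d("m")
    k_ax, k_dx = params.k_a("x"), params.k_d("x")
    k_dr = params.k_d("r")
    k_ap, k_dp = params.k_a("p"), params.k_d("p")
    k_am = scaling.K_m * k_dm
    k_ar = scaling.K_r * k_dr
    Es, In, Cs, p0, v0 = params.E_s, params.I_n, params.C_s, params.p0, params.v0
    Km_ns = scaling.K_m * ns
    Kr_ns = scaling.K_r * ns

    def vel(c: np.ndarray) -> float:
        drive = c[4] / Kr_ns + v0
        return drive / (1.0 + drive) / (1.0 + In * (c[1] / ns))

    def fm(c: np.ndarray) -> float:
        return 1.0 + Es * (c[2] / Km_ns)

    defs = [
        ("n_formation", (1, 0, 0, 0, 0, 0),
         lambda c: kb * vel(c) * ns, (1, 4)),
        ("n_turnover", (-1, 0, 0, 0, 0, 0),
         lambda c: k_dn * vel(c) * (c[0] - c[3]), (0, 1, 3, 4)),
        ("n_turnover_phospho", (-1, 0, 0, -1, 0, 0),
         lambda c: k_dn * vel(c) * (c[3] - c[5]), (1, 3, 4, 5)),
        ("n_turnover_phospho_pak", (-1, 0, 0, -1, 0, -1),
         lambda c: k_dn * vel(c) * c[5], (1, 4, 5)),
        ("maturation", (-1, 1, 0, 0, 0, 0),
         lambda c: k_as * fm(c) * (c[0] - c[3]), (0, 2, 3)),
        ("maturation_phospho", (-1, 1, 0, -1, 0, 0),
         lambda c: k_as * fm(c) * (c[3] - c[5]), (2, 3, 5)),
        ("maturation_phospho_pak", (-1, 1, 0, -1, 0, -1),
         lambda c: k_as * fm(c) * c[5], (2, 5)),
        ("s_disassembly", (0, -1, 0, 0, 0, 0),
         lambda c: k_ds * c[1], (1,)),
        ("s_convective_removal", (0, -1, 0, 0, 0, 0),
         lambda c: k_ds * Cs * vel(c) * c[1], (1, 4)),
        ("m_recruitment", (0, 0, 1, 0, 0, 0),
         lambda c: k_am * c[1], (1,)),
        ("m_release", (0, 0, -1, 0, 0, 0),
         lambda c: k_dm * c[2], (2,)),
        ("x_phosphorylation", (0, 0, 0, 1, 0, 0),
         lambda c: k_ax * (c[5] / ns + p0) * (c[0] - c[3]), (0, 3, 5)),
        ("x_dephosphorylation", (0, 0, 0, -1, 0, 0),
         lambda c: k_dx * (c[3] - c[5]), (3, 5)),
        ("x_dephosphorylation_pak", (0, 0, 0, -1, 0, -1),
         lambda c: k_dx * c[5], (5,)),
        ("r_activation", (0, 0, 0, 0, 1, 0),
         lambda c: k_ar * c[3], (3,)),
        ("r_deactivation", (0, 0, 0, 0, -1, 0),
         lambda c: k_dr * c[4], (4,)),
        ("p_activation", (0, 0, 0, 0, 0, 1),
         lambda c: k_ap * (c[4] / Kr_ns) * (c[3] - c[5]), (3, 4, 5)),
        ("p_deactivation", (0, 0, 0, 0, 0, -1),
         lambda c: k_dp * c[5], (5,)),
    ]
    channels = [ReactionChannel(nm, st, pr, dep) for nm, st, pr, dep in defs]
    net = ReactionNetwork(channels, velocity=vel)

    def fast(c: np.ndarray) -> np.ndarray:
        N, S, M, X, R, P = c
        v = vel(c)
        f = fm(c)
        return np.array([
            kb * v * ns,
            k_dn * v * (N - X), k_dn * v * (X - P), k_dn * v * P,
            k_as * f * (N - X), k_as * f * (X - P), k_as * f * P,
            k_ds * S, k_ds * Cs * v * S,
            k_am * S, k_dm * M,
            k_ax * (P / ns + p0) * (N - X),
            k_dx * (X - P), k_dx * P,
            k_ar * X, k_dr * R,
            k_ap * (R / Kr_ns) * (X - P), k_dp * P,
        ])

    net._fast = fast
    net._packed = _kernels.pack_params(params, scaling)
    assert np.array_equal(net.stoich, _kernels.MODEL_STOICH)
    return net


@dataclass
class StochasticTrajectory:
    """Sample-and-hold record of a jump-process realization."""

    t: np.ndarray
    counts: np.ndarray                  # shape (len(t), n_species)
    v: np.ndarray | None
    n_events: int
    seed: int | None = None
    method: str = ""
    event_times: np.ndarray | None = None
    event_channels: np.ndarray | None = None

    def to_dataframe(self, species: Sequence[str] = SPECIES) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(species))
        df.insert(0, "t", self.t)
        if self.v is not None:
            df["v"] = self.v
        return df


class _GridRecorder:
    """Sample-and-hold recorder on a uniform time grid."""

    def __init__(self, t_end: float, dt: float, n_species: int):
        grid = np.arange(0.0, t_end + 0.5 * dt, dt)
        if grid[-1] < t_end:
            grid = np.append(grid, t_end)
        grid[-1] = t_end
        self.grid = grid
        self.counts = np.zeros((len(grid), n_species), dtype=np.int64)
        self._g = 0

    def advance(self, t_event: float, counts_before: np.ndarray) -> None:
        """Fill grid points strictly before t_event with the pre-event state."""
        while self._g < len(self.grid) and self.grid[self._g] < t_event:
            self.counts[self._g] = counts_before
            self._g += 1

    def finish(self, counts: np.ndarray) -> None:
        while self._g < len(self.grid):
            self.counts[self._g] = counts
            self._g += 1


def _make_traj(net: ReactionNetwork, rec: _GridRecorder, n_events: int,
               seed, method, ev_t=None, ev_c=None) -> StochasticTrajectory:
    v = None
    if net.velocity is not None:
        v = np.array([net.velocity(c) for c in rec.counts])
    return StochasticTrajectory(rec.grid, rec.counts, v, n_events, seed, method,
                                None if ev_t is None else np.array(ev_t),
                                None if ev_c is None else np.array(ev_c, dtype=np.int64))


def _grid_for(t_end: float, dt: float) -> np.ndarray:
    grid = np.arange(0.0, t_end + 0.5 * dt, dt)
    if grid[-1] < t_end:
        grid = np.append(grid, t_end)
    grid[-1] = t_end
    return grid


def _kernel_run(kernel, net, state0, t_end, seed, dt_record, max_events, method):
    c0 = state0.to_array() if isinstance(state0, DiscreteState) else np.asarray(state0, np.int64)
    grid = _grid_for(t_end, dt_record)
    sd = int(seed) if seed is not None else int(np.random.default_rng().integers(2**31))
    rec, nev = kernel(net._packed, net.stoich, c0.copy(), float(t_end),
                      sd, grid, max_events)
    v = np.array([net.velocity(c) for c in rec]) if net.velocity is not None else None
    return StochasticTrajectory(grid, rec, v, int(nev), sd, method)


def simulate_frm(net: ReactionNetwork, state0, t_end: float, seed: int | None = None,
                 dt_record: float = 0.5, max_events: int = 50_000_000,
                 return_events: bool = False) -> StochasticTrajectory:
    """First Reaction Method: exact realization of the jump process.

    Model networks built by :func:`compile_reactions` dispatch to a compiled
    event loop; arbitrary networks run the generic loop below.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if net._packed is not None and not return_events:
        return _kernel_run(_kernels.frm_kernel, net, state0, t_end, seed,
                           dt_record, max_events, "FRM")
    rng = np.random.default_rng(seed)
    c = state0.to_array() if isinstance(state0, DiscreteState) else np.asarray(state0, np.int64).copy()
    t = 0.0
    rec = _GridRecorder(t_end, dt_record, c.size)
    stoich = net.stoich
    nchan = len(net)
    n_events = 0
    ev_t = [] if return_events else None
    ev_c = [] if return_events else None
    while t < t_end and n_events < max_events:
        a = net.propensities(c)
        if a.sum() <= 0.0:
            break
        with np.errstate(divide="ignore"):
            taus = rng.exponential(1.0, size=nchan) / a
        j = int(np.argmin(taus))          # ties resolve to the lowest index
        t_next = t + taus[j]
        if t_next > t_end:
            break
        rec.advance(t_next, c)
        c = c + stoich[j]
        t = t_next
        n_events += 1
        if return_events:
            ev_t.append(t)
            ev_c.append(j)
    rec.finish(c)
    return _make_traj(net, rec, n_events, seed, "FRM", ev_t, ev_c)


def simulate_nrm(net: ReactionNetwork, state0, t_end: float, seed: int | None = None,
                 dt_record: float = 0.5, max_events: int = 50_000_000,
                 return_events: bool = False) -> StochasticTrajectory:
    """Next Reaction Method: exact, with candidate-time reuse via rescaling.

    Absolute candidate firing times live in a priority queue; after an event,
    channels whose propensity changed have their unexpired candidate times
    rescaled by the old/new propensity ratio, which preserves the exponential
    law.  Distributionally equivalent to the First Reaction Method.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if net._packed is not None and not return_events:
        return _kernel_run(_kernels.nrm_kernel, net, state0, t_end, seed,
                           dt_record, max_events, "NRM")
    rng = np.random.default_rng(seed)
    c = state0.to_array() if isinstance(state0, DiscreteState) else np.asarray(state0, np.int64).copy()
    t = 0.0
    nchan = len(net)
    stoich = net.stoich
    dep = []
    for i in range(nchan):
        changed = {k for k, dv in enumerate(stoich[i]) if dv != 0}
        dep.append([j for j in range(nchan)
                    if changed & set(net.channels[j].depends_on) or j == i])

    a = net.propensities(c).astype(float)
    tau = np.full(nchan, np.inf)
    for j in range(nchan):
        if a[j] > 0:
            tau[j] = rng.exponential(1.0 / a[j])
    heap = [(tau[j], j) for j in range(nchan) if np.isfinite(tau[j])]
    heapq.heapify(heap)

    rec = _GridRecorder(t_end, dt_record, c.size)
    n_events = 0
    ev_t = [] if return_events else None
    ev_c = [] if return_events else None
    while n_events < max_events:
        while heap and heap[0][0] != tau[heap[0][1]]:
            heapq.heappop(heap)           # stale entry
        if not heap:
            break
        t_next, i = heap[0]
        if t_next > t_end:
            break
        rec.advance(t_next, c)
        t = t_next
        c = c + stoich[i]
        n_events += 1
        if return_events:
            ev_t.append(t)
            ev_c.append(i)
        a_new = net.propensities(c)
        for j in dep[i]:
            old, new = a[j], a_new[j]
            if j == i:
                tau[j] = t + rng.exponential(1.0 / new) if new > 0 else np.inf
            elif new <= 0:
                tau[j] = np.inf
            elif old <= 0 or not np.isfinite(tau[j]):
                tau[j] = t + rng.exponential(1.0 / new)
            else:
                tau[j] = t + (old / new) * (tau[j] - t)
            a[j] = new
            if np.isfinite(tau[j]):
                heapq.heappush(heap, (tau[j], j))
    rec.finish(c)
    return _make_traj(net, rec, n_events, seed, "NRM", ev_t, ev_c)


def run_phenotype_matrix(params_base: ModelParameters,
                         k_ecm_list: Sequence[float],
                         N_star_list: Sequence[int],
                         E_s_list: Sequence[float],
                         I_n_list: Sequence[float],
                         t_end: float = 1000.0,
                         seeds: Sequence[int] = (0,),
                         burn_in: float = 100.0,
                         keep_trajectories: bool = False):
    """Simulate and classify v(t) for each cell of the parameter matrix.

    Every run starts from the all-zero state.  Returns a DataFrame with one
    row per (k_ecm, N_star, E_s, I_n, seed), carrying the phenotype label and
    summary statistics of v(t) and S(t); raw trajectories are returned
    alongside when ``keep_trajectories`` is set.
    """
    from .phenotype import classify_trace

    if not (len(k_ecm_list) and len(N_star_list) and len(E_s_list) and len(I_n_list)):
        raise ValueError("all parameter grids must be non-empty")
    rows = []
    trajs = {}
    for kb in k_ecm_list:
        for ns in N_star_list:
            scaling = ScalingSpec(n_star=int(ns))
            for Es in E_s_list:
                for In in I_n_list:
                    p = params_base.with_overrides(k_ecm=kb, E_s=Es, I_n=In)
                    net = compile_reactions(p, scaling)
                    for sd in seeds:
                        traj = simulate_frm(net, DiscreteState(), t_end, seed=int(sd))
                        label = classify_trace(traj.v, traj.t, burn_in=burn_in)
                        mask = traj.t >= burn_in
                        rows.append(dict(
                            k_ecm=kb, N_star=int(ns), E_s=Es, I_n=In, seed=int(sd),
                            label=label,
                            mean_v=float(traj.v[mask].mean()),
                            median_v=float(np.median(traj.v[mask])),
                            mean_S=float(traj.counts[mask, 1].mean()),
                            n_events=traj.n_events,
                        ))
                        if keep_trajectories:
                            trajs[(kb, int(ns), Es, In, int(sd))] = traj
    df = pd.DataFrame(rows)
    return (df, trajs) if keep_trajectories else df
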