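"""Deterministic core of the leading-edge adhesion/protrusion model.

Six coupled dimensionless densities evolve in time (minutes):

.. math::

    dn/dt &= \\bar{k} v - k_{d,n} v\\, n - k_{a,s} f(m)\\, n \\\\
    ds/dt &= k_{a,s} f(m)\\, n - k_{d,s} (1 + C_s v)\\, s \\\\
    dm/dt &= k_{d,m} (s - m) \\\\
    dx/dt &= k_{a,x} (p + p_0)(n - x) - (k_{d,x} + \\lambda)\\, x \\\\
    dr/dt &= k_{d,r} (x - r) \\\\
    dp/dt &= k_{a,p} r (x - p) - (k_{d,p} + k_{d,x} + \\lambda)\\, p

with the linear feedback functions ``f(m) = 1 + E_s m`` and
``g(s) = 1 + I_n s``, the saturable velocity law

.. math:: v = \\frac{r + v_0}{1 + r + v_0} \\cdot \\frac{1}{g(s)},

and ``lambda = k_{d,n} v + k_{a,s} f(m)``, the per-capita rate at which
nascent adhesions leave the pool.  Because ``x`` is the subset of ``n``
carrying phosphorylated paxillin and ``p`` the subset of ``x`` carrying active
PAK, members of those subsets are lost whenever their carrier turns over,
matures, or (for ``p``) is dephosphorylated; the ``lambda`` terms keep the
mean-field equations exactly consistent with the discrete jump process and
preserve the subset ordering ``p <= x <= n`` along trajectories.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import ModelParameters

__all__ = [
    "ContinuousState", "Trajectory", "feedback_f", "feedback_g",
    "protrusion_velocity", "signaling_quasi_steady", "QuasiSteadySignaling",
    "rhs", "integrate_ode",
]

STATE_VARS = ("n", "s", "m", "x", "r", "p")


@dataclass(frozen=True)
class ContinuousState:
    """Dimensionless densities of the six model species."""

    n: float = 0.0
    s: float = 0.0
    m: float = 0.0
    x: float = 0.0
    r: float = 0.0
    p: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_VARS:
            if getattr(self, name) < 0:
                raise ValueError(f"density {name} must be non-negative")
        if self.x > self.n * (1 + 1e-9) + 1e-12:
            raise ValueError("x (phospho-paxillin subset) cannot exceed n")
        if self.p > self.x * (1 + 1e-9) + 1e-12:
            raise ValueError("p (active-PAK subset) cannot exceed x")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, v) for v in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "ContinuousState":
        return cls(**dict(zip(STATE_VARS, map(float, y))))


def feedback_f(m: float | np.ndarray, params: ModelParameters):
    """Myosin-dependent enhancement of adhesion maturation, f(m) = 1 + E_s*m.

    Setting ``E_s = 0`` turns the feedback off (f identically 1).
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("myosin density m must be non-negative")
    out = 1.0 + params.E_s * m
    return float(out) if out.ndim == 0 else out


def feedback_g(s: float | np.ndarray, params: ModelParameters):
    """Stable-adhesion inhibition of protrusion, g(s) = 1 + I_n*s.

    Setting ``I_n = 0`` turns the feedback off (g identically 1).
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("stable-adhesion density s must be non-negative")
    out = 1.0 + params.I_n * s
    return float(out) if out.ndim == 0 else out


def protrusion_velocity(r: float | np.ndarray, s: float | np.ndarray,
                        params: ModelParameters):
    """Dimensionless protrusion velocity.

    Protrusion responds to active Rac in a saturable manner, normalized so the
    maximum attainable velocity is 1, and is directly antagonized by stable
    adhesions through ``g(s)``; the small basal drive ``v0`` permits growth of
    nascent adhesions from the all-zero state.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("Rac density r must be non-negative")
    drive = r + params.v0
    out = drive / (1.0 + drive) / feedback_g(s, params)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class QuasiSteadySignaling:
    """One steady-state branch of the fast signaling subsystem at fixed (n, s)."""

    x: float
    r: float
    p: float
    v: float
    stable: bool
    residual: float


def _fast_balance(x: float, n: float, s: float, params: ModelParameters):
    """Return (residual of the x-balance, r, p, v, lam) at quasi-steady r, p."""
    k_dn = params.k_d("n")
    k_as = params.k_a("s")
    k_ax, k_dx = params.k_a("x"), params.k_d("x")
    k_ap, k_dp = params.k_a("p"), params.k_d("p")
    f = feedback_f(s, params)          # m = s at quasi-steady myosin
    r = x                              # dr/dt = k_dr (x - r)
    v = protrusion_velocity(r, s, params)
    lam = k_dn * v + k_as * f
    p = x * k_ap * r / (k_dp + k_dx + lam + k_ap * r)
    res = k_ax * (p + params.p0) * (n - x) - (k_dx + lam) * x
    return res, r, p, v, lam


def signaling_quasi_steady(n: float, s: float, params: ModelParameters,
                           scan_points: int = 400) -> list[QuasiSteadySignaling]:
    """All steady states of the fast (x, r, p) subsystem at fixed (n, s).

    The subsystem reduces to a single scalar balance in ``x`` on [0, n] after
    eliminating ``r`` and ``p`` at their own steady states.  All roots are
    isolated by a dense sign scan and polished by bracketed root finding; near
    the bistable regime the fast subsystem itself can carry three branches.
    Each branch is labelled stable/unstable from the eigenvalues of the 3x3
    fast-subsystem Jacobian.

    Returns branches sorted by ``x``; raises if the residual tolerance (1e-10)
    cannot be met.
    """
    if n < 0 or s < 0:
        raise ValueError("n and s must be non-negative")
    if n == 0:
        res, r, p, v, _ = _fast_balance(0.0, 0.0, s, params)
        return [QuasiSteadySignaling(0.0, 0.0, 0.0, v, True, abs(res))]

    def h(x):
        return _fast_balance(x, n, s, params)[0]

    grid = np.linspace(0.0, n, scan_points)
    vals = np.array([h(x) for x in grid])
    roots = [g for g, val in zip(grid, vals) if val == 0.0]
    for i in range(len(grid) - 1):
        if vals[i] * vals[i + 1] < 0:
            roots.append(brentq(h, grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16))
    if not roots:
        raise RuntimeError(f"no quasi-steady signaling state found for n={n}, s={s}")
    out = []
    for x in sorted(set(roots)):
        res, r, p, v, _ = _fast_balance(x, n, s, params)
        if abs(res) > 1e-10:
            raise RuntimeError(
                f"quasi-steady signaling residual {abs(res):.2e} exceeds 1e-10")
        out.append(QuasiSteadySignaling(x, r, min(p, x), v,
                                        _fast_branch_stable(x, n, s, params), abs(res)))
    return out


def _fast_branch_stable(x: float, n: float, s: float, params: ModelParameters,
                        eps: float = 1e-7) -> bool:
    """Stability of a fast-subsystem branch from the 3x3 (x, r, p) Jacobian."""
    def fast_rhs(z):
        xx, rr, pp = z
        k_dn = params.k_d("n")
        k_as = params.k_a("s")
        f = feedback_f(s, params)
        v = protrusion_velocity(max(rr, 0.0), s, params)
        lam = k_dn * v + k_as * f
        dx = params.k_a("x") * (pp + params.p0) * (n - xx) - (params.k_d("x") + lam) * xx
        dr = params.k_d("r") * (xx - rr)
        dp = params.k_a("p") * rr * (xx - pp) - (params.k_d("p") + params.k_d("x") + lam) * pp
        return np.array([dx, dr, dp])

    res, r, p, v, _ = _fast_balance(x, n, s, params)
    z0 = np.array([x, r, p])
    J = np.empty((3, 3))
    for j in range(3):
        dz = np.zeros(3)
        dz[j] = eps * max(1.0, abs(z0[j]))
        J[:, j] = (fast_rhs(z0 + dz) - fast_rhs(z0 - dz)) / (2 * dz[j])
    return bool(np.all(np.real(np.linalg.eigvals(J)) < 0))


def rhs(y: np.ndarray | ContinuousState, params: ModelParameters) -> np.ndarray:
    """Time derivatives (min^-1) of (n, s, m, x, r, p)."""
    if isinstance(y, ContinuousState):
        y = y.to_array()
    n, s, m, x, r, p = y
    k_dn = params.k_d("n")
    k_as, k_ds = params.k_a("s"), params.k_d("s")
    k_dm = params.k_d("m")
    k_ax, k_dx = params.k_a("x"), params.k_d("x")
    k_dr = params.k_d("r")
    k_ap, k_dp = params.k_a("p"), params.k_d("p")

    f = feedback_f(m, params)
    v = protrusion_velocity(r, s, params)
    lam = k_dn * v + k_as * f

    dn = params.k_ecm * v - k_dn * v * n - k_as * f * n
    ds = k_as * f * n - k_ds * (1.0 + params.C_s * v) * s
    dm = k_dm * (s - m)
    dx = k_ax * (p + params.p0) * (n - x) - (k_dx + lam) * x
    dr = k_dr * (x - r)
    dp = k_ap * r * (x - p) - (k_dp + k_dx + lam) * p
    return np.array([dn, ds, dm, dx, dr, dp])


@dataclass
class Trajectory:
    """Time series of the model state and derived protrusion velocity."""

    t: np.ndarray                 # minutes
    y: np.ndarray                 # shape (len(t), 6), columns n,s,m,x,r,p
    v: np.ndarray                 # dimensionless velocity

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(STATE_VARS))
        df.insert(0, "t", self.t)
        df["v"] = self.v
        return df

    @property
    def final_state(self) -> np.ndarray:
        return self.y[-1]


def integrate_ode(state0: ContinuousState | np.ndarray, params: ModelParameters,
                  t_end: float, dt_out: float = 0.5,
                  rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the deterministic system with a stiff, adaptive solver.

    The signaling variables relax an order of magnitude faster than the
    adhesion variables, so an implicit method (LSODA) with tight tolerances
    is used; ``dt_out`` only controls the dense-output grid.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = state0.to_array() if isinstance(state0, ContinuousState) else np.asarray(state0, float)
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval[-1] = min(t_eval[-1], t_end)
    sol = solve_ivp(lambda t, y: rhs(y, params), (0.0, t_end), y0,
                    method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed at t={sol.t[-1]:.4g}: {sol.message}")
    y = np.clip(sol.y.T, 0.0, None)   # clamp solver round-off below zero
    v = protrusion_velocity(y[:, 4], y[:, 1], params)
    return Trajectory(t=sol.t, y=y, v=np.asarray(v))
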