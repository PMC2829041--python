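"""Phase-plane analysis: nullclines, fixed points, and bistability cartography.

The slow variables are the adhesion densities (n, s); myosin and the
signaling circuit respond faster and are taken quasi-steady (m = s, and
(x, r, p) at the steady state of the fast subsystem).  Nullclines are drawn
in (v, s) space, the experimentally accessible plane: the n-nullcline is the
locus dn/dt = 0 and the s-nullcline ds/dt = 0, and their intersections are
fixed points of the full system.

Bistability is mapped over a (k_ecm, E_s) grid at fixed (I_n, C_s) by
counting fixed points per cell: 1 (monostable) or 3 (bistable: two stable
states separated by a saddle), with 2 tolerated and flagged on bifurcation
boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root

from .model import (ContinuousState, feedback_f, feedback_g,
                    protrusion_velocity, rhs, signaling_quasi_steady)
from .params import ModelParameters

__all__ = ["NullclineCurve", "FixedPoint", "BifurcationMap",
           "compute_nullcline", "find_fixed_points", "bifurcation_scan"]


# --------------------------------------------------------------------------
# quasi-steady parameterization by (x, s): n is a smooth single-valued
# function of the quasi-steady signaling level x, which makes multistart
# root finding robust even where x(n) is multivalued.
# --------------------------------------------------------------------------

def _qss_xs(x: float, s: float, params: ModelParameters):
    """Given quasi-steady x and s, return (n, r, p, v, f, lam)."""
    k_dn = params.k_d("n")
    k_as = params.k_a("s")
    k_ax, k_dx = params.k_a("x"), params.k_d("x")
    k_ap, k_dp = params.k_a("p"), params.k_d("p")
    f = feedback_f(s, params)
    r = x
    v = protrusion_velocity(r, s, params)
    lam = k_dn * v + k_as * f
    p = x * k_ap * r / (k_dp + k_dx + lam + k_ap * r)
    n = x * (1.0 + (k_dx + lam) / (k_ax * (p + params.p0)))
    return n, r, p, v, f, lam


def _slow_residuals(x: float, s: float, params: ModelParameters):
    n, r, p, v, f, lam = _qss_xs(x, s, params)
    F1 = params.k_ecm * v - params.k_d("n") * v * n - params.k_a("s") * f * n
    F2 = params.k_a("s") * f * n - params.k_d("s") * (1.0 + params.C_s * v) * s
    return F1, F2


@dataclass
class NullclineCurve:
    """Ordered samples of one nullcline in (v, s) space.

    ``segments`` splits the samples into continuous branches where the curve
    is multivalued.  ``diagnostic`` is set when no solution exists in the
    scanned window.
    """

    variable: str                      # "n" or "s"
    v: np.ndarray
    s: np.ndarray
    branch: np.ndarray                 # integer branch id per sample
    params: ModelParameters
    diagnostic: str = ""

    @property
    def segments(self) -> list[np.ndarray]:
        return [np.column_stack([self.v[self.branch == b], self.s[self.branch == b]])
                for b in np.unique(self.branch)]


def _x_roots_at_s(which: str, s: float, params: ModelParameters,
                  x_max: float, n_scan: int = 300) -> list[float]:
    idx = 0 if which == "n" else 1

    def h(x):
        return _slow_residuals(x, s, params)[idx]

    grid = np.linspace(0.0, x_max, n_scan)
    vals = np.array([h(x) for x in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(h, grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    return roots


def _default_s_window(params: ModelParameters) -> float:
    # generous first-pass cap: all of the maturation flux ends up in s at v=0
    return params.k_ecm / params.k_d("s") * 2.0 + 10.0


def compute_nullcline(which: str, params: ModelParameters,
                      resolution: int = 64) -> NullclineCurve:
    """Sample the n- or s-nullcline in (v, s) space.

    The scan window in s is chosen adaptively as 3x the largest s value on
    the s-nullcline; every reported sample satisfies the defining derivative
    condition with residual < 1e-8.
    """
    if which not in ("n", "s"):
        raise ValueError("which must be 'n' or 's'")
    if resolution < 16:
        raise ValueError("resolution must be >= 16")

    x_max = params.k_ecm / params.k_a("s") * 2.0 + 2.0
    # adaptive s window from a coarse pass over the s-nullcline
    s_cap = _default_s_window(params)
    coarse = np.linspace(0.0, s_cap, 48)
    s_seen = [s for s in coarse if _x_roots_at_s("s", s, params, x_max)]
    s_hi = 3.0 * max(s_seen) if s_seen else s_cap

    s_grid = np.linspace(0.0, s_hi, resolution)
    vs, ss, branches = [], [], []
    prev_roots: list[tuple[float, int]] = []
    next_branch = 0
    for s in s_grid:
        roots = _x_roots_at_s(which, s, params, x_max)
        assigned = []
        for xr in roots:
            n, r, p, v, f, lam = _qss_xs(xr, s, params)
            # continuity-based branch assignment
            if prev_roots:
                j = int(np.argmin([abs(xr - pr[0]) for pr in prev_roots]))
                if abs(xr - prev_roots[j][0]) < 0.25 * (1.0 + abs(xr)):
                    b = prev_roots[j][1]
                else:
                    b, next_branch = next_branch, next_branch + 1
            else:
                b, next_branch = next_branch, next_branch + 1
            vs.append(v)
            ss.append(s)
            branches.append(b)
            assigned.append((xr, b))
        prev_roots = assigned or prev_roots
    diag = "" if vs else "no nullcline solution in scanned window"
    return NullclineCurve(which, np.array(vs), np.array(ss),
                          np.array(branches, dtype=int), params, diag)


@dataclass
class FixedPoint:
    """A fixed point of the full system with its stability label."""

    state: ContinuousState
    v: float
    stability: str                      # "stable" | "unstable" | "saddle"
    eigenvalues: np.ndarray             # reduced (n, s) Jacobian eigenvalues
    residual: float
    flagged: bool = False               # set on bifurcation-boundary artifacts

    @property
    def n(self) -> float:
        return self.state.n

    @property
    def s(self) -> float:
        return self.state.s


def _reduced_rhs(n: float, s: float, params: ModelParameters,
                 x_hint: float) -> np.ndarray:
    """Slow (n, s) vector field on the quasi-steady branch nearest x_hint."""
    branches = signaling_quasi_steady(n, s, params, scan_points=160)
    q = min(branches, key=lambda b: abs(b.x - x_hint))
    f = feedback_f(s, params)
    dn = params.k_ecm * q.v - params.k_d("n") * q.v * n - params.k_a("s") * f * n
    ds = params.k_a("s") * f * n - params.k_d("s") * (1.0 + params.C_s * q.v) * s
    return np.array([dn, ds])


def _classify(eigs: np.ndarray) -> str:
    re = np.real(eigs)
    if np.all(re < 0):
        return "stable"
    if np.all(np.isreal(eigs)) and re.min() < 0 < re.max():
        return "saddle"
    return "unstable"


def find_fixed_points(params: ModelParameters, compute_stability: bool = True,
                      n_starts: tuple[int, int] = (12, 9)) -> list[FixedPoint]:
    """Locate all fixed points by multistart root finding in (x, s) space.

    Away from bifurcation boundaries the count is odd (1 or 3); each point
    carries a stability label from the reduced (n, s) Jacobian evaluated with
    the fast variables quasi-steady.
    """
    x_max = params.k_ecm / params.k_a("s") * 2.0 + 1.0
    s_max = _default_s_window(params)

    def F(z):
        return _slow_residuals(abs(z[0]), abs(z[1]), params)

    found: list[tuple[float, float]] = []
    xg = np.concatenate([[1e-6, 1e-4, 1e-3], np.geomspace(0.01, x_max, n_starts[0])])
    sg = np.concatenate([[1e-6, 1e-3], np.geomspace(0.01, s_max, n_starts[1])])
    for x0 in xg:
        for s0 in sg:
            sol = root(F, [x0, s0], method="hybr", tol=1e-13)
            if not sol.success:
                continue
            x, s = abs(sol.x[0]), abs(sol.x[1])
            r1, r2 = F([x, s])
            if max(abs(r1), abs(r2)) > 1e-9:
                continue
            if not any(abs(x - fx) < 1e-5 * (1 + fx) and abs(s - fs) < 1e-5 * (1 + fs)
                       for fx, fs in found):
                found.append((x, s))

    fps = []
    for x, s in sorted(found):
        n, r, p, v, f, lam = _qss_xs(x, s, params)
        full = ContinuousState(n=n, s=s, m=s, x=x, r=r, p=min(p, x))
        resid = float(np.max(np.abs(rhs(full, params))))
        if compute_stability:
            J = np.empty((2, 2))
            z0 = np.array([n, s])
            for j in range(2):
                dz = np.zeros(2)
                dz[j] = 1e-6 * max(1.0, abs(z0[j]))
                J[:, j] = (_reduced_rhs(*(z0 + dz), params, x_hint=x)
                           - _reduced_rhs(*(z0 - dz), params, x_hint=x)) / (2 * dz[j])
            eigs = np.linalg.eigvals(J)
            label = _classify(eigs)
        else:
            eigs = np.array([np.nan, np.nan])
            label = "unknown"
        fps.append(FixedPoint(full, float(v), label, eigs, resid))
    return sorted(fps, key=lambda fp: fp.v)


@dataclass
class BifurcationMap:
    """Fixed-point multiplicity over a (k_ecm, E_s) grid at fixed (I_n, C_s)."""

    k_ecm_grid: np.ndarray
    E_s_grid: np.ndarray
    I_n: float
    C_s: float
    multiplicity: np.ndarray            # shape (len(E_s_grid), len(k_ecm_grid))
    v_low: np.ndarray                   # lowest fixed-point v per cell
    v_high: np.ndarray                  # highest fixed-point v per cell
    flagged: np.ndarray = field(default=None)  # cells with even multiplicity

    def region(self, i: int, j: int, v_split: float = 0.25) -> str:
        if self.multiplicity[i, j] > 1:
            return "bistable"
        return "monostable_high" if self.v_high[i, j] >= v_split else "monostable_low"


def bifurcation_scan(k_ecm_grid, E_s_grid, I_n: float, C_s: float,
                     params: ModelParameters) -> BifurcationMap:
    """Count fixed points on each cell of a (k_ecm, E_s) grid."""
    k_ecm_grid = np.asarray(k_ecm_grid, dtype=float)
    E_s_grid = np.asarray(E_s_grid, dtype=float)
    for g, name in ((k_ecm_grid, "k_ecm_grid"), (E_s_grid, "E_s_grid")):
        if np.any(np.diff(g) <= 0):
            raise ValueError(f"{name} must be strictly increasing")
    mult = np.zeros((len(E_s_grid), len(k_ecm_grid)), dtype=int)
    v_lo = np.zeros_like(mult, dtype=float)
    v_hi = np.zeros_like(mult, dtype=float)
    flag = np.zeros_like(mult, dtype=bool)
    for i, Es in enumerate(E_s_grid):
        for j, kb in enumerate(k_ecm_grid):
            p = params.with_overrides(k_ecm=kb, E_s=Es, I_n=I_n, C_s=C_s)
            fps = find_fixed_points(p, compute_stability=False, n_starts=(10, 8))
            mult[i, j] = len(fps)
            if fps:
                v_lo[i, j] = fps[0].v
                v_hi[i, j] = fps[-1].v
            flag[i, j] = len(fps) % 2 == 0
    return BifurcationMap(k_ecm_grid, E_s_grid, I_n, C_s, mult, v_lo, v_hi, flag)
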