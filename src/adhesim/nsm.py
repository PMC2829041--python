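"""Spatially extended exact simulation via the Next Subvolume Method.

The virtual leading edge is a 1D periodic chain of subvolumes, each running
the full reaction set of the one-compartment model at its own N* scale.
Active Rac is the only mobile species ("adhesions are immobile", and myosin,
phospho-paxillin and PAK ride on adhesions): an R molecule hops to each of
its two neighbors at rate D_r / L^2 per direction, where the node spacing L
defaults to the characteristic Rac dispersion length sqrt(D_r / k_d,r) — with
the base-case values (D_r = 15 um^2/min, k_d,r = 4 min^-1) that is 1.94 um
and the per-direction hop frequency equals k_d,r.

Each subvolume keeps its own event clock: the next-event time is exponential
in its total (reaction + diffusion) propensity, the earliest subvolume fires,
and only the touched subvolumes redraw.  Per-subvolume RNG streams are
spawned from the master seed so results are reproducible and insensitive to
lattice size changes elsewhere.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters, ScalingSpec
from .ssa import DiscreteState, compile_reactions
from . import _kernels
from .phenotype import VelocityMap

__all__ = ["SpatialLattice", "SpatioTemporalTrajectory", "build_lattice",
           "simulate_nsm", "render_kymograph", "save_kymograph_png"]

_R_INDEX = 4  # position of R in the (N, S, M, X, R, P) count vector


@dataclass(frozen=True)
class SpatialLattice:
    """Geometry of the 1D periodic subvolume chain."""

    n_subvolumes: int = 20
    spacing: float = 1.94          # um
    D_r: float = 15.0              # um^2/min
    periodic: bool = True

    def __post_init__(self) -> None:
        # a single subvolume degenerates to the well-mixed compartment
        # (hops become no-ops onto itself)
        if self.n_subvolumes < 1:
            raise ValueError("need at least 1 subvolume")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def hop_rate(self) -> float:
        """Per-molecule hop frequency to each neighbor (min^-1)."""
        return self.D_r / self.spacing ** 2


def build_lattice(params: ModelParameters, n_subvolumes: int = 20) -> SpatialLattice:
    """Build the lattice with node spacing sqrt(D_r / k_d,r)."""
    k_dr = params.k_d("r")
    if params.D_r < 0 or k_dr <= 0:
        raise ValueError("require D_r >= 0 and k_d,r > 0 to set the node spacing")
    if params.D_r == 0:
        # decoupled compartments; spacing is arbitrary but must be positive
        return SpatialLattice(n_subvolumes, 1.0, 0.0)
    spacing = float(np.sqrt(params.D_r / k_dr))
    return SpatialLattice(n_subvolumes, spacing, params.D_r)


@dataclass
class SpatioTemporalTrajectory:
    """Sample-and-hold record of the spatial jump process."""

    t: np.ndarray                  # (T,)
    counts: np.ndarray             # (T, n_subvolumes, 6)
    v: np.ndarray                  # (T, n_subvolumes)
    n_events: int
    seed: int | None = None


def simulate_nsm(lattice: SpatialLattice, params: ModelParameters,
                 scaling: ScalingSpec, state0=None, t_end: float = 1000.0,
                 seed: int | None = None, dt_record: float = 0.5,
                 max_events: int = 200_000_000) -> SpatioTemporalTrajectory:
    """Exact Next Subvolume Method realization.

    ``state0`` may be None (all zero), a DiscreteState applied to every
    subvolume, or an array of shape (n_subvolumes, 6).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    nsub = lattice.n_subvolumes
    net = compile_reactions(params, scaling)
    hop = lattice.hop_rate

    if state0 is None:
        counts = np.zeros((nsub, 6), dtype=np.int64)
    elif isinstance(state0, DiscreteState):
        counts = np.tile(state0.to_array(), (nsub, 1))
    else:
        counts = np.asarray(state0, dtype=np.int64).copy()
        if counts.shape != (nsub, 6):
            raise ValueError(f"state0 must have shape ({nsub}, 6)")

    grid = np.arange(0.0, t_end + 0.5 * dt_record, dt_record)
    if grid[-1] < t_end:
        grid = np.append(grid, t_end)
    grid[-1] = t_end
    sd = int(seed) if seed is not None else int(np.random.default_rng().integers(2**31))
    rec, n_events = _kernels.nsm_kernel(net._packed, net.stoich, counts,
                                        float(hop), float(t_end), sd, grid,
                                        max_events)
    v = np.empty((len(grid), nsub))
    for k in range(nsub):
        v[:, k] = [net.velocity(c) for c in rec[:, k, :]]
    return SpatioTemporalTrajectory(grid, rec, v, int(n_events), sd)


def render_kymograph(traj: SpatioTemporalTrajectory,
                     lattice: SpatialLattice | None = None,
                     frame_interval: float | None = None):
    """Velocity map (position x time) and stable-adhesion map from a run.

    Values are sample-and-hold copies of the recorded series, no smoothing.
    Returns ``(velocity_map, adhesion_counts)``.
    """
    if traj.t.size == 0:
        raise ValueError("empty trajectory")
    vmap = traj.v.T.copy()                     # rows = positions, cols = time
    smap = traj.counts[:, :, 1].T.astype(float)
    step = lattice.spacing if lattice is not None else 1.0
    dt = frame_interval if frame_interval is not None else float(np.median(np.diff(traj.t)))
    velocity_map = VelocityMap(values=vmap, spatial_step=step,
                               frame_interval=dt, units="dimensionless")
    return velocity_map, smap


def save_kymograph_png(velocity_map: VelocityMap, path, adhesion_map=None,
                       adhesion_path=None) -> None:
    """Write grayscale velocity (white v=0, black v=1) and, optionally, the
    stable-adhesion map (black S=0 to red S=max) as PNG images."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.imshow(velocity_map.values, cmap="gray_r", vmin=0.0, vmax=1.0,
              aspect="auto", origin="lower", interpolation="nearest")
    ax.set_xlabel("time bin")
    ax.set_ylabel("position")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    if adhesion_map is not None and adhesion_path is not None:
        cmap = LinearSegmentedColormap.from_list("adh", ["black", "red"])
        smax = adhesion_map.max() if adhesion_map.max() > 0 else 1.0
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.imshow(adhesion_map, cmap=cmap, vmin=0.0, vmax=smax,
                  aspect="auto", origin="lower", interpolation="nearest")
        ax.set_xlabel("time bin")
        ax.set_ylabel("position")
        fig.tight_layout()
        fig.savefig(adhesion_path, dpi=150)
        plt.close(fig)
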