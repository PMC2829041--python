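"""Phenotype classification and velocity-map event segmentation.

A stochastic v(t) trace falls in one of four phenotypes:

* ``stable_protrusion``      — high baseline, no pauses;
* ``protrusion_with_pauses`` — high baseline punctuated by sub-threshold dips;
* ``transient_protrusions``  — low baseline punctuated by at least one brief
  excursion peaking above 0.5 (the initial transient excluded);
* ``minimal_protrusion``     — low baseline, no such excursion.

On velocity maps (protrusion velocity over position x time), a protrusion
event is a contiguous region exceeding a low threshold (1 nm/s) that contains
at least one cell exceeding a high threshold (5 nm/s); above-low cells not
connected to any above-high cell are discarded.  Total protrusive activity is
the summed event area (length x time) normalized by the map duration.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["PHENOTYPES", "VelocityMap", "ProtrusionEvent", "MapRegion",
           "classify_trace", "smooth_trace", "segment_protrusion_events",
           "total_protrusive_activity", "make_synthetic_velocity_map",
           "random_velocity_map"]

PHENOTYPES = ("stable_protrusion", "protrusion_with_pauses",
              "transient_protrusions", "minimal_protrusion")


@dataclass
class VelocityMap:
    """2D protrusion-velocity array over (position, time).

    ``mask`` marks cells where the velocity could not be determined; masked
    cells break event connectivity.
    """

    values: np.ndarray                     # shape (n_positions, n_frames)
    spatial_step: float = 1.0              # um per row
    frame_interval: float = 1.0            # min per column
    units: str = "dimensionless"           # or "nm_per_s"
    mask: np.ndarray | None = None         # True where undetermined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("velocity map must be 2D (position x time)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")
        if not np.all(np.isfinite(self.values[~self.mask if self.mask is not None
                                              else slice(None)])):
            raise ValueError("velocity map contains non-finite unmasked values")

    @property
    def duration(self) -> float:
        return self.values.shape[1] * self.frame_interval


@dataclass
class ProtrusionEvent:
    """One contiguous protrusion event on a velocity map."""

    cells: np.ndarray                      # (k, 2) array of (row, col) indices
    peak_velocity: float
    spatial_step: float = 1.0
    frame_interval: float = 1.0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def area(self) -> float:
        """Event area in length x time units."""
        return self.n_cells * self.spatial_step * self.frame_interval


def classify_trace(v_series: Sequence[float], t_series: Sequence[float],
                   burn_in: float = 100.0, high_threshold: float = 0.5,
                   pause_min_duration: float = 2.0) -> str:
    """Assign one of the four phenotypes to a v(t) trace.

    The baseline is called from the post-burn-in median of v: a high baseline
    (median >= ``high_threshold``) yields stable protrusion, or protrusion
    with pauses if any maximal sub-threshold dip lasts at least
    ``pause_min_duration`` minutes; a low baseline yields transient
    protrusions if any post-burn-in sample exceeds ``high_threshold``, and
    minimal protrusion otherwise.
    """
    v = np.asarray(v_series, dtype=float)
    t = np.asarray(t_series, dtype=float)
    if v.shape != t.shape or v.ndim != 1:
        raise ValueError("v_series and t_series must be 1D and equal length")
    if t[-1] <= burn_in:
        raise ValueError(f"trace duration {t[-1]} must exceed burn_in {burn_in}")
    sel = t >= burn_in
    vp, tp = v[sel], t[sel]
    if np.median(vp) >= high_threshold:
        below = vp < high_threshold
        # maximal sub-threshold runs and their durations
        edges = np.diff(below.astype(int))
        starts = list(np.where(edges == 1)[0] + 1)
        ends = list(np.where(edges == -1)[0] + 1)
        if below[0]:
            starts.insert(0, 0)
        if below[-1]:
            ends.append(len(vp))
        for i0, i1 in zip(starts, ends):
            if tp[min(i1, len(tp) - 1)] - tp[i0] >= pause_min_duration:
                return "protrusion_with_pauses"
        return "stable_protrusion"
    if np.any(vp > high_threshold):
        return "transient_protrusions"
    return "minimal_protrusion"


def smooth_trace(series: Sequence[float], window_frames: int = 20) -> np.ndarray:
    """Centered moving average with a shrinking window at the boundaries."""
    if window_frames < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(series, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    if window_frames == 1:
        return v.copy()
    kernel = np.ones(window_frames)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def segment_protrusion_events(vmap: VelocityMap, low: float = 1.0,
                              high: float = 5.0, connectivity: int = 4,
                              conversion: float | None = None) -> list[ProtrusionEvent]:
    """Find contiguous protrusion events on a velocity map.

    Above-high cells seed events; above-low cells join an event iff they are
    connected to a seed through above-low cells; above-low cells with no seed
    connection are excluded.  Masked cells break connectivity.  Thresholds are
    in nm/s; a dimensionless map must supply ``conversion`` (nm/s per unit v).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    vals = vmap.values
    if vmap.units == "nm_per_s":
        pass
    elif vmap.units == "dimensionless":
        if conversion is None:
            raise ValueError(
                "dimensionless map requires a conversion factor to nm/s")
        vals = vals * conversion
    else:
        raise ValueError(f"unknown velocity units {vmap.units!r}")
    valid = np.isfinite(vals)
    if vmap.mask is not None:
        valid &= ~vmap.mask
    above_low = valid & (vals > low)
    labels, n_comp = ndimage.label(above_low, structure=_STRUCTURES[connectivity])
    events = []
    for lab in range(1, n_comp + 1):
        cells = np.argwhere(labels == lab)
        cell_vals = vals[labels == lab]
        if np.any(cell_vals > high):
            events.append(ProtrusionEvent(
                cells=cells, peak_velocity=float(cell_vals.max()),
                spatial_step=vmap.spatial_step,
                frame_interval=vmap.frame_interval))
    return events


def total_protrusive_activity(events: Sequence[ProtrusionEvent],
                              map_duration: float,
                              spatial_step: float | None = None,
                              frame_interval: float | None = None) -> float:
    """Summed event area normalized by the observation duration (units: length)."""
    if map_duration <= 0:
        raise ValueError("map duration must be positive")
    total = 0.0
    for ev in events:
        step = spatial_step if spatial_step is not None else ev.spatial_step
        dt = frame_interval if frame_interval is not None else ev.frame_interval
        total += ev.n_cells * step * dt
    return total / map_duration


@dataclass(frozen=True)
class MapRegion:
    """A rectangular block on a synthetic velocity map.

    ``kind`` is "event" (supra-high block), "patch" (sub-high block) or
    "mask" (undetermined cells).
    """

    row0: int
    row1: int
    col0: int
    col1: int
    value: float = 0.0
    kind: str = "event"

    def slices(self):
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def overlaps(self, other: "MapRegion") -> bool:
        return (self.row0 < other.row1 and other.row0 < self.row1
                and self.col0 < other.col1 and other.col0 < self.col1)


def make_synthetic_velocity_map(shape: tuple[int, int],
                                regions: Sequence[MapRegion],
                                background: float = 0.0,
                                noise_sd: float = 0.0,
                                seed: int | None = None,
                                spatial_step: float = 1.0,
                                frame_interval: float = 1.0,
                                units: str = "nm_per_s"):
    """Seeded synthetic velocity map with ground-truth event labels.

    Returns ``(VelocityMap, truth)`` where ``truth`` is an integer array with
    one positive id per "event" region (0 elsewhere).  Distinct value-carrying
    regions may not overlap.
    """
    rng = np.random.default_rng(seed)
    n_pos, n_t = shape
    for reg in regions:
        if not (0 <= reg.row0 < reg.row1 <= n_pos and 0 <= reg.col0 < reg.col1 <= n_t):
            raise ValueError(f"region {reg} outside map bounds {shape}")
    value_regions = [r for r in regions if r.kind != "mask"]
    for i, a in enumerate(value_regions):
        for b in value_regions[i + 1:]:
            if a.overlaps(b):
                raise ValueError(f"contradictory overlapping regions: {a} and {b}")
    values = np.full(shape, float(background))
    truth = np.zeros(shape, dtype=int)
    ev_id = 0
    for reg in regions:
        if reg.kind == "mask":
            continue
        values[reg.slices()] = reg.value
        if reg.kind == "event":
            ev_id += 1
            truth[reg.slices()] = ev_id
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=shape)
    mask = None
    mask_regions = [r for r in regions if r.kind == "mask"]
    if mask_regions:
        mask = np.zeros(shape, dtype=bool)
        for reg in mask_regions:
            mask[reg.slices()] = True
    vmap = VelocityMap(values=values, spatial_step=spatial_step,
                       frame_interval=frame_interval, units=units, mask=mask)
    return vmap, truth


def random_velocity_map(seed: int, shape: tuple[int, int] = (40, 60),
                        n_events: int = 3, n_patches: int = 3,
                        noise_sd: float = 0.0, with_mask: bool = False):
    """Random non-overlapping layout of event blocks and sub-high patches.

    Blocks are placed on a coarse lattice with at least one empty cell between
    them, so each "event" region is recovered as exactly one segmented event
    at zero noise.
    """
    rng = np.random.default_rng(seed)
    n_pos, n_t = shape
    # coarse lattice of 10x10 slots with 2-cell gaps
    slot_r, slot_c = 10, 10
    rows = (n_pos - 2) // slot_r
    cols = (n_t - 2) // slot_c
    slots = [(i, j) for i in range(rows) for j in range(cols)]
    rng.shuffle(slots)
    regions = []
    kinds = ["event"] * n_events + ["patch"] * n_patches
    if with_mask:
        kinds.append("mask")
    if len(kinds) > len(slots):
        raise ValueError("map too small for requested regions")
    for kind, (si, sj) in zip(kinds, slots):
        r0 = si * slot_r + 2
        c0 = sj * slot_c + 2
        h = int(rng.integers(2, slot_r - 3))
        w = int(rng.integers(2, slot_c - 3))
        if kind == "event":
            val = float(rng.uniform(5.5, 10.0))
        elif kind == "patch":
            val = float(rng.uniform(1.5, 4.5))
        else:
            val = 0.0
        regions.append(MapRegion(r0, r0 + h, c0, c0 + w, val, kind))
    return make_synthetic_velocity_map(shape, regions, background=0.0,
                                       noise_sd=noise_sd, seed=seed + 1)
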