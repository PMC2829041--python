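import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adhesim import (MapRegion, VelocityMap, classify_trace,
                     make_synthetic_velocity_map, random_velocity_map,
                     segment_protrusion_events, smooth_trace,
                     total_protrusive_activity)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


# ------------------------------------------------------------- classification

def _trace(values, dt=0.5):
    v = np.asarray(values, dtype=float)
    return v, np.arange(len(v)) * dt


def test_classify_flat_zero_is_minimal():
    v, t = _trace(np.zeros(500))
    assert classify_trace(v, t, burn_in=100.0) == "minimal_protrusion"


def test_classify_low_baseline_with_excursion_is_transient():
    v, t = _trace(np.full(600, 0.05))
    v[420:425] = 0.8        # one brief excursion after burn-in
    assert classify_trace(v, t, burn_in=100.0) == "transient_protrusions"


def test_classify_excursion_only_in_initial_transient_is_minimal():
    v, t = _trace(np.full(600, 0.05))
    v[50:60] = 0.9          # before the 100-min burn-in
    assert classify_trace(v, t, burn_in=100.0) == "minimal_protrusion"


def test_classify_high_flat_is_stable():
    v, t = _trace(np.full(600, 0.9))
    assert classify_trace(v, t, burn_in=100.0) == "stable_protrusion"


def test_classify_high_with_long_dip_is_pauses():
    v, t = _trace(np.full(600, 0.9))
    v[400:410] = 0.1        # 5-minute dip below threshold
    assert classify_trace(v, t, burn_in=100.0) == "protrusion_with_pauses"


def test_classify_high_with_subminute_dip_is_stable():
    v, t = _trace(np.full(600, 0.9))
    v[400:402] = 0.1        # 1-minute dip: shorter than the 2-min pause rule
    assert classify_trace(v, t, burn_in=100.0) == "stable_protrusion"


def test_classify_short_trace_rejected():
    v, t = _trace(np.zeros(100))
    with pytest.raises(ValueError):
        classify_trace(v, t, burn_in=100.0)


@given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 1000))
def test_classification_invariant_to_time_rescaling(scale, seed):
    """Labels depend on v levels and ordering, not absolute duration, once
    the explicit time parameters are rescaled alongside."""
    rng = np.random.default_rng(seed)
    v = np.clip(rng.uniform(0, 1, 400) * rng.choice([0.2, 1.0]), 0, 1)
    t = np.arange(400) * 0.5
    lab1 = classify_trace(v, t, burn_in=50.0, pause_min_duration=2.0)
    lab2 = classify_trace(v, t * scale, burn_in=50.0 * scale,
                          pause_min_duration=2.0 * scale)
    assert lab1 == lab2


# ------------------------------------------------------------------ smoothing

def test_smooth_constant_unchanged():
    out = smooth_trace(np.full(100, 3.7), window_frames=20)
    assert np.allclose(out, 3.7)


def test_smooth_window_one_is_identity(rng):
    v = rng.normal(size=50)
    assert np.array_equal(smooth_trace(v, 1), v)


def test_smooth_impulse_spreads_to_plateau():
    v = np.zeros(101)
    v[50] = 1.0
    out = smooth_trace(v, window_frames=20)
    covered = out[out > 0]
    assert len(covered) == 20
    assert np.allclose(covered, 1.0 / 20.0)
    # independent oracle: direct normalized convolution
    oracle = np.convolve(v, np.ones(20), "same") / np.convolve(
        np.ones_like(v), np.ones(20), "same")
    assert np.allclose(out, oracle)


def test_smooth_empty_rejected():
    with pytest.raises(ValueError):
        smooth_trace([], 20)


# --------------------------------------------------------------- segmentation

def _nm_map(values, **kw):
    return VelocityMap(values=np.asarray(values, float), units="nm_per_s", **kw)


def test_segment_empty_map():
    assert segment_protrusion_events(_nm_map(np.zeros((10, 10)))) == []


def test_segment_block_with_adjoining_ring():
    """A supra-high block plus its touching above-low ring form one event."""
    m = np.zeros((9, 9))
    m[2:7, 2:7] = 2.0           # above-low ring
    m[3:6, 3:6] = 6.0           # above the 5 nm/s seed threshold
    events = segment_protrusion_events(_nm_map(m))
    assert len(events) == 1
    assert events[0].n_cells == 25
    assert events[0].peak_velocity == 6.0


def test_segment_isolated_subhigh_patch_excluded():
    m = np.zeros((10, 10))
    m[1:3, 1:3] = 3.0           # above low, never above high, no seed contact
    assert segment_protrusion_events(_nm_map(m)) == []


def test_segment_mask_breaks_connectivity():
    m = np.zeros((5, 9))
    m[2, :] = 2.0
    m[2, 0] = 6.0                # seed at the left end of the bridge
    mask = np.zeros_like(m, dtype=bool)
    events = segment_protrusion_events(_nm_map(m, mask=mask))
    assert len(events) == 1 and events[0].n_cells == 9
    mask[2, 4] = True            # masked cell cuts the bridge
    events = segment_protrusion_events(_nm_map(m, mask=mask))
    assert len(events) == 1 and events[0].n_cells == 4


def test_segment_dimensionless_requires_conversion():
    vmap = VelocityMap(values=np.zeros((4, 4)), units="dimensionless")
    with pytest.raises(ValueError):
        segment_protrusion_events(vmap)
    assert segment_protrusion_events(vmap, conversion=10.0) == []


def _flood_fill_oracle(values, mask, low, high, connectivity=4):
    """Brute-force BFS flood fill, independent of the scipy-based path."""
    n, m = values.shape
    ok = (values > low) & ~mask
    seen = np.zeros_like(ok)
    comps = []
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    for i in range(n):
        for j in range(m):
            if ok[i, j] and not seen[i, j]:
                stack, comp = [(i, j)], []
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    comp.append((a, b))
                    for da, db in steps:
                        x, y = a + da, b + db
                        if 0 <= x < n and 0 <= y < m and ok[x, y] and not seen[x, y]:
                            seen[x, y] = True
                            stack.append((x, y))
                if any(values[a, b] > high for a, b in comp):
                    comps.append(frozenset(comp))
    return set(comps)


@pytest.mark.parametrize("with_mask", [False, True])
def test_segmentation_matches_flood_fill_oracle(with_mask):
    """Cell-exact agreement with an independent flood fill on 50 random maps."""
    for seed in range(50):
        vmap, _ = random_velocity_map(seed, shape=(30, 40), n_events=2,
                                      n_patches=2, noise_sd=1.2,
                                      with_mask=with_mask)
        events = segment_protrusion_events(vmap)
        got = {frozenset(map(tuple, ev.cells)) for ev in events}
        mask = vmap.mask if vmap.mask is not None else np.zeros_like(
            vmap.values, dtype=bool)
        expected = _flood_fill_oracle(vmap.values, mask, 1.0, 5.0)
        assert got == expected


def test_segmentation_threshold_monotone():
    """Raising `high` never adds events; raising `low` never adds area."""
    for seed in range(10):
        vmap, _ = random_velocity_map(seed, noise_sd=1.5)
        n_events, areas = [], []
        for hi in (4.0, 5.0, 7.0):
            n_events.append(len(segment_protrusion_events(vmap, high=hi)))
        assert n_events == sorted(n_events, reverse=True)
        for lo in (0.5, 1.0, 2.0):
            evs = segment_protrusion_events(vmap, low=lo)
            areas.append(sum(ev.n_cells for ev in evs))
        assert areas == sorted(areas, reverse=True)


def test_segmentation_idempotent():
    vmap, _ = random_velocity_map(3, noise_sd=1.0)
    e1 = segment_protrusion_events(vmap)
    e2 = segment_protrusion_events(vmap)
    assert [set(map(tuple, e.cells)) for e in e1] == \
           [set(map(tuple, e.cells)) for e in e2]


# ------------------------------------------------------------ activity metric

def test_total_activity_empty():
    assert total_protrusive_activity([], map_duration=30.0) == 0.0


def test_total_activity_arithmetic():
    m = np.zeros((10, 12))
    m[2:4, 3:8] = 6.0            # one event of 10 cells
    vmap = _nm_map(m)
    vmap.spatial_step, vmap.frame_interval = 1.0, 0.5
    events = segment_protrusion_events(vmap)
    assert sum(ev.n_cells for ev in events) == 10
    tpa = total_protrusive_activity(events, map_duration=30.0)
    assert tpa == pytest.approx(10 * 1.0 * 0.5 / 30.0)
    with pytest.raises(ValueError):
        total_protrusive_activity(events, map_duration=0.0)


def test_total_activity_transpose_symmetric():
    vmap, _ = random_velocity_map(11, noise_sd=0.8)
    ev = segment_protrusion_events(vmap)
    a1 = total_protrusive_activity(ev, 30.0, spatial_step=2.0, frame_interval=0.5)
    vm_t = VelocityMap(values=vmap.values.T, units="nm_per_s",
                       spatial_step=vmap.frame_interval,
                       frame_interval=vmap.spatial_step)
    ev_t = segment_protrusion_events(vm_t)
    a2 = total_protrusive_activity(ev_t, 30.0, spatial_step=0.5, frame_interval=2.0)
    assert a1 == pytest.approx(a2)


# ------------------------------------------------------------- fixture maps

def test_synthetic_map_trivial_and_reproducible():
    vmap, truth = make_synthetic_velocity_map((10, 10), [], background=0.0)
    assert np.all(vmap.values == 0) and np.all(truth == 0)
    m1, _ = random_velocity_map(5, noise_sd=1.0)
    m2, _ = random_velocity_map(5, noise_sd=1.0)
    assert np.array_equal(m1.values, m2.values)


def test_synthetic_map_rejects_bad_layouts():
    with pytest.raises(ValueError):
        make_synthetic_velocity_map((10, 10), [MapRegion(5, 15, 0, 3, 6.0)])
    with pytest.raises(ValueError):
        make_synthetic_velocity_map(
            (10, 10), [MapRegion(0, 4, 0, 4, 6.0), MapRegion(2, 6, 2, 6, 2.0, "patch")])


def test_ground_truth_recovered_at_zero_noise():
    """Each generated event block is segmented back exactly, none spurious."""
    for seed in range(20):
        vmap, truth = random_velocity_map(seed, n_events=3, n_patches=3,
                                          noise_sd=0.0)
        events = segment_protrusion_events(vmap)
        assert len(events) == truth.max()
        got = {frozenset(map(tuple, ev.cells)) for ev in events}
        expected = {frozenset(map(tuple, np.argwhere(truth == k)))
                    for k in range(1, truth.max() + 1)}
        assert got == expected
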