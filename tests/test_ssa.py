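import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from adhesim import (DiscreteState, ReactionChannel, ReactionNetwork, ScalingSpec,
                     base_case, compile_reactions, rhs, run_phenotype_matrix,
                     simulate_frm, simulate_nrm)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


# hand enumeration of the channel decomposition: one channel per additive term,
# with nascent-adhesion removal split over the phosphorylation sub-populations
EXPECTED_STOICH = {
    "n_formation": (1, 0, 0, 0, 0, 0),
    "n_turnover": (-1, 0, 0, 0, 0, 0),
    "n_turnover_phospho": (-1, 0, 0, -1, 0, 0),
    "n_turnover_phospho_pak": (-1, 0, 0, -1, 0, -1),
    "maturation": (-1, 1, 0, 0, 0, 0),
    "maturation_phospho": (-1, 1, 0, -1, 0, 0),
    "maturation_phospho_pak": (-1, 1, 0, -1, 0, -1),
    "s_disassembly": (0, -1, 0, 0, 0, 0),
    "s_convective_removal": (0, -1, 0, 0, 0, 0),
    "m_recruitment": (0, 0, 1, 0, 0, 0),
    "m_release": (0, 0, -1, 0, 0, 0),
    "x_phosphorylation": (0, 0, 0, 1, 0, 0),
    "x_dephosphorylation": (0, 0, 0, -1, 0, 0),
    "x_dephosphorylation_pak": (0, 0, 0, -1, 0, -1),
    "r_activation": (0, 0, 0, 0, 1, 0),
    "r_deactivation": (0, 0, 0, 0, -1, 0),
    "p_activation": (0, 0, 0, 0, 0, 1),
    "p_deactivation": (0, 0, 0, 0, 0, -1),
}


def random_discrete_state(rng):
    N = int(rng.integers(0, 12))
    X = int(rng.integers(0, N + 1))
    P = int(rng.integers(0, X + 1))
    return np.array([N, int(rng.integers(0, 8)), int(rng.integers(0, 60)),
                     X, int(rng.integers(0, 80)), P], dtype=np.int64)


def test_channel_enumeration(params, scaling):
    net = compile_reactions(params.with_overrides(E_s=3.0, I_n=2.0), scaling)
    assert len(net) == len(EXPECTED_STOICH)
    for ch in net.channels:
        assert tuple(ch.stoich) == EXPECTED_STOICH[ch.name]


@given(seed=st.integers(0, 100_000))
def test_channel_drift_matches_scaled_rhs(seed):
    """Summed channel drift equals the count-scaled deterministic rhs."""
    params = base_case(k_ecm=0.3, E_s=5.0, I_n=5.0)
    scaling = ScalingSpec(n_star=3)
    net = compile_reactions(params, scaling)
    c = random_discrete_state(np.random.default_rng(seed))
    a = net.propensities(c)
    assert np.all(a >= 0)
    drift = net.stoich.T @ a
    ns = float(scaling.n_star)
    scales = np.array([ns, ns, scaling.K_m * ns, ns, scaling.K_r * ns, ns])
    dens = c / scales
    expected = scales * rhs(dens, params)
    assert np.allclose(drift, expected, rtol=1e-12, atol=1e-12)


@given(seed=st.integers(0, 100_000))
def test_propensity_zero_when_firing_would_violate_invariants(seed):
    net = compile_reactions(base_case(k_ecm=0.3), ScalingSpec(n_star=3))
    c = random_discrete_state(np.random.default_rng(seed))
    a = net.propensities(c)
    for ch, ai in zip(net.channels, a):
        after = c + np.array(ch.stoich)
        violates = (np.any(after < 0) or after[3] > after[0] or after[5] > after[3])
        if violates:
            assert ai == 0.0


def test_x_formation_propensity_zero_when_saturated(params, scaling):
    net = compile_reactions(params, scaling)
    c = np.array([4, 1, 5, 4, 10, 2], dtype=np.int64)   # N == X
    a = {ch.name: ai for ch, ai in zip(net.channels, net.propensities(c))}
    assert a["x_phosphorylation"] == 0.0


def test_zero_propensity_network_stays_constant(scaling):
    p = base_case(k_ecm=0.0, p0=0.0)
    net = compile_reactions(p, scaling)
    traj = simulate_frm(net, DiscreteState(), t_end=100.0, seed=4)
    assert traj.n_events == 0
    assert np.all(traj.counts == 0)
    assert np.all(traj.v == traj.v[0])


def test_same_seed_reproducible(params_high_ecm, scaling):
    net = compile_reactions(params_high_ecm, scaling)
    t1 = simulate_frm(net, DiscreteState(), 200.0, seed=11)
    t2 = simulate_frm(net, DiscreteState(), 200.0, seed=11)
    assert t1.n_events == t2.n_events
    assert np.array_equal(t1.counts, t2.counts)
    t3 = simulate_frm(net, DiscreteState(), 200.0, seed=12)
    assert not np.array_equal(t1.counts, t3.counts)


def test_same_seed_identical_event_lists_generic_engine(params_high_ecm, scaling):
    net = compile_reactions(params_high_ecm, scaling)
    t1 = simulate_frm(net, DiscreteState(), 40.0, seed=3, return_events=True)
    t2 = simulate_frm(net, DiscreteState(), 40.0, seed=3, return_events=True)
    assert np.array_equal(t1.event_times, t2.event_times)
    assert np.array_equal(t1.event_channels, t2.event_channels)
    assert t1.n_events > 0


def test_subset_invariants_after_every_recorded_sample(params_high_ecm, scaling):
    net = compile_reactions(params_high_ecm.with_overrides(E_s=5.0, I_n=5.0), scaling)
    traj = simulate_frm(net, DiscreteState(), 300.0, seed=21, dt_record=0.05)
    N, X, P = traj.counts[:, 0], traj.counts[:, 3], traj.counts[:, 5]
    assert np.all(traj.counts >= 0)
    assert np.all(X <= N)
    assert np.all(P <= X)
    assert np.all((traj.v >= 0) & (traj.v <= 1))


def _birth_death_network(lam=5.0, mu=1.0):
    """Toy X0 -> X (rate lam), X -> 0 (rate mu*X); stationary Poisson(lam/mu)."""
    channels = [
        ReactionChannel("birth", (1, 0, 0, 0, 0, 0), lambda c: lam, (0,)),
        ReactionChannel("death", (-1, 0, 0, 0, 0, 0), lambda c: mu * c[0], (0,)),
    ]
    return ReactionNetwork(channels)


def test_birth_death_poisson_moments():
    """The generic engine reproduces the analytic birth-death stationary law."""
    net = _birth_death_network(lam=5.0, mu=1.0)
    traj = simulate_frm(net, np.zeros(6, dtype=np.int64), t_end=10_000.0,
                        seed=42, dt_record=1.0)
    assert traj.n_events > 50_000
    x = traj.counts[traj.t >= 20.0, 0]
    # ~1e4 samples at ~1 autocorrelation time: SE(mean) ~ 0.022
    assert abs(x.mean() - 5.0) < 0.15
    assert abs(x.var() - 5.0) < 0.8


def test_frm_nrm_event_counts_match_on_toy():
    """Kolmogorov-Smirnov agreement of event counts across 200 runs."""
    net = _birth_death_network()
    n_frm = [simulate_frm(net, np.zeros(6, np.int64), 10.0, seed=s,
                          dt_record=10.0).n_events for s in range(200)]
    n_nrm = [simulate_nrm(net, np.zeros(6, np.int64), 10.0, seed=10_000 + s,
                          dt_record=10.0).n_events for s in range(200)]
    assert stats.ks_2samp(n_frm, n_nrm).pvalue > 0.01


def test_frm_nrm_agree_on_model(params_high_ecm, scaling):
    """Time-averaged v agrees between methods within two standard errors."""
    net = compile_reactions(params_high_ecm, scaling)
    v_frm = [simulate_frm(net, DiscreteState(), 1000.0, seed=s).v[200:].mean()
             for s in range(20)]
    v_nrm = [simulate_nrm(net, DiscreteState(), 1000.0, seed=500 + s).v[200:].mean()
             for s in range(20)]
    se = np.sqrt(np.var(v_frm, ddof=1) / 20 + np.var(v_nrm, ddof=1) / 20)
    assert abs(np.mean(v_frm) - np.mean(v_nrm)) < 2.0 * se + 1e-12


def test_count_amplification_insensitive(params_high_ecm):
    """K_m = K_r in {5, 10, 20} leaves the time-averaged v unchanged."""
    means = []
    for K in (5.0, 10.0, 20.0):
        sc = ScalingSpec(n_star=3, K_m=K, K_r=K)
        net = compile_reactions(params_high_ecm, sc)
        vs = [simulate_frm(net, DiscreteState(), 1000.0, seed=s).v[200:].mean()
              for s in range(10)]
        means.append((np.mean(vs), np.std(vs, ddof=1) / np.sqrt(10)))
    for (m1, s1), (m2, s2) in [(means[0], means[1]), (means[1], means[2])]:
        assert abs(m1 - m2) < 3.0 * np.hypot(s1, s2)


def test_phenotype_matrix_output(params):
    df = run_phenotype_matrix(params, [0.3], [3], [0.0, 10.0], [0.0, 10.0],
                              t_end=150.0, seeds=(0, 1))
    assert len(df) == 8
    assert set(df.columns) >= {"k_ecm", "N_star", "E_s", "I_n", "seed",
                               "label", "mean_v", "mean_S"}
    from adhesim.phenotype import PHENOTYPES
    assert df.label.isin(PHENOTYPES).all()
    with pytest.raises(ValueError):
        run_phenotype_matrix(params, [], [3], [0.0], [0.0])
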