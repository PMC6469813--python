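import numpy as np
import pytest
from scipy import sparse

from cros.dynamics import (NeuronState, P0_EXC, RESET_EXC, RESET_INH,
                           SimulationTrace, simulate, step)
from cros.topology import NetworkTopology, build_network


def _isolated_net(n=100, exc=True):
    """Neurons with no synapses (pure background drive)."""
    return NetworkTopology(
        L=int(np.sqrt(n)), ell=1, r_E=0.5, r_I=0.5, exc_fraction=1.0, seed=0,
        neuron_type=np.full(n, exc),
        weights=sparse.csr_matrix((n, n)),
    )


def test_current_decays_by_8_ninths_per_step():
    net = _isolated_net(4)
    state = NeuronState(I=np.full(4, 3.0), R_S=np.full(4, -50.0),
                        S=np.zeros(4, bool))
    rng = np.random.default_rng(0)
    for k in range(1, 6):
        state = step(state, net, rng)
        assert np.allclose(state.I, 3.0 * (8.0 / 9.0) ** k)


def test_rate_fixed_point_is_background_probability():
    """With no input, R_S converges to P0 = 1e-6 exactly (excitatory)."""
    net = _isolated_net(10)
    state = NeuronState.zeros(10)
    rng = np.random.default_rng(1)
    for _ in range(600):
        state = step(state, net, rng)
    assert np.allclose(state.R_S, P0_EXC, rtol=1e-9)
    # and the fixed point is exactly invariant
    r = (P0_EXC + 0.0) * (1 - 1 / 9) + P0_EXC / 9
    assert r == pytest.approx(P0_EXC, rel=1e-12)


def test_isolated_population_fires_at_background_rate():
    """~1e-6 spikes per neuron-step over >= 1e7 neuron-steps (Poisson error)."""
    net = _isolated_net(10000)
    tr = simulate(net, n_steps=2000, seed=3)
    total = tr.A[600:].sum()  # discard convergence to the fixed point
    n_draws = 10000 * (2000 - 600)
    expected = n_draws * P0_EXC
    assert abs(total - expected) < 5 * np.sqrt(expected) + 5


def test_absorbing_state_stays_absorbing():
    """Zero weights, zero state, no drive -> A(t) = 0 forever (inhibitory P0=0)."""
    net = _isolated_net(16, exc=False)
    tr = simulate(net, n_steps=500, seed=0)
    assert not tr.A.any()


def test_spike_resets_rate_variable():
    net = _isolated_net(2)
    net.neuron_type[:] = [True, False]
    state = NeuronState(I=np.zeros(2), R_S=np.full(2, 2.0), S=np.zeros(2, bool))
    state = step(state, net, np.random.default_rng(0))
    assert state.S.all()  # R_S >= 1 -> spike probability 1
    assert state.R_S[0] == RESET_EXC and state.R_S[1] == RESET_INH


def test_nonfinite_state_aborts():
    net = _isolated_net(2)
    state = NeuronState(I=np.array([np.inf, 0.0]), R_S=np.zeros(2),
                        S=np.zeros(2, bool))
    with pytest.raises(FloatingPointError):
        step(state, net, np.random.default_rng(0))


def test_simulate_deterministic_and_bounded(small_net, small_trace):
    again = simulate(small_net, n_steps=2 ** 15, seed=11)
    assert np.array_equal(small_trace.A, again.A)
    assert small_trace.A.min() >= 0
    assert small_trace.A.max() <= small_net.n_neurons
    assert small_trace.n_steps == 2 ** 15


def test_zero_steps_gives_empty_trace(small_net):
    tr = simulate(small_net, n_steps=0, seed=0)
    assert tr.n_steps == 0


def test_raster_consistent_with_activity(small_net):
    tr = simulate(small_net, n_steps=2000, seed=5, record_raster=True)
    counts = np.bincount(tr.raster[:, 0], minlength=2000)
    assert np.array_equal(counts, tr.A)


def test_mean_activity_monotone_in_excitation():
    """Mean A(t) is non-decreasing in r_E at fixed r_I (3 points, 2 seeds)."""
    means = []
    for r_E in (0.04, 0.12, 0.24):
        vals = []
        for s in range(2):
            net = build_network(L=20, r_E=r_E, r_I=0.60, seed=30 + s)
            vals.append(simulate(net, 2 ** 15, seed=40 + s).A.mean())
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_trace_hdf5_and_text_roundtrip(tmp_path, small_trace):
    p = tmp_path / "trace.h5"
    small_trace.save(p)
    back = SimulationTrace.load(p)
    assert np.array_equal(back.A, small_trace.A)
    assert back.seed == small_trace.seed
    t = tmp_path / "trace.txt"
    small_trace.save_text(t)
    assert np.array_equal(np.loadtxt(t), small_trace.A)
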