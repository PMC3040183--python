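import numpy as np
import pytest

import mgcnet.engine as eng
from mgcnet.engine import (Simulation, SimulationConfig, integrate,
                           single_neuron_spikes, integrate_single_neuron)
from mgcnet.neurons import HHParams
from mgcnet.network import build_elementary, ConductanceSet
from mgcnet.experiments import REFERENCE_CONDUCTANCES
from mgcnet.protocol import decision_latency
from mgcnet.synapses import single_spike_activation


def test_zero_input_network_stays_silent():
    """No ORN drive and no injected current: every cell silent, S → 0."""
    g = ConductanceSet(0.1, 0.07, 0.3, 0.3, 0.3)
    spec = build_elementary(g)
    for c in list(spec.cells):
        if c.i_inj != 0.0:
            spec.cells[spec.cells.index(c)] = type(c)(c.name, c.role, c.group, 0.0)
    rec = integrate(spec, (0.0, 0.0), SimulationConfig(duration=500.0, eps=1e-6))
    assert all(v.size == 0 for v in rec.values())


def test_identical_seeds_identical_spike_records():
    spec = build_elementary(REFERENCE_CONDUCTANCES)
    out = []
    for _ in range(2):
        sim = Simulation(spec, SimulationConfig(duration=600.0, eps=1e-6, seed=9))
        sim.run_segment(200.0)
        sim.run_segment(450.0, 0.03, 0.03)
        out.append(sim.spikes())
    for name in out[0]:
        assert np.array_equal(out[0][name], out[1][name])


def test_different_seeds_differ():
    spec = build_elementary(REFERENCE_CONDUCTANCES)
    recs = []
    for seed in (1, 2):
        sim = Simulation(spec, SimulationConfig(duration=600.0, eps=1e-6, seed=seed))
        sim.run_segment(200.0)
        sim.run_segment(450.0, 0.03, 0.03)
        recs.append(np.concatenate(list(sim.spikes().values())))
    assert not np.array_equal(recs[0], recs[1])


def test_accuracy_refinement_bounds_spike_time_shift():
    """Halving the accuracy goal moves no spike of a 500 ms deterministic run
    by more than 0.1 ms."""
    p = HHParams(i_inj=0.1)
    s1 = single_neuron_spikes(p, duration=500.0, eps=1e-6)
    s2 = single_neuron_spikes(p, duration=500.0, eps=5e-7)
    assert s1.size == s2.size
    assert np.max(np.abs(s1 - s2)) < 0.1


def test_adaptive_solution_matches_fixed_step_reference():
    """Subthreshold relaxation: adaptive integration at tight tolerance agrees
    with a fixed-step RK4 reference at Δt = 10⁻⁴ ms to within 10⁻³ mV."""
    from mgcnet.network import Cell, NetworkSpec

    spec = NetworkSpec("elementary", [], [Cell("cell", "PN", i_inj=0.0)], [])
    cfg = SimulationConfig(duration=100.0, eps=1e-12, seed=0)
    sim = Simulation(spec, cfg)
    sim.y[0] = -55.0  # subthreshold displacement from rest
    y_ref = sim.y.copy()
    sim.run_segment(100.0)
    eng._rk4_fixed(y_ref, 0.0, 100.0, 1e-4, np.zeros(1), sim.cellp,
                   sim.syn_src, sim.syn_post, sim.syn_alpha, sim.syn_beta,
                   sim.syn_g, sim.syn_erev, sim.syn_tscale, 1, 0)
    assert abs(sim.y[0] - y_ref[0]) < 1e-3


def test_injected_event_drives_synapse_exactly_like_closed_form():
    """A single presynaptic event integrated by the engine reproduces the
    analytic piecewise solution of the kinetics along the whole trace."""
    from mgcnet.network import Cell, ORNSource, Synapse, NetworkSpec
    from mgcnet.synapses import SynapseParams

    params = SynapseParams(alpha=1 / 20, beta=1 / 50, t_release=1.0,
                           g=0.0, e_rev=0.0, compound=False)
    spec = NetworkSpec("elementary", [ORNSource("src", "a", 1)],
                       [Cell("cell", "LN", group="a")],
                       [Synapse("src", "cell", params)])
    cfg = SimulationConfig(duration=50.0, eps=1e-10, seed=0, record_traces=True)
    sim = Simulation(spec, cfg)
    sim.inject_event("src", 0.0, 1)
    sim.run_segment(50.0)
    t, y = sim.trace_arrays()
    s_num = y[:, 4]  # single synapse state after the 4 neuron states
    s_ref = single_spike_activation(t, params.alpha, params.beta, 1.0)
    assert np.max(np.abs(s_num - s_ref)) < 1e-6


def test_activations_and_gating_bounded_under_strong_drive():
    spec = build_elementary(REFERENCE_CONDUCTANCES)
    cfg = SimulationConfig(duration=400.0, eps=1e-6, seed=3)
    sim = Simulation(spec, cfg)
    sim.run_segment(400.0, 0.1, 0.1)  # top-of-grid drive
    nc = sim.nc
    assert sim.y[nc:].min() >= 0.0 and sim.y[nc:].max() <= 1.0


def test_sampled_orn_counts_match_rate():
    spec = build_elementary(REFERENCE_CONDUCTANCES, convergence=1000)
    cfg = SimulationConfig(duration=2000.0, eps=1e-5, seed=4)
    sim = Simulation(spec, cfg)
    lam_s = 0.02
    sim.run_segment(2000.0, lam_s, lam_s)
    expected = lam_s * 1000 * 2000.0
    for k in range(sim.n_orn):
        assert abs(sim.q_sampled[k] - expected) < 4 * np.sqrt(expected)


def test_diagonal_stimulus_elicits_sustained_pn_train():
    """Mid-grid 1:1 input disinhibits the PN: a stable train through the
    presentation after the characteristic disinhibition delay."""
    spec = build_elementary(REFERENCE_CONDUCTANCES, convergence=1000)
    cfg = SimulationConfig(duration=800.0, eps=1e-6, seed=8)
    sim = Simulation(spec, cfg)
    sim.run_segment(250.0)
    lam = 0.01 * 1.3 ** 4
    sim.run_segment(500.0, lam, lam)
    pn = sim.spikes()["PN"]
    lat = decision_latency(pn, (250.0, 500.0))
    assert lat is not None and 50.0 < lat < 220.0


def test_time_must_advance():
    spec = build_elementary(REFERENCE_CONDUCTANCES)
    sim = Simulation(spec, SimulationConfig(duration=100.0, eps=1e-6))
    sim.run_segment(50.0)
    with pytest.raises(ValueError):
        sim.run_segment(30.0)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(min_step=1.0, max_step=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(eps=0.0)
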