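"""Adaptive-step integration of the whole network with Poisson event injection.

All neuron and synapse ODEs are integrated as one coupled vector with an
embedded Dormand–Prince Runge–Kutta pair under per-step error control.  The
step size is confined to [10⁻⁶, 0.5] ms and additionally clipped so that no
step crosses the expiry of an open transmitter-release window, which keeps the
piecewise-constant transmitter drive T exact over every accepted step.

Compound-ORN spike counts are sampled per *accepted* step as q ~ Poisson(λ·Δt)
and enter the summed transmitter drive of their target synapses from the end
of that step; rejected trial steps consume no randomness, so trajectories are
bit-reproducible for a given (network, rates, seed, accuracy) combination.
Spikes of Hodgkin–Huxley cells are detected online as upward threshold
crossings (linearly interpolated, 1 ms refractory guard) and feed their
outgoing synapses the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .neurons import HHParams
from .network import NetworkSpec

__all__ = [
    "SimulationConfig",
    "Simulation",
    "EngineError",
    "integrate",
    "integrate_single_neuron",
    "single_neuron_spikes",
]


class EngineError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Integration contract: step bounds, local accuracy goal, seed."""

    duration: float = 1000.0   # ms
    eps: float = 1e-12         # local accuracy goal
    min_step: float = 1e-6     # ms
    max_step: float = 0.5      # ms
    seed: int = 0
    record_traces: bool = False
    trace_cap: int = 2_000_000
    refractory: float = 1.0    # ms, spike-detection guard
    orn_event_grid: float = 0.1  # ms; compound-ORN event times are snapped up
                                 # to this grid so release windows share edges
    max_steps_per_segment: int = 20_000_000  # abort guard for pathological runs

    def __post_init__(self) -> None:
        if not (0 < self.min_step < self.max_step):
            raise ValueError("require 0 < min_step < max_step")
        if self.eps <= 0:
            raise ValueError("accuracy goal must be positive")


_OK, _UNDERFLOW, _SPIKE_OVERFLOW, _STEP_BUDGET = 0, -2, -3, -5


@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=False)
def _rhs(y, dy, t_drive, cellp, syn_src, syn_post, syn_alpha, syn_beta,
         syn_g, syn_erev, syn_tscale, nc, ns):
    # synaptic currents onto each cell
    for c in range(nc):
        dy[c] = 0.0
    for s in range(ns):
        sval = y[4 * nc + s]
        post = syn_post[s]
        dy[post] += syn_g[s] * sval * (syn_erev[s] - y[post])
    for c in range(nc):
        v = y[c]
        m = y[nc + c]
        h = y[2 * nc + c]
        n = y[3 * nc + c]
        x = v + 54.0
        if x > 1e-7 or x < -1e-7:
            a_m = 0.32 * x / (1.0 - np.exp(-x / 4.0))
        else:
            a_m = 1.28
        x = v + 27.0
        if x > 1e-7 or x < -1e-7:
            b_m = 0.28 * x / (np.exp(x / 5.0) - 1.0)
        else:
            b_m = 1.4
        a_h = 0.128 * np.exp(-(v + 50.0) / 18.0)
        b_h = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
        x = v + 52.0
        if x > 1e-7 or x < -1e-7:
            a_n = 0.032 * x / (1.0 - np.exp(-x / 5.0))
        else:
            a_n = 0.16
        b_n = 0.5 * np.exp(-(v + 57.0) / 40.0)
        i_na = cellp[c, 1] * m * m * m * h * (v - cellp[c, 4])
        i_k = cellp[c, 2] * n * n * n * n * (v - cellp[c, 5])
        i_l = cellp[c, 3] * (v - cellp[c, 6])
        dy[c] = (cellp[c, 7] + dy[c] - i_na - i_k - i_l) / cellp[c, 0]
        dy[nc + c] = a_m * (1.0 - m) - b_m * m
        dy[2 * nc + c] = a_h * (1.0 - h) - b_h * h
        dy[3 * nc + c] = a_n * (1.0 - n) - b_n * n
    for s in range(ns):
        sval = y[4 * nc + s]
        dy[4 * nc + s] = (syn_alpha[s] * syn_tscale[s] * t_drive[syn_src[s]] * (1.0 - sval)
                          - syn_beta[s] * sval)


@njit(cache=True)
def _push_event(ev_t, ev_q, ev_head, ev_len, src, t, q):
    cap = ev_t.shape[1]
    if ev_len[src] == cap:
        # merge the two oldest events to bound memory; conserves total count
        i0 = ev_head[src]
        i1 = (i0 + 1) % cap
        ev_q[src, i1] += ev_q[src, i0]
        ev_head[src] = i1
        ev_len[src] -= 1
    tail = (ev_head[src] + ev_len[src]) % cap
    ev_t[src, tail] = t
    ev_q[src, tail] = q
    ev_len[src] += 1


@njit(cache=True)
def _run_segment(y, t0, t1, h0,
                 ev_t, ev_q, ev_head, ev_len, tr_src, rates, q_sampled,
                 cellp, syn_src, syn_post, syn_alpha, syn_beta, syn_g, syn_erev, syn_tscale,
                 spk_t, spk_n, last_spike,
                 eps, min_step, max_step, refractory, n_orn, ev_grid, max_steps,
                 trace, trace_n, record_trace):
    nc = cellp.shape[0]
    ns = syn_src.shape[0]
    nsrc = ev_t.shape[0]
    cap = ev_t.shape[1]
    ndim = y.shape[0]

    t_drive = np.zeros(nsrc)
    k = np.zeros((7, ndim))
    ytmp = np.empty(ndim)
    y5 = np.empty(ndim)
    t = t0
    h_prop = h0
    n_steps = 0

    b5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
    b4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
                   -92097 / 339200, 187 / 2100, 1 / 40])
    a = np.zeros((7, 7))
    a[1, 0] = 1 / 5
    a[2, 0] = 3 / 40
    a[2, 1] = 9 / 40
    a[3, 0] = 44 / 45
    a[3, 1] = -56 / 15
    a[3, 2] = 32 / 9
    a[4, 0] = 19372 / 6561
    a[4, 1] = -25360 / 2187
    a[4, 2] = 64448 / 6561
    a[4, 3] = -212 / 729
    a[5, 0] = 9017 / 3168
    a[5, 1] = -355 / 33
    a[5, 2] = 46732 / 5247
    a[5, 3] = 49 / 176
    a[5, 4] = -5103 / 18656
    a[6, 0] = 35 / 384
    a[6, 1] = 0.0
    a[6, 2] = 500 / 1113
    a[6, 3] = 125 / 192
    a[6, 4] = -2187 / 6784
    a[6, 5] = 11 / 84

    while t < t1 - 1e-12:
        n_steps += 1
        if n_steps > max_steps:
            return _STEP_BUDGET, t, h_prop, n_steps
        # prune expired release windows; compute drive and the next time the
        # drive changes (an active window closing or a pending one opening)
        next_change = 1e300
        for s in range(nsrc):
            while ev_len[s] > 0:
                i = ev_head[s]
                if ev_t[s, i] + tr_src[s] <= t + 1e-12:
                    ev_head[s] = (i + 1) % cap
                    ev_len[s] -= 1
                else:
                    break
            tot = 0.0
            for j in range(ev_len[s]):
                i = (ev_head[s] + j) % cap
                if ev_t[s, i] <= t + 1e-12:
                    tot += ev_q[s, i]
                    e = ev_t[s, i] + tr_src[s]
                else:
                    e = ev_t[s, i]
                if e < next_change:
                    next_change = e
            t_drive[s] = tot

        h = h_prop
        if h > max_step:
            h = max_step
        if t + h > t1:
            h = t1 - t
        if next_change > t + 1e-12 and t + h > next_change:
            # align to the drive change, but never below a floor that would
            # stall the integration (bounded release-timing overshoot)
            hc = next_change - t
            floor = 0.02
            if t + h > t1 - 1e-12:
                pass
            if hc < floor:
                hc = floor
                if t + hc > t1:
                    hc = t1 - t
            if h > hc:
                h = hc

        # attempt the step, shrinking h until the local error passes
        while True:
            for stage in range(7):
                for i in range(ndim):
                    acc = y[i]
                    for j in range(stage):
                        acc += h * a[stage, j] * k[j, i]
                    ytmp[i] = acc
                _rhs(ytmp, k[stage], t_drive, cellp, syn_src, syn_post,
                     syn_alpha, syn_beta, syn_g, syn_erev, syn_tscale, nc, ns)
            err = 0.0
            ok = True
            for i in range(ndim):
                y5i = y[i]
                ei = 0.0
                for stage in range(7):
                    y5i += h * b5[stage] * k[stage, i]
                    ei += h * (b5[stage] - b4[stage]) * k[stage, i]
                y5[i] = y5i
                if not np.isfinite(y5i):
                    ok = False
                sc = eps * (100.0 + abs(y[i])) if i < nc else eps * (1.0 + abs(y[i]))
                err += (ei / sc) ** 2
            err = np.sqrt(err / ndim)
            if ok and err <= 1.0:
                break
            if not ok or not np.isfinite(err):
                h *= 0.2
            else:
                fac = 0.9 * err ** -0.2
                if fac < 0.2:
                    fac = 0.2
                h *= fac
            if h < min_step:
                return _UNDERFLOW, t, h_prop, n_steps

        t_new = t + h

        # online spike detection and event injection from HH cells
        for c in range(nc):
            v0 = y[c]
            v1 = y5[c]
            thr = cellp[c, 8]
            if v0 < thr and v1 >= thr:
                ts = t + h * (thr - v0) / (v1 - v0)
                if ts - last_spike[c] >= refractory:
                    last_spike[c] = ts
                    if spk_n[c] >= spk_t.shape[1]:
                        return _SPIKE_OVERFLOW, t, h_prop, n_steps
                    spk_t[c, spk_n[c]] = ts
                    spk_n[c] += 1
                    _push_event(ev_t, ev_q, ev_head, ev_len, n_orn + c, ts, 1.0)

        # accept
        for i in range(ndim):
            y[i] = y5[i]
        for i in range(nc, ndim):  # clamp gating variables and activations
            if y[i] < 0.0:
                y[i] = 0.0
            elif y[i] > 1.0:
                y[i] = 1.0
        t = t_new

        # per-accepted-step Poisson sampling for compound ORN sources; event
        # times snap up to the ev_grid lattice so window edges coincide
        for s in range(n_orn):
            if rates[s] > 0.0:
                q = np.random.poisson(rates[s] * h)
                if q > 0:
                    q_sampled[s] += q
                    ts = np.ceil(t_new / ev_grid - 1e-9) * ev_grid
                    if ev_len[s] > 0:
                        tail = (ev_head[s] + ev_len[s] - 1) % cap
                        if abs(ev_t[s, tail] - ts) < 1e-12:
                            ev_q[s, tail] += float(q)
                            continue
                    _push_event(ev_t, ev_q, ev_head, ev_len, s, ts, float(q))

        if record_trace and trace_n[0] < trace.shape[0]:
            row = trace_n[0]
            trace[row, 0] = t
            for i in range(ndim):
                trace[row, 1 + i] = y[i]
            trace_n[0] += 1

        if err == 0.0:
            fac = 5.0
        else:
            fac = 0.9 * err ** -0.2
            if fac > 5.0:
                fac = 5.0
            elif fac < 0.2:
                fac = 0.2
        h_prop = h * fac

    return _OK, t, h_prop, n_steps


@njit(cache=True)
def _rk4_fixed(y, t0, t1, dt, t_drive, cellp, syn_src, syn_post, syn_alpha,
               syn_beta, syn_g, syn_erev, syn_tscale, nc, ns):
    """Fixed-step classical RK4 reference integrator (no events, no spikes)."""
    ndim = y.shape[0]
    k1 = np.empty(ndim)
    k2 = np.empty(ndim)
    k3 = np.empty(ndim)
    k4 = np.empty(ndim)
    ytmp = np.empty(ndim)
    nsteps = int(np.round((t1 - t0) / dt))
    for _ in range(nsteps):
        _rhs(y, k1, t_drive, cellp, syn_src, syn_post, syn_alpha, syn_beta, syn_g, syn_erev, syn_tscale, nc, ns)
        for i in range(ndim):
            ytmp[i] = y[i] + 0.5 * dt * k1[i]
        _rhs(ytmp, k2, t_drive, cellp, syn_src, syn_post, syn_alpha, syn_beta, syn_g, syn_erev, syn_tscale, nc, ns)
        for i in range(ndim):
            ytmp[i] = y[i] + 0.5 * dt * k2[i]
        _rhs(ytmp, k3, t_drive, cellp, syn_src, syn_post, syn_alpha, syn_beta, syn_g, syn_erev, syn_tscale, nc, ns)
        for i in range(ndim):
            ytmp[i] = y[i] + dt * k3[i]
        _rhs(ytmp, k4, t_drive, cellp, syn_src, syn_post, syn_alpha, syn_beta, syn_g, syn_erev, syn_tscale, nc, ns)
        for i in range(ndim):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
    return y


# --------------------------------------------------------------------------


def _gating_steady(v: float) -> tuple[float, float, float]:
    from .neurons import hh_rates

    a_m, b_m, a_h, b_h, a_n, b_n = hh_rates(v)
    return a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n)


class Simulation:
    """Stateful simulation of one :class:`~mgcnet.network.NetworkSpec`.

    The network is compiled to flat arrays once; :meth:`run_segment` advances
    the coupled system to an absolute time under constant ORN rates, so a
    stimulus protocol is a sequence of segment calls on one continuous clock.
    """

    EVENT_QUEUE = 512

    def __init__(self, spec: NetworkSpec, config: SimulationConfig,
                 hh_params: HHParams | None = None):
        spec.validate()
        self.spec = spec
        self.config = config
        base = hh_params or HHParams()

        self.orn_names = [s.name for s in spec.orn_sources]
        self.cell_names = [c.name for c in spec.cells]
        self.n_orn = len(self.orn_names)
        nc = len(self.cell_names)
        self.nc = nc
        src_index = {n: i for i, n in enumerate(self.orn_names)}
        src_index.update({n: self.n_orn + i for i, n in enumerate(self.cell_names)})
        cell_index = {n: i for i, n in enumerate(self.cell_names)}

        self.cellp = np.empty((nc, 9))
        for i, c in enumerate(spec.cells):
            self.cellp[i] = (base.c_m, base.g_na, base.g_k, base.g_leak,
                             base.e_na, base.e_k, base.e_leak, c.i_inj,
                             base.spike_threshold)

        ns = len(spec.synapses)
        self.ns = ns
        self.syn_src = np.array([src_index[s.pre] for s in spec.synapses], dtype=np.int64)
        self.syn_post = np.array([cell_index[s.post] for s in spec.synapses], dtype=np.int64)
        self.syn_alpha = np.array([s.params.effective_alpha for s in spec.synapses])
        self.syn_beta = np.array([s.params.beta for s in spec.synapses])
        self.syn_g = np.array([s.params.g for s in spec.synapses])
        self.syn_erev = np.array([s.params.e_rev for s in spec.synapses])
        # compound-ORN synapses track the population-mean activation:
        # transmitter drive per spike is 1/N_ORN of a unit synapse's
        n_by_name = {s.name: s.n_orn for s in spec.orn_sources}
        self.syn_tscale = np.array([
            1.0 / n_by_name[s.pre]
            if (s.pre in n_by_name and s.params.compound) else 1.0
            for s in spec.synapses
        ])

        nsrc = self.n_orn + nc
        tr = np.full(nsrc, np.nan)
        for s in spec.synapses:
            i = src_index[s.pre]
            if np.isnan(tr[i]):
                tr[i] = s.params.t_release
            elif abs(tr[i] - s.params.t_release) > 1e-12:
                raise ValueError(f"source {s.pre} has synapses with differing t_release")
        tr[np.isnan(tr)] = 1.0
        self.tr_src = tr

        # state
        v0 = -67.0
        m0, h0, n0 = _gating_steady(v0)
        self.y = np.concatenate([
            np.full(nc, v0), np.full(nc, m0), np.full(nc, h0), np.full(nc, n0),
            np.zeros(ns),
        ])
        self.t = 0.0
        self._h = 0.01
        self.ev_t = np.zeros((nsrc, self.EVENT_QUEUE))
        self.ev_q = np.zeros((nsrc, self.EVENT_QUEUE))
        self.ev_head = np.zeros(nsrc, dtype=np.int64)
        self.ev_len = np.zeros(nsrc, dtype=np.int64)
        self.q_sampled = np.zeros(nsrc)
        max_spk = int(config.duration / 1000.0 * 400) + 256
        self.spk_t = np.zeros((nc, max_spk))
        self.spk_n = np.zeros(nc, dtype=np.int64)
        self.last_spike = np.full(nc, -1e9)
        if config.record_traces:
            self.trace = np.zeros((config.trace_cap, 1 + self.y.size))
        else:
            self.trace = np.zeros((1, 1 + self.y.size))
        self.trace_n = np.zeros(1, dtype=np.int64)
        self.steps_total = 0
        _seed_rng(config.seed % (2 ** 31))

    # -- event injection (used by tests and by the synapse-oracle check) ----
    def inject_event(self, source: str, t: float, q: int = 1) -> None:
        names = self.orn_names + self.cell_names
        src = names.index(source)
        _push_event(self.ev_t, self.ev_q, self.ev_head, self.ev_len, src, t, float(q))

    def run_segment(self, t_end: float, lam_a: float = 0.0, lam_b: float = 0.0) -> None:
        """Advance the network to absolute time ``t_end`` (ms) under constant
        component rates λ_a, λ_b (ms⁻¹, per single ORN; scaled by each
        source's convergence)."""
        if t_end <= self.t:
            raise ValueError("t_end must exceed the current time")
        rates = np.zeros(self.n_orn + self.nc)
        for i, s in enumerate(self.spec.orn_sources):
            lam = lam_a if s.component == "a" else lam_b
            rates[i] = lam * s.n_orn
        cfg = self.config
        status, t, h, n_steps = _run_segment(
            self.y, self.t, t_end, self._h,
            self.ev_t, self.ev_q, self.ev_head, self.ev_len, self.tr_src,
            rates, self.q_sampled,
            self.cellp, self.syn_src, self.syn_post, self.syn_alpha,
            self.syn_beta, self.syn_g, self.syn_erev, self.syn_tscale,
            self.spk_t, self.spk_n, self.last_spike,
            cfg.eps, cfg.min_step, cfg.max_step, cfg.refractory, self.n_orn,
            cfg.orn_event_grid, cfg.max_steps_per_segment,
            self.trace, self.trace_n, cfg.record_traces,
        )
        if status == _UNDERFLOW:
            raise EngineError(f"step size underflow below {cfg.min_step} ms at t={t:.6f}")
        if status == _SPIKE_OVERFLOW:
            raise EngineError(f"spike buffer overflow at t={t:.6f}")
        if status == _STEP_BUDGET:
            raise EngineError(f"step budget exceeded at t={t:.6f}")
        if status != _OK:
            raise EngineError(f"integration aborted (status {status}) at t={t:.6f}")
        self.t = t
        self._h = h
        self.steps_total += int(n_steps)

    # -- results ------------------------------------------------------------
    def spikes(self) -> dict[str, np.ndarray]:
        return {name: self.spk_t[i, :self.spk_n[i]].copy()
                for i, name in enumerate(self.cell_names)}

    def trace_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        n = int(self.trace_n[0])
        return self.trace[:n, 0].copy(), self.trace[:n, 1:].copy()

    def activation(self, synapse_idx: int) -> float:
        return float(self.y[4 * self.nc + synapse_idx])


def integrate(spec: NetworkSpec, rates: tuple[float, float],
              config: SimulationConfig) -> dict[str, np.ndarray]:
    """Run one constant-rate segment of ``config.duration`` ms; returns the
    per-cell spike trains."""
    sim = Simulation(spec, config)
    sim.run_segment(config.duration, rates[0], rates[1])
    return sim.spikes()


def _single_neuron_sim(params: HHParams, duration: float, eps: float,
                       record: bool) -> Simulation:
    from .network import Cell

    spec = NetworkSpec("elementary", [], [Cell("cell", "PN", i_inj=params.i_inj)], [])
    cfg = SimulationConfig(duration=duration, eps=eps, seed=0,
                           record_traces=record, trace_cap=4_000_000)
    sim = Simulation(spec, cfg, hh_params=params)
    sim.run_segment(duration)
    return sim


def integrate_single_neuron(params: HHParams, duration: float,
                            eps: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Voltage/gating trajectory of an isolated neuron (t, y[nt, 4])."""
    sim = _single_neuron_sim(params, duration, eps, record=True)
    t, y = sim.trace_arrays()
    return t, y


def single_neuron_spikes(params: HHParams, duration: float,
                         eps: float = 1e-6) -> np.ndarray:
    """Spike times of an isolated neuron under its constant injected current."""
    sim = _single_neuron_sim(params, duration, eps, record=False)
    return sim.spikes()["cell"]
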