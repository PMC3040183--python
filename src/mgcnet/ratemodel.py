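"""Rate-based reduction of the conductance network.

Each Hodgkin–Huxley cell is replaced by a firing-rate unit whose rate relaxes,
with the resting membrane time constant, toward the tabulated f-I value of its
total (synaptic + injected) current; each synapse carries the mean activation
of the first-order kinetics driven by the presynaptic rate:

    τ dν/dt = F(I_inj + Σ g S̄ (E_rev − V_eff)) − ν
    dS̄/dt  = α ν_pre t_release (1 − S̄) − β S̄

F is measured once from the spiking neuron (steady rate vs constant current)
and interpolated; V_eff is a fixed effective membrane potential for the
driving force.  Compound ORN sources enter through their mean drive
λ_s·t_release with the same α rescaling as in the spiking model.  The model is
deterministic — no Poisson noise, hence no first-spike lock-in — so the
competition it expresses is purely in sustained rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .neurons import HHParams, f_i_curve
from .network import NetworkSpec
from .protocol import StimulusGrid, build_grid, ResponseMatrix

__all__ = ["RateModel", "rate_dynamics", "run_rate_protocol",
           "steady_state_activation", "DEFAULT_V_EFF", "DEFAULT_TAU_MS"]

#: effective membrane potential (mV) used for synaptic driving forces
DEFAULT_V_EFF = -60.0
#: rate relaxation time constant: the membrane time constant at rest, C/g_leak
DEFAULT_TAU_MS = 10.0


def steady_state_activation(alpha: float, beta: float, nu: float,
                            t_release: float) -> float:
    """Mean activation at presynaptic rate ν (ms⁻¹): S̄∞ = αν t_r / (αν t_r + β)."""
    drive = alpha * nu * t_release
    return drive / (drive + beta)


class RateModel:
    """Deterministic rate version of one :class:`~mgcnet.network.NetworkSpec`.

    The f-I table is measured from the spiking neuron on construction (a grid
    of constant currents, one short simulation each) and shared across cells.
    """

    def __init__(self, spec: NetworkSpec, hh_params: HHParams | None = None,
                 tau: float = DEFAULT_TAU_MS, v_eff: float = DEFAULT_V_EFF,
                 fi_currents: np.ndarray | None = None, fi_eps: float = 1e-5):
        spec.validate()
        self.spec = spec
        self.tau = tau
        self.v_eff = v_eff
        base = hh_params or HHParams()
        if fi_currents is None:
            fi_currents = np.concatenate([
                np.linspace(0.0, 0.5, 11), np.linspace(0.75, 3.0, 10),
            ])
        table = f_i_curve(base, fi_currents, duration=1500.0, transient=500.0,
                          eps=fi_eps)
        self._fi_i = table[:, 0]
        self._fi_r = table[:, 1] / 1000.0  # ms⁻¹

        self.cell_names = [c.name for c in spec.cells]
        self.nc = len(self.cell_names)
        cell_index = {n: i for i, n in enumerate(self.cell_names)}
        self.i_inj = np.array([c.i_inj for c in spec.cells])

        orn_index = {s.name: i for i, s in enumerate(spec.orn_sources)}
        self.orn_components = [s.name for s in spec.orn_sources]
        ns = len(spec.synapses)
        self.ns = ns
        self.syn_post = np.array([cell_index[s.post] for s in spec.synapses])
        self.syn_alpha = np.array([s.params.effective_alpha for s in spec.synapses])
        self.syn_beta = np.array([s.params.beta for s in spec.synapses])
        self.syn_trel = np.array([s.params.t_release for s in spec.synapses])
        self.syn_g = np.array([s.params.g for s in spec.synapses])
        self.syn_erev = np.array([s.params.e_rev for s in spec.synapses])
        # presynaptic rate source: cell index, or -1-orn_index for ORN sources
        self.syn_pre = np.array([
            cell_index[s.pre] if s.pre in cell_index else -1 - orn_index[s.pre]
            for s in spec.synapses
        ])
        self._orn_rates = np.zeros(len(spec.orn_sources))  # λ_s per source

    def f_of_i(self, current: float | np.ndarray) -> float | np.ndarray:
        """Interpolated steady firing rate (ms⁻¹) at a constant current (nA)."""
        return np.interp(current, self._fi_i, self._fi_r)

    def set_component_rates(self, lam_a: float, lam_b: float) -> None:
        """Single-ORN rates λ_s (ms⁻¹) per pheromone component."""
        for k, src in enumerate(self.spec.orn_sources):
            self._orn_rates[k] = lam_a if src.component == "a" else lam_b

    # -- dynamics ------------------------------------------------------------
    def derivative(self, y: np.ndarray) -> np.ndarray:
        """Right-hand side over the state [ν (per cell), S̄ (per synapse)]."""
        nu = y[:self.nc]
        s = y[self.nc:]
        i_tot = self.i_inj + np.zeros(self.nc)
        np.add.at(i_tot, self.syn_post, self.syn_g * s * (self.syn_erev - self.v_eff))
        dnu = (self.f_of_i(i_tot) - nu) / self.tau
        pre_rate = np.where(
            self.syn_pre >= 0,
            nu[np.clip(self.syn_pre, 0, None)],
            self._orn_rates[np.clip(-1 - self.syn_pre, 0, None)],
        )
        drive = self.syn_alpha * pre_rate * self.syn_trel
        ds = drive * (1.0 - s) - self.syn_beta * s
        return np.concatenate([dnu, ds])

    def initial_state(self) -> np.ndarray:
        return np.zeros(self.nc + self.ns)

    def run_segment(self, y0: np.ndarray, duration: float,
                    n_samples: int = 26) -> tuple[np.ndarray, np.ndarray]:
        """Integrate for ``duration`` ms; returns (sample times, states)."""
        t_eval = np.linspace(0.0, duration, n_samples)
        sol = solve_ivp(lambda t, y: self.derivative(y), (0.0, duration), y0,
                        t_eval=t_eval, method="LSODA", rtol=1e-8, atol=1e-10)
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"rate-model integration failed: {sol.message}")
        return sol.t, sol.y.T


def rate_dynamics(model: RateModel, state: np.ndarray,
                  orn_rates: tuple[float, float]) -> np.ndarray:
    """Derivative of the rate-model state at single-ORN rates (λ_a, λ_b)."""
    model.set_component_rates(*orn_rates)
    return model.derivative(np.asarray(state, dtype=float))


def run_rate_protocol(spec_or_model: NetworkSpec | RateModel,
                      grid: StimulusGrid | None = None,
                      readout_group: str = "c") -> ResponseMatrix:
    """Deterministic response matrix of the rate model.

    The readout is the mean firing rate (ms⁻¹) of the generalist LN group
    averaged over each presentation window, in place of the spike density
    function of the spiking pipeline.
    """
    grid = grid or build_grid()
    model = (spec_or_model if isinstance(spec_or_model, RateModel)
             else RateModel(spec_or_model))
    read_cells = [i for i, c in enumerate(model.spec.cells)
                  if c.role == "LN" and c.group == readout_group]
    if not read_cells:
        raise ValueError(f"no LN group {readout_group!r} in the network")
    idx_of = {v: k for k, v in enumerate(grid.active_indices)}
    n = grid.n
    vals = np.zeros((n, n))
    y = model.initial_state()
    model.set_component_rates(0.0, 0.0)
    _, ys = model.run_segment(y, grid.settle_ms or grid.off_ms)
    y = ys[-1]
    for (i, j, la, lb) in grid.pairs():
        model.set_component_rates(la, lb)
        _, ys = model.run_segment(y, grid.on_ms)
        vals[idx_of[i], idx_of[j]] = max(0.0, float(np.mean(ys[:, read_cells])))
        y = ys[-1]
        model.set_component_rates(0.0, 0.0)
        _, ys = model.run_segment(y, grid.off_ms)
        y = ys[-1]
    return ResponseMatrix(vals, grid, meta={"model": "rate"})
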