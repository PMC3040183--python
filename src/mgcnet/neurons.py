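"""Hodgkin–Huxley point-neuron model for antennal-lobe local and projection neurons.

The local neurons (LNs), the intermediary inhibitory neuron (LNi) and the
projection neuron (PN) are all modelled as type-1-excitable Traub–Miles
Hodgkin–Huxley neurons, the standard single-compartment formulation used in
earlier insect antennal-lobe network models.  Type-1 excitability means the
firing rate rises continuously from zero at rheobase, so the cells support the
graded changes of spike frequency the competition mechanism relies on.

Unit convention (used throughout the package): mV, ms, nA, µS, nF.  The
membrane area is folded into the capacitance and maximal conductances, so
synaptic strengths expressed in µS apply directly.  The default constants
correspond to the canonical Traub–Miles densities (C = 1 µF/cm²,
g_Na = 100 mS/cm², g_K = 80 mS/cm², g_L = 0.1 mS/cm², E_Na = 50 mV,
E_K = −100 mV, E_L = −67 mV) on a membrane area of 10⁻⁴ cm².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HHParams",
    "HHState",
    "hh_rates",
    "hh_derivatives",
    "resting_state",
    "detect_spikes",
    "f_i_curve",
]

#: membrane area folded into absolute units, cm²
MEMBRANE_AREA_CM2 = 1e-4


@dataclass(frozen=True)
class HHParams:
    """Constants of the Traub–Miles neuron in absolute units (nF, µS, mV, nA)."""

    c_m: float = 0.1            # nF
    g_na: float = 10.0          # µS
    g_k: float = 8.0            # µS
    g_leak: float = 0.01        # µS
    e_na: float = 50.0          # mV
    e_k: float = -100.0         # mV
    e_leak: float = -67.0       # mV
    i_inj: float = 0.0          # nA, constant injected current
    spike_threshold: float = 0.0  # mV, upward crossing
    refractory: float = 1.0     # ms, guard between detected spikes

    def __post_init__(self) -> None:
        if min(self.g_na, self.g_k, self.g_leak) < 0:
            raise ValueError("conductances must be non-negative")
        if not (self.e_na > self.e_leak > self.e_k):
            raise ValueError("require E_Na > E_leak > E_K")
        if not np.isfinite(self.i_inj):
            raise ValueError("injected current must be finite")

    def with_current(self, i_inj: float) -> "HHParams":
        return replace(self, i_inj=i_inj)


@dataclass
class HHState:
    """Dynamical state: membrane potential and the three gating variables."""

    v: float = -67.0
    m: float = 0.0
    h: float = 1.0
    n: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.m, self.h, self.n], dtype=float)

    def validate(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite neuron state: {arr}")
        for name in ("m", "h", "n"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"gating variable {name}={x} outside [0, 1]")


def hh_rates(v: float) -> tuple[float, float, float, float, float, float]:
    """Voltage-dependent opening/closing rates (ms⁻¹) of the Traub–Miles model.

    Returns (α_m, β_m, α_h, β_h, α_n, β_n).  The removable singularities at
    v = −54, −27 and −52 mV are filled with the analytic limits.
    """
    x = v + 54.0
    a_m = 0.32 * 4.0 if abs(x) < 1e-9 else 0.32 * x / (1.0 - np.exp(-x / 4.0))
    x = v + 27.0
    b_m = 0.28 * 5.0 if abs(x) < 1e-9 else 0.28 * x / (np.exp(x / 5.0) - 1.0)
    a_h = 0.128 * np.exp(-(v + 50.0) / 18.0)
    b_h = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    x = v + 52.0
    a_n = 0.032 * 5.0 if abs(x) < 1e-9 else 0.032 * x / (1.0 - np.exp(-x / 5.0))
    b_n = 0.5 * np.exp(-(v + 57.0) / 40.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def hh_derivatives(state: HHState, params: HHParams, synaptic_current: float = 0.0) -> np.ndarray:
    """Right-hand side of the neuron ODEs with total current I_inj + I_syn.

    Parameters
    ----------
    state
        Current neuron state (validated; non-finite values raise).
    params
        Membrane constants.
    synaptic_current
        Total synaptic current in nA (positive depolarizes).

    Returns
    -------
    ndarray
        (dV/dt [mV/ms], dm/dt, dh/dt, dn/dt).
    """
    state.validate()
    v, m, h, n = state.v, state.m, state.h, state.n
    a_m, b_m, a_h, b_h, a_n, b_n = hh_rates(v)
    i_na = params.g_na * m ** 3 * h * (v - params.e_na)
    i_k = params.g_k * n ** 4 * (v - params.e_k)
    i_l = params.g_leak * (v - params.e_leak)
    dv = (params.i_inj + synaptic_current - i_na - i_k - i_l) / params.c_m
    return np.array([
        dv,
        a_m * (1.0 - m) - b_m * m,
        a_h * (1.0 - h) - b_h * h,
        a_n * (1.0 - n) - b_n * n,
    ])


def resting_state(params: HHParams, settle_ms: float = 500.0) -> HHState:
    """Relax the neuron (I_inj as given, no synaptic input) to its fixed point.

    For subthreshold I_inj this returns the resting point; with suprathreshold
    current there is no fixed point and the state is simply wherever the
    trajectory ends, which is still a sensible initial condition.
    """
    from .engine import integrate_single_neuron  # local import: engine depends on this module

    t, y = integrate_single_neuron(params, duration=settle_ms, eps=1e-9)
    return HHState(v=y[-1, 0], m=y[-1, 1], h=y[-1, 2], n=y[-1, 3])


def detect_spikes(times: np.ndarray, voltages: np.ndarray,
                  threshold: float = 0.0, refractory: float = 1.0) -> np.ndarray:
    """Spike times from a sampled voltage trace.

    One spike per upward threshold crossing (linearly interpolated between
    samples); crossings closer than ``refractory`` ms to the previous accepted
    spike are ignored as re-crossings of the same action potential.
    """
    times = np.asarray(times, dtype=float)
    voltages = np.asarray(voltages, dtype=float)
    if times.size == 0:
        return np.empty(0)
    if times.size != voltages.size:
        raise ValueError("times and voltages must have the same length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("trace times must be strictly increasing")
    below = voltages[:-1] < threshold
    above = voltages[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    spikes: list[float] = []
    last = -np.inf
    for i in idx:
        frac = (threshold - voltages[i]) / (voltages[i + 1] - voltages[i])
        t_sp = times[i] + frac * (times[i + 1] - times[i])
        if t_sp - last >= refractory:
            spikes.append(t_sp)
            last = t_sp
    return np.array(spikes)


def f_i_curve(params: HHParams, current_grid: np.ndarray,
              duration: float = 2000.0, transient: float = 500.0,
              eps: float = 1e-6) -> np.ndarray:
    """Steady firing rate (Hz) as a function of constant injected current (nA).

    Each grid point is simulated for ``duration`` ms and spikes are counted
    after discarding the first ``transient`` ms.  The grid must be sorted
    ascending.  Returns an array of shape (len(grid), 2): (current, rate).
    """
    from .engine import single_neuron_spikes

    grid = np.asarray(current_grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("current grid must be sorted ascending")
    out = np.empty((grid.size, 2))
    for k, i_inj in enumerate(grid):
        p = params.with_current(float(i_inj))
        try:
            sp = single_neuron_spikes(p, duration=duration, eps=eps)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"integration failed at I = {i_inj} nA") from exc
        rate = np.sum(sp > transient) / ((duration - transient) / 1000.0)
        out[k] = (i_inj, rate)
    return out
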