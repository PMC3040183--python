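"""First-order kinetic synapse with finite-duration transmitter release.

The synaptic activation S follows the first-order kinetics

    dS/dt = α · T(t) · (1 − S) − β · S,

where α and β are the transmitter release and decay rates and T(t) is the
transmitter drive: a step function equal to the number of presynaptic spikes
whose release window is open at time t.  Each presynaptic event of q spikes at
time t_i contributes q to T during [t_i, t_i + t_release]; overlapping windows
sum.  The postsynaptic current is I = g · S · (E_rev − E_post).

A whole olfactory receptor neuron (ORN) population is emulated by a single
"compound" Poisson source whose per-step spike counts q feed T directly.  To
keep the maximal single-spike activation of the compound synapse equal to that
of a per-ORN description — in which a durationless spike drives release only
for the integration step in which it occurs — the release rate of the compound
synapse is rescaled by the factor computed in :func:`compound_alpha_scale`
(0.556 at α = (20 ms)⁻¹, β = (50 ms)⁻¹ with the package defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SynapseParams",
    "SynapseState",
    "transmitter_drive",
    "synapse_derivative",
    "synaptic_current",
    "single_spike_peak",
    "single_spike_activation",
    "compound_alpha_scale",
    "DEFAULT_T_RELEASE",
    "POPULATION_RELEASE_STEP",
]

#: release duration of a durationless presynaptic impulse in the per-ORN
#: population description: one integration step at the engine's step cap (ms)
POPULATION_RELEASE_STEP = 0.5

#: default transmitter release duration t_release (ms); calibrated so that the
#: compound rescaling factor at α=(20 ms)⁻¹, β=(50 ms)⁻¹ equals 0.556
DEFAULT_T_RELEASE = 0.9029332342592705


@dataclass(frozen=True)
class SynapseParams:
    """Kinetic and conductance constants of one synapse."""

    alpha: float = 1.0 / 20.0   # ms⁻¹, transmitter release rate
    beta: float = 1.0 / 50.0    # ms⁻¹, transmitter decay rate
    t_release: float = DEFAULT_T_RELEASE  # ms
    g: float = 0.1              # µS, maximal conductance
    e_rev: float = 0.0          # mV, reversal potential
    compound: bool = False      # apply the compound-ORN α rescaling

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.t_release) <= 0 or self.g < 0:
            raise ValueError("require alpha, beta, t_release > 0 and g >= 0")

    @property
    def effective_alpha(self) -> float:
        """Release rate actually used: α̃ = k·α for compound-ORN synapses."""
        if not self.compound:
            return self.alpha
        return self.alpha * compound_alpha_scale(self.alpha, self.beta, self.t_release)


@dataclass
class SynapseState:
    """Activation plus the queue of release events still inside t_release."""

    s: float = 0.0
    events: list[tuple[float, int]] = field(default_factory=list)  # (t_i, q)

    def push(self, t: float, q: int) -> None:
        if q > 0:
            self.events.append((t, int(q)))

    def prune(self, t: float, t_release: float) -> None:
        self.events = [(ti, q) for ti, q in self.events if ti + t_release > t]


def transmitter_drive(state: SynapseState, t: float, t_release: float) -> int:
    """Total transmitter drive T(t): sum of spike counts with open windows."""
    return sum(q for ti, q in state.events if ti <= t < ti + t_release)


def synapse_derivative(s: float, t_drive: float, params: SynapseParams) -> float:
    """dS/dt of the saturating first-order kinetics at drive T."""
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"activation S={s} outside [0, 1]")
    return params.effective_alpha * t_drive * (1.0 - s) - params.beta * s


def synaptic_current(s: float, g: float, e_post: float, e_rev: float) -> float:
    """Postsynaptic current in nA; positive values depolarize."""
    if g < 0:
        raise ValueError("conductance must be non-negative")
    return g * s * (e_rev - e_post)


def single_spike_peak(alpha: float, beta: float, release_duration: float) -> float:
    """Closed-form peak activation after one spike (S(0) = 0).

    During the release window dS/dt = α(1 − S) − βS, so
    S(t) = α/(α+β) · (1 − e^{−(α+β)t}); the peak is reached at the end of the
    window, after which S decays as e^{−βt}.
    """
    ab = alpha + beta
    return alpha / ab * (1.0 - np.exp(-ab * release_duration))


def single_spike_activation(t: np.ndarray, alpha: float, beta: float,
                            release_duration: float) -> np.ndarray:
    """Closed-form S(t) for a single spike at t = 0 (piecewise solution)."""
    t = np.asarray(t, dtype=float)
    ab = alpha + beta
    s_inf = alpha / ab
    rising = s_inf * (1.0 - np.exp(-ab * np.clip(t, 0.0, release_duration)))
    peak = single_spike_peak(alpha, beta, release_duration)
    falling = peak * np.exp(-beta * (t - release_duration))
    out = np.where(t <= release_duration, rising, falling)
    return np.where(t < 0, 0.0, out)


def compound_alpha_scale(alpha: float, beta: float, t_release: float,
                         population_release: float = POPULATION_RELEASE_STEP) -> float:
    """Rescaling factor k for the compound-ORN release rate, α̃ = k·α.

    k is defined so that the maximal single-spike activation of the compound
    synapse (release open for ``t_release``) equals that of the per-ORN
    population description, in which a durationless spike holds T = 1 only for
    the integration step in which it occurs (``population_release`` ms, the
    engine's step-size cap by default).  Both peaks have closed forms, so k is
    found by root bracketing on their difference.

    Raises
    ------
    ValueError
        If no root exists in (0, 1] (i.e. the population peak exceeds the
        compound peak even at k = 1, which happens when
        ``population_release`` > ``t_release``).
    """
    if min(alpha, beta, t_release, population_release) <= 0:
        raise ValueError("all rates and durations must be positive")
    target = single_spike_peak(alpha, beta, population_release)
    if abs(t_release - population_release) < 1e-12:
        return 1.0

    def gap(k: float) -> float:
        return single_spike_peak(k * alpha, beta, t_release) - target

    lo, hi = 1e-12, 1.0
    if gap(hi) < 0:
        raise ValueError(
            "no rescaling factor in (0, 1]: the population-description peak "
            f"exceeds the compound peak at k=1 (t_release={t_release}, "
            f"population_release={population_release})"
        )
    return float(brentq(gap, lo, hi, xtol=1e-15, rtol=1e-15))


def calibrate_t_release(alpha: float = 1.0 / 20.0, beta: float = 1.0 / 50.0,
                        target_scale: float = 0.556,
                        population_release: float = POPULATION_RELEASE_STEP) -> float:
    """Release duration at which the compound rescaling equals ``target_scale``.

    Used once to fix the package default t_release from the published
    compound-ORN calibration anchor; kept as a function so the calibration is
    reproducible.
    """
    def gap(tr: float) -> float:
        return compound_alpha_scale(alpha, beta, tr, population_release) - target_scale

    return float(brentq(gap, population_release + 1e-9, 5.0, xtol=1e-13))
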