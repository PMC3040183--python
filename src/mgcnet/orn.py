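"""Compound-Poisson olfactory receptor neuron (ORN) populations.

ORN spiking in the presence of pheromone follows Poisson statistics with a
stimulus-dependent rate.  Since the superposition of independent Poisson
processes is again Poisson, a population of N_ORN cells firing at the
single-cell rate λ_s is emulated by one "compound" source of rate
λ = λ_s · N_ORN.  At the rates reached here (up to ~100 spikes/ms for a
convergence of 1000) several spikes routinely fall inside a single
integration step, so the source emits integer spike *counts* per step which
feed the summed transmitter drive of the modified synapse model directly;
the ORN membrane potential plays no further role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ORNPopulation",
    "compound_rate",
    "sample_spike_counts",
    "dose_to_rate",
    "convergence_estimate",
]

#: dose–response anchors: flow (µg/sec) → single-ORN firing rate (Hz)
DOSE_ANCHORS = ((1e-8, 10.0), (1e-2, 300.0))


@dataclass(frozen=True)
class ORNPopulation:
    """One ORN population represented by a compound Poisson source."""

    lambda_s: float = 0.01      # ms⁻¹, single-cell rate
    n_orn: int = 1000           # population size (= ORN→LN convergence)
    resting_potential: float = -60.0  # mV (bookkeeping only)
    spike_amplitude: float = 80.0     # mV, durationless impulse (bookkeeping)
    stream_id: int = 0          # RNG sub-stream, split from the master seed

    def __post_init__(self) -> None:
        if self.lambda_s < 0:
            raise ValueError("single-cell rate must be non-negative")
        if self.n_orn < 1:
            raise ValueError("population size must be at least 1")

    @property
    def rate(self) -> float:
        """Compound rate λ = λ_s · N_ORN (ms⁻¹)."""
        return compound_rate(self.lambda_s, self.n_orn)


def compound_rate(lambda_s: float, n_orn: int) -> float:
    """Compound Poisson rate λ = λ_s · N_ORN (ms⁻¹)."""
    if lambda_s < 0 or n_orn < 1:
        raise ValueError("require lambda_s >= 0 and n_orn >= 1")
    return lambda_s * n_orn


def sample_spike_counts(lam: float, dt: float, steps: int, seed: int) -> np.ndarray:
    """Per-step spike counts q ~ Poisson(λ·Δt), reproducible given the seed."""
    if lam < 0 or dt <= 0:
        raise ValueError("require lam >= 0 and dt > 0")
    rng = np.random.default_rng(seed)
    return rng.poisson(lam * dt, size=int(steps))


def dose_to_rate(flow: float) -> float:
    """Single-ORN firing rate λ_s (ms⁻¹) for a pheromone flow (µg/sec).

    Log-linear interpolation between the published dose–response anchors
    (10⁻⁸ µg/sec → 10 Hz, 10⁻² µg/sec → 300 Hz).  Flows outside the anchored
    range are refused rather than extrapolated.
    """
    (f_lo, r_lo), (f_hi, r_hi) = DOSE_ANCHORS
    if not (f_lo <= flow <= f_hi):
        raise ValueError(f"flow {flow} µg/sec outside calibrated range [{f_lo}, {f_hi}]")
    frac = (np.log10(flow) - np.log10(f_lo)) / (np.log10(f_hi) - np.log10(f_lo))
    rate_hz = r_lo + frac * (r_hi - r_lo)
    return rate_hz / 1000.0


def convergence_estimate(n_orn: float, n_ln: float) -> float:
    """Anatomical ORN→LN convergence ratio n_ORN / n_LN.

    With ~85,700 pheromone-sensitive ORNs and ~300 pheromone-sensitive LNs
    (25% of the 1225 LN somata) the ratio is upwards of 285:1; since ORN axons
    arborise and contact several LNs the effective value can be larger still.
    """
    if n_ln < 1:
        raise ValueError("need at least one LN")
    return n_orn / n_ln
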