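"""Stimulus protocol, response matrix, target profile, cost and latency metrics.

The model is probed with all pairings of 10 geometrically spaced single-ORN
rates, λ_i = λ₀·1.3^i with λ₀ = 0.01 ms⁻¹ (10 Hz), covering roughly one order
of magnitude of ORN firing.  Each rate pair is presented for 250 ms with
250 ms of silence between presentations.  The projection neuron's output is
summarized by a Gaussian-kernel spike density function evaluated at each
presentation midpoint, giving a 10×10 response matrix r.  A trial's quality is
the negated overlap of r with a target-profile weight matrix ř favouring
responses on the target-ratio diagonal: s(r) = −Σ_ij r_ij·ř_ij (lower is
better).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .engine import Simulation, SimulationConfig, EngineError
from .network import NetworkSpec

__all__ = [
    "StimulusGrid",
    "ResponseMatrix",
    "TargetProfile",
    "LatencyRecord",
    "build_grid",
    "sdf",
    "run_protocol",
    "response_matrix",
    "target_profile",
    "cost",
    "decision_latency",
    "winner_census",
    "latency_cost_correlation",
    "ProtocolResult",
    "STABLE_TRAIN_MAX_ISI",
    "STABLE_TRAIN_END_SLACK",
]

#: operationalization of a "stable, unbroken spike train": no inter-spike
#: interval above this (ms) and the train reaches within END_SLACK of offset
STABLE_TRAIN_MAX_ISI = 50.0
STABLE_TRAIN_END_SLACK = 50.0


@dataclass(frozen=True)
class StimulusGrid:
    """Geometric grid of single-ORN rates plus the presentation timing."""

    lambda0: float = 0.01        # ms⁻¹
    factor: float = 1.3
    size: int = 10
    indices: tuple[int, ...] = ()  # subset of 0..size-1; empty = all
    on_ms: float = 250.0
    off_ms: float = 250.0
    settle_ms: float = 250.0     # silent lead-in before the first presentation

    def __post_init__(self) -> None:
        if min(self.on_ms, self.off_ms) <= 0 or self.settle_ms < 0:
            raise ValueError("durations must be positive")

    @property
    def active_indices(self) -> tuple[int, ...]:
        return self.indices if self.indices else tuple(range(self.size))

    @property
    def n(self) -> int:
        return len(self.active_indices)

    def rate(self, i: int) -> float:
        """λ_i = λ₀ · factor^i (ms⁻¹)."""
        return self.lambda0 * self.factor ** i

    def rates(self) -> np.ndarray:
        return np.array([self.rate(i) for i in self.active_indices])

    def pairs(self, order_seed: int | None = None) -> list[tuple[int, int, float, float]]:
        """Presentation order over (i: λ_a index, j: λ_b index).

        Row-major by default.  With ``order_seed`` the order is a seeded
        permutation: synaptic tails from one presentation (≈1% of peak after
        the 250 ms gap) then bias each window's early competition in a random
        rather than systematic direction, the usual counterbalancing argument.
        """
        out = []
        for i in self.active_indices:
            for j in self.active_indices:
                out.append((i, j, self.rate(i), self.rate(j)))
        if order_seed is not None:
            rng = np.random.default_rng(order_seed)
            out = [out[k] for k in rng.permutation(len(out))]
        return out

    def onset(self, k: int) -> float:
        return self.settle_ms + k * (self.on_ms + self.off_ms)

    @property
    def total_duration(self) -> float:
        return self.settle_ms + self.n ** 2 * (self.on_ms + self.off_ms)


def build_grid(**kwargs) -> StimulusGrid:
    """The full 10×10 protocol grid with the standard timing."""
    return StimulusGrid(**kwargs)


@dataclass
class ResponseMatrix:
    values: np.ndarray          # (n, n), rows = λ_a index, cols = λ_b index
    grid: StimulusGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("response values must be non-negative")


@dataclass
class TargetProfile:
    """Weight matrix ř for a target ratio R (λ_b = R·λ_a on the ridge)."""

    ratio: float
    weights: np.ndarray
    grid: StimulusGrid
    a: float = 18.0
    b: float = 1.25
    c: float = 0.3


@dataclass
class LatencyRecord:
    i: int
    j: int
    level: str                  # 'LN' | 'PN'
    latency: float | None       # ms from onset, None when omitted
    omission: str = ""          # '' | 'no train' | 'truncated train' |
                                # 'multiple winners' | 'active at onset'


def sdf(spikes: np.ndarray, t: float, sigma: float = 400.0) -> float:
    """Spike density f(t) = Σ_i exp(−(t−t_i)²/σ²) with σ = 400 ms.

    The kernel is used exactly as printed (σ², no 2σ², no normalization), so a
    single spike at t contributes 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size == 0:
        return 0.0
    return float(np.sum(np.exp(-((t - spikes) / sigma) ** 2)))


def response_matrix(pn_spikes: np.ndarray, grid: StimulusGrid,
                    sigma: float = 400.0, meta: dict | None = None) -> ResponseMatrix:
    """SDF of the PN at the temporal midpoint of every presentation.

    The SDF is evaluated on the full protocol spike record, so spikes from
    adjacent presentations contribute (σ exceeds the presentation window).
    """
    pn_spikes = np.asarray(pn_spikes, dtype=float)
    if pn_spikes.size and pn_spikes.max() > grid.total_duration + 1e-6:
        raise ValueError("spike record extends beyond the protocol duration")
    n = grid.n
    vals = np.empty((n, n))
    for k in range(n * n):
        mid = grid.onset(k) + grid.on_ms / 2.0
        vals[k // n, k % n] = sdf(pn_spikes, mid, sigma)
    return ResponseMatrix(vals, grid, meta or {})


def target_profile(ratio: float, grid: StimulusGrid | None = None, *,
                   a: float = 18.0, b: float = 1.25, c: float = 3 / 10) -> TargetProfile:
    """Target weights ř_ij = a·(exp(−(d_ij/b)²) − c).

    d_ij is the distance in (geometric) grid steps from the target-ratio ridge
    C_j = R·C_i, computed on the concentration scale C_i = 2·1.3^i:
    d_ij = |log_f (C_j / (R·C_i))| = |j − i − log_f R|.  The weights are
    maximal on the ridge, the punishment grows smoothly with distance near the
    ridge, and far off the ridge it plateaus at the constant −a·c.
    """
    grid = grid or build_grid()
    f = grid.factor
    shift = np.log(ratio) / np.log(f)
    idx = np.array(grid.active_indices, dtype=float)
    d = np.abs(idx[None, :] - idx[:, None] - shift)  # [i (λ_a), j (λ_b)]
    w = a * (np.exp(-((d / b) ** 2)) - c)
    return TargetProfile(ratio=ratio, weights=w, grid=grid, a=a, b=b, c=c)


def cost(r: ResponseMatrix | np.ndarray, profile: TargetProfile) -> float:
    """Trial cost s(r) = −Σ_ij r_ij·ř_ij; lower (more negative) is better."""
    vals = r.values if isinstance(r, ResponseMatrix) else np.asarray(r, dtype=float)
    if vals.shape != profile.weights.shape:
        raise ValueError("response and target shapes differ")
    return float(-np.sum(vals * profile.weights))


def _stable_train_start(spikes: np.ndarray, onset: float, offset: float,
                        max_isi: float = STABLE_TRAIN_MAX_ISI,
                        end_slack: float = STABLE_TRAIN_END_SLACK) -> tuple[float | None, str]:
    """First spike of the maximal unbroken train reaching the window end."""
    sp = np.asarray(spikes, dtype=float)
    sp = sp[(sp >= onset) & (sp <= offset)]
    if sp.size == 0:
        return None, "no train"
    # walk back from the last spike while gaps stay within max_isi
    start = sp.size - 1
    while start > 0 and sp[start] - sp[start - 1] <= max_isi:
        start -= 1
    if sp[-1] < offset - end_slack:
        return None, "truncated train"
    return float(sp[start]), ""


def decision_latency(spikes: np.ndarray, window: tuple[float, float],
                     max_isi: float = STABLE_TRAIN_MAX_ISI,
                     end_slack: float = STABLE_TRAIN_END_SLACK, *,
                     require_fresh: bool = False) -> float | None:
    """Time from stimulus onset to the first spike of a stable unbroken train.

    Returns None when the cell produced no train inside the window or the
    train did not last to the end of the presentation.  With
    ``require_fresh`` a train whose spiking predates the onset (a spike within
    ``max_isi`` before it, i.e. the cell was still responding to the previous
    stimulus) is omitted too: it is not a decision *about this stimulus*.
    """
    onset, offset = window
    spikes = np.asarray(spikes, dtype=float)
    t0, _ = _stable_train_start(spikes, onset, offset, max_isi, end_slack)
    if t0 is None:
        return None
    if require_fresh and np.any((spikes >= onset - max_isi) & (spikes < onset)):
        return None
    return t0 - onset


def winner_census(group_spikes: dict[str, np.ndarray], window: tuple[float, float],
                  max_isi: float = STABLE_TRAIN_MAX_ISI,
                  end_slack: float = STABLE_TRAIN_END_SLACK) -> str:
    """Which LN group sustains an unbroken train through the presentation.

    ``group_spikes`` maps group labels to the merged spike train of the
    group's LNs.  Returns the unique winning label, 'multiple' when more than
    one group qualifies, or 'none'.
    """
    onset, offset = window
    winners = [g for g, sp in group_spikes.items()
               if _stable_train_start(np.sort(np.asarray(sp, dtype=float)),
                                      onset, offset, max_isi, end_slack)[0] is not None]
    if not winners:
        return "none"
    if len(winners) > 1:
        return "multiple"
    return winners[0]


def latency_cost_correlation(latencies, costs) -> tuple[float, float]:
    """Pearson product-moment correlation of per-trial latency and cost."""
    lat = np.asarray(latencies, dtype=float)
    cst = np.asarray(costs, dtype=float)
    if lat.size != cst.size or lat.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(lat) == 0 or np.std(cst) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(lat, cst)
    return float(r), float(p)


# --------------------------------------------------------------------------


@dataclass
class ProtocolResult:
    """Everything one full-protocol trial yields."""

    grid: StimulusGrid
    spikes: dict[str, np.ndarray]
    response: ResponseMatrix
    pn_latencies: list[LatencyRecord]
    ln_latencies: list[LatencyRecord]
    winners: np.ndarray          # (n, n) array of winner labels
    n_multiple_winners: int
    seed: int

    def mean_pn_latency(self) -> float:
        vals = [rec.latency for rec in self.pn_latencies if rec.latency is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def trial_cost(self, profile: TargetProfile) -> float:
        return cost(self.response, profile)


def run_protocol(spec: NetworkSpec, grid: StimulusGrid, seed: int = 0, *,
                 eps: float = 1e-6, pn_name: str | None = None,
                 sigma: float = 400.0, shuffle_order: bool = False,
                 orn_event_grid: float = 0.1,
                 max_steps_per_segment: int = 3_000_000,
                 max_steps_total: int | None = None) -> ProtocolResult:
    """Run the full stimulus protocol on one network and score it.

    Each presentation window is integrated on a continuous clock; ORN rates
    step to (λ_a, λ_b) at onset and back to zero during gaps.  Decision
    latencies are taken at the PN and at the LN groups, with the published
    omission rules: windows without a stable train, with a truncated train, or
    with multiple winning LN groups yield no latency data point.
    """
    cfg = SimulationConfig(duration=grid.total_duration, eps=eps, seed=seed,
                           orn_event_grid=orn_event_grid,
                           max_steps_per_segment=max_steps_per_segment)
    sim = Simulation(spec, cfg)
    order = grid.pairs(order_seed=seed) if shuffle_order else grid.pairs()
    if grid.settle_ms > 0:
        sim.run_segment(grid.settle_ms)
    for k, (_, _, la, lb) in enumerate(order):
        onset = grid.onset(k)
        sim.run_segment(onset + grid.on_ms, la, lb)
        sim.run_segment(onset + grid.on_ms + grid.off_ms)
        if max_steps_total is not None and sim.steps_total > max_steps_total:
            raise EngineError(
                f"protocol step budget exceeded after presentation {k}")
    spikes = sim.spikes()

    pn = pn_name or next(c.name for c in spec.cells if c.role == "PN")
    groups = spec.ln_groups()
    merged = {g: np.sort(np.concatenate([spikes[n] for n in names]))
              for g, names in groups.items()}

    idx_of = {v: k for k, v in enumerate(grid.active_indices)}
    n = grid.n
    vals = np.empty((n, n))
    for k, (i, j, _, _) in enumerate(order):
        mid = grid.onset(k) + grid.on_ms / 2.0
        vals[idx_of[i], idx_of[j]] = sdf(spikes[pn], mid, sigma)
    resp = ResponseMatrix(vals, grid,
                          meta={"model": "conductance", "seed": seed,
                                "arrangement": spec.arrangement})
    pn_lat: list[LatencyRecord] = []
    ln_lat: list[LatencyRecord] = []
    winners = np.empty((n, n), dtype=object)
    n_multi = 0
    for k, (i, j, _, _) in enumerate(order):
        onset = grid.onset(k)
        window = (onset, onset + grid.on_ms)
        win = winner_census(merged, window)
        winners[idx_of[i], idx_of[j]] = win
        if win == "multiple":
            n_multi += 1
            pn_lat.append(LatencyRecord(i, j, "PN", None, "multiple winners"))
            ln_lat.append(LatencyRecord(i, j, "LN", None, "multiple winners"))
            continue
        # LN-level latency: earliest stable-train onset over the groups
        ln_candidates = [decision_latency(merged[g], window) for g in merged]
        ln_vals = [v for v in ln_candidates if v is not None]
        if ln_vals:
            ln_lat.append(LatencyRecord(i, j, "LN", min(ln_vals)))
        else:
            ln_lat.append(LatencyRecord(i, j, "LN", None, "no train"))
        lat = decision_latency(spikes[pn], window)
        if lat is None:
            sp = spikes[pn]
            sp = sp[(sp >= window[0]) & (sp <= window[1])]
            pn_lat.append(LatencyRecord(i, j, "PN", None,
                                        "no train" if sp.size == 0 else "truncated train"))
        else:
            pn_lat.append(LatencyRecord(i, j, "PN", lat))
    return ProtocolResult(grid, spikes, resp, pn_lat, ln_lat, winners, n_multi, seed)
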