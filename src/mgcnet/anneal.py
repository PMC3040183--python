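"""Simplex simulated annealing of the five free synaptic conductances.

The optimizer is the classic downhill-simplex-with-thermal-noise hybrid: every
stored vertex cost is perturbed upward by a random amount proportional to the
temperature T and every trial-point cost downward, so uphill moves are
accepted with a Boltzmann-like probability; at T = 0 the procedure reduces to
the plain Nelder–Mead simplex.  The objective is the trial cost of a full
stimulus protocol averaged over a small number of Poisson realizations
(three in the published procedure), evaluated at non-negative conductances
(negative proposals are clipped).

The five optimized parameters are the ORN→specialist, ORN→generalist and the
three inter-LN conductances; the disinhibition pathway (LNc→LNi, LNi→PN) is
fixed.  Every evaluated point is logged, which is what makes post-hoc "cloud"
analyses of the explored parameter space possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .network import ConductanceSet, build_elementary
from .protocol import StimulusGrid, build_grid, target_profile, run_protocol, cost

__all__ = ["AnnealingConfig", "AnnealingResult", "objective", "anneal"]


@dataclass(frozen=True)
class AnnealingConfig:
    """Controls of the simplex annealing run."""

    x0: tuple[float, ...] = (0.12, 0.06, 0.3, 0.3, 0.3)  # µS, initial vertex
    spread: float = 0.4          # relative displacement of the other vertices
    t0: float | None = None      # initial temperature; None = cost-spread scale
    cooling: float = 0.9         # geometric decay applied per simplex sweep
    sweeps_per_temp: int = 10    # iterations between cooling steps
    max_iter: int = 40_000       # iteration (objective evaluation) cap
    shrink_fraction: float = 1e-4  # stop when mean edge length shrinks to 0.01%
    trials: int = 3              # Poisson realizations averaged per evaluation
    g_max: float = 2.0           # µS, physiological box bound on proposals
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("need at least one trial per evaluation")
        if not (0 < self.shrink_fraction < 1):
            raise ValueError("shrink fraction must be in (0, 1)")


@dataclass
class AnnealingResult:
    best: ConductanceSet
    best_cost: float
    trace: pd.DataFrame          # iteration, g1..g5, cost, temperature
    n_iter: int
    terminated_by: str           # 'shrink' | 'max_iter'


def objective(conductances, *, convergence: int = 1000,
              grid: StimulusGrid | None = None, seed: int = 0,
              trials: int = 3, ratio: float = 1.0, eps: float = 1e-5,
              inter_ln_alpha: float = 1 / 20, inter_ln_beta: float = 1 / 50,
              shuffle_order: bool = False, orn_event_grid: float = 0.1,
              max_steps_total: int | None = None) -> float:
    """Mean trial cost of the elementary unit at the given conductances.

    Runs ``trials`` full-protocol simulations with distinct sub-seeds and
    averages the cost against the target profile for ``ratio``.  A simulation
    abort maps to +inf so the annealer simply rejects the proposal.
    """
    grid = grid or build_grid()
    if max_steps_total is None:
        # generous per-trial budget: pathological always-firing proposals abort
        # to +inf instead of dominating the optimization wall time
        max_steps_total = 20_000 * len(grid.pairs())
    gset = ConductanceSet.from_free_vector(np.asarray(conductances, dtype=float))
    spec = build_elementary(gset, convergence=convergence,
                            inter_ln_alpha=inter_ln_alpha,
                            inter_ln_beta=inter_ln_beta)
    prof = target_profile(ratio, grid)
    costs = []
    for k in range(trials):
        try:
            res = run_protocol(spec, grid, seed=seed * 1009 + k, eps=eps,
                               shuffle_order=shuffle_order,
                               orn_event_grid=orn_event_grid,
                               max_steps_total=max_steps_total)
        except Exception:
            return float("inf")
        costs.append(cost(res.response, prof))
    return float(np.mean(costs))


def _mean_edge_length(simplex: np.ndarray) -> float:
    n = simplex.shape[0]
    acc, cnt = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            acc += float(np.linalg.norm(simplex[i] - simplex[j]))
            cnt += 1
    return acc / cnt


def anneal(func: Callable[[np.ndarray, int], float] | Callable[[np.ndarray], float],
           config: AnnealingConfig) -> AnnealingResult:
    """Minimize ``func`` over the five conductances by simplex annealing.

    ``func`` is called as ``func(x)`` with a parameter vector (clipped to be
    non-negative by the caller's objective as needed).  The best-so-far point
    and cost are tracked exactly (without thermal noise); the logged trace
    contains every evaluated point.
    """
    rng = np.random.default_rng(config.seed)
    x0 = np.asarray(config.x0, dtype=float)
    ndim = x0.size
    simplex = np.tile(x0, (ndim + 1, 1))
    for k in range(ndim):
        simplex[k + 1, k] *= (1.0 + config.spread)
        if simplex[k + 1, k] == 0.0:
            simplex[k + 1, k] = config.spread * 0.01
    simplex = np.clip(simplex, 0.0, config.g_max)

    log_rows: list[dict] = []
    n_eval = 0

    def evaluate(x: np.ndarray, temp: float) -> float:
        nonlocal n_eval
        y = float(func(x))
        n_eval += 1
        log_rows.append({"iteration": n_eval,
                         **{f"g{k + 1}": float(v) for k, v in enumerate(x)},
                         "cost": y, "temperature": temp})
        return y

    init_edge = _mean_edge_length(simplex)
    t = config.t0
    y = np.array([evaluate(simplex[i], t or 0.0) for i in range(ndim + 1)])
    if t is None:
        spread = float(np.max(y) - np.min(y))
        t = 0.2 * spread if spread > 0 else 1.0

    best_idx = int(np.argmin(y))
    best_x, best_y = simplex[best_idx].copy(), float(y[best_idx])
    terminated_by = "max_iter"

    def thermal(size=None):
        # positive log-distributed fluctuation, the amebsa prescription
        return -np.log(rng.uniform(low=1e-12, high=1.0, size=size))

    sweep = 0
    while n_eval < config.max_iter:
        # thermally perturbed ranking of the vertices
        y_fluct = y + t * thermal(ndim + 1)
        order = np.argsort(y_fluct)
        lo, hi, nhi = order[0], order[-1], order[-2]

        centroid = (np.sum(simplex, axis=0) - simplex[hi]) / ndim

        def try_point(fac: float) -> tuple[np.ndarray, float, float]:
            x_new = np.clip(centroid + fac * (simplex[hi] - centroid),
                            0.0, config.g_max)
            y_new = evaluate(x_new, t)
            return x_new, y_new, y_new - t * thermal()

        # reflection
        x_r, y_r, yf_r = try_point(-1.0)
        if y_r < best_y:
            best_x, best_y = x_r.copy(), y_r
        if yf_r < y_fluct[lo]:
            # expansion
            x_e, y_e, yf_e = try_point(-2.0)
            if y_e < best_y:
                best_x, best_y = x_e.copy(), y_e
            if yf_e < yf_r:
                simplex[hi], y[hi] = x_e, y_e
            else:
                simplex[hi], y[hi] = x_r, y_r
        elif yf_r < y_fluct[nhi]:
            simplex[hi], y[hi] = x_r, y_r
        else:
            # contraction
            x_c, y_c, yf_c = try_point(0.5)
            if y_c < best_y:
                best_x, best_y = x_c.copy(), y_c
            if yf_c < y_fluct[hi]:
                simplex[hi], y[hi] = x_c, y_c
            else:
                # shrink toward the (thermally) best vertex
                for i in range(ndim + 1):
                    if i != lo:
                        simplex[i] = 0.5 * (simplex[i] + simplex[lo])
                        y[i] = evaluate(simplex[i], t)
                        if y[i] < best_y:
                            best_x, best_y = simplex[i].copy(), float(y[i])

        sweep += 1
        if sweep % config.sweeps_per_temp == 0:
            t *= config.cooling
        if _mean_edge_length(simplex) <= config.shrink_fraction * init_edge:
            terminated_by = "shrink"
            break

    trace = pd.DataFrame(log_rows)
    return AnnealingResult(
        best=ConductanceSet.from_free_vector(best_x),
        best_cost=best_y,
        trace=trace,
        n_iter=n_eval,
        terminated_by=terminated_by,
    )
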