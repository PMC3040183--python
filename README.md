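# mgcnet

Conductance-based model of pheromone component-**ratio** detection in the
macroglomerular complex (MGC) of the male moth antennal lobe.

Male moths of many species must recognise a specific concentration ratio of
two pheromone blend components, independently of the overall concentration,
to locate conspecific females. `mgcnet` implements a minimal feed-forward
competition circuit that does this: two compound-Poisson ORN populations
(one per component) excite *specialist* local neurons (LNa, LNb) and a
*generalist* (LNc); all LNs inhibit each other (winner-take-all); the
generalist's victory silences an intermediary inhibitory neuron (LNi),
disinhibiting the projection neuron (PN) — a discrete, concentration-invariant
"ratio detected" spike train. The package is for computational neuroscientists
studying olfactory blend coding, latency-to-first-spike competition, and
winner-take-all dynamics in spiking networks.

## The model in brief

* **Neurons** — Traub–Miles type-1 Hodgkin–Huxley point neurons (mV, ms, nA,
  µS units; membrane area folded into the constants). LNi and PN are
  spontaneously active via a constant 0.1 nA injection.
* **Synapses** — first-order transmitter kinetics
  `dS/dt = α·T·(1−S) − β·S`, `I = g·S·(E_rev − E_post)`, with release open for
  `t_release` after each presynaptic event and overlapping windows summing;
  defaults α = (20 ms)⁻¹, β = (50 ms)⁻¹. A whole ORN population is emulated by
  one compound Poisson source (rate λ = λ_s·N_ORN) whose release rate carries
  the calibrated rescaling α̃ = 0.556·α.
* **Protocol** — all 100 pairings of rates λ_i = 0.01·1.3^i ms⁻¹ (i = 0…9),
  250 ms on / 250 ms off; PN output scored by a Gaussian spike-density
  function (σ = 400 ms) at presentation midpoints; trial cost
  `s(r) = −Σ r_ij·ř_ij` against a target profile peaked on the ratio-R
  diagonal (a = 18, b = 1.25, c = 0.3, C_i = 2·1.3^i).
* **Optimization** — simplex simulated annealing of the five free
  conductances against the trial-averaged cost.
* **Extensions** — stacked (independent units, shared LNi/PN) and grouped
  (glomerular LN populations, all-to-all inhibition between glomeruli)
  arrangements; decision-latency analysis; a deterministic rate-based
  reduction.

See `docs/methods.md` for assumptions, parameter provenance, and limitations.

## Worked example

Run one full stimulus protocol on the elementary unit and score it:

```python
import numpy as np
from mgcnet import (build_elementary, build_grid, run_protocol,
                    target_profile, cost, PERTURBATION_BASELINE)

spec = build_elementary(PERTURBATION_BASELINE, convergence=1000)
grid = build_grid()                        # the 10×10 rate grid
res = run_protocol(spec, grid, seed=11, eps=1e-5)

prof = target_profile(1.0, grid)           # 1:1 target ratio
print("trial cost:", round(cost(res.response, prof), 1))
print("mean PN decision latency [ms]:", round(res.mean_pn_latency(), 1))
pn = res.spikes["PN"]
on = grid.onset(22)                        # the (2,2) diagonal presentation
print("PN spikes in one 1:1 window:",
      int(((pn >= on) & (pn <= on + 250)).sum()))
```

prints

```
trial cost: -429.2
mean PN decision latency [ms]: 122.8
PN spikes in one 1:1 window: 5
```

The cost is negative because the PN responds mainly on and next to the 1:1
diagonal, where the target profile rewards it. The misses on parts of the
diagonal and the stray responses one step off it at high concentrations are
the elementary unit's documented error modes — the single-LN competition is
decided by the first spike, so Poisson input noise produces both. The PN's
decision latency of ≈120–150 ms is dominated by the decay of the LNi→PN
inhibition after the generalist wins (≈3/β); the ~5 PN spikes in a correct
250 ms window are what remains of the presentation after that disinhibition
delay.

The same pipeline drives the scripted experiment reproductions:

```bash
mgcnet experiment population --arrangement grouped --trials 10 --seed 1 --out out/
mgcnet experiment first-spike --trials 50 --out out_fs/
mgcnet anneal --convergence 200 --iterations 500 --out out_anneal/
```

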