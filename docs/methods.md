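# Methods

## The model

`mgcnet` simulates an elementary pheromone component-ratio recognition unit of
the male moth macroglomerular complex (MGC) and its population extensions. Two
olfactory receptor neuron (ORN) populations, each narrowly tuned to one of the
two components of a binary pheromone blend, excite their ipsilateral
*specialist* local neurons (LNa, LNb) and a shared *generalist* local neuron
(LNc). The three LNs inhibit one another all-to-all (GABAergic), implementing
a winner-take-all competition; the generalist's output inhibits an
intermediary inhibitory neuron (LNi) that tonically inhibits the projection
neuron (PN). When the blend is near the unit's target ratio the generalist
wins, LNi falls silent, and the PN is disinhibited — a discrete "ratio
detected" signal that is concentration-invariant by construction. When one
component dominates, the corresponding specialist wins, LNi keeps firing and
the PN stays silent.

The network is feed-forward (no PN→LN or LN→ORN feedback); the only
recurrence is within the LN layer.

### Neurons

LNs, LNi and PN are single-compartment Traub–Miles Hodgkin–Huxley neurons
(type-1 excitability: firing rates rise continuously from zero at rheobase,
so the cells support graded rate competition). The canonical densities
(C = 1 µF/cm², g_Na = 100 mS/cm², g_K = 80 mS/cm², g_L = 0.1 mS/cm²,
E_Na = 50 mV, E_K = −100 mV, E_L = −67 mV) are folded into absolute units on
a membrane area of 10⁻⁴ cm², giving C = 0.1 nF and conductances in µS so that
synaptic strengths quoted in µS apply directly. Units throughout: mV, ms, nA,
µS, nF. With this scaling the 0.1 nA of constant current injected into LNi
and PN is suprathreshold (≈43 Hz tonic firing), which is what the
disinhibition readout requires, while the rheobase remains far below the
synaptic drives of interest.

LNi and PN are the spontaneously active cells; all inhibitory synapses
reverse at −80 mV, the ORN→LN synapses at 0 mV.

### Synapses

All synapses follow first-order transmitter kinetics

    dS/dt = α·T(t)·(1−S) − β·S,       I = g·S·(E_rev − E_post),

where T is the transmitter drive: each presynaptic event of q spikes at t_i
contributes q to T during [t_i, t_i + t_release]; overlapping windows sum.
Default rates are α = (20 ms)⁻¹ and β = (50 ms)⁻¹; the population-model
latency experiments vary the inter-LN α and use β = 0.025 ms⁻¹ there.

**Release duration.** t_release is not a published constant. We calibrate it
against the published compound-ORN anchor: the rescaled release rate
α̃ = 0.556·α is defined so that the maximal single-spike activation of the
compound synapse equals that of the per-ORN population description, in which
a "durationless" ORN impulse drives release only for the integration step in
which it occurs (0.5 ms, the step cap). Solving for the release duration that
makes the peak-matching factor equal 0.556 at α = (20 ms)⁻¹, β = (50 ms)⁻¹
gives t_release = 0.9029 ms, the package default. `compound_alpha_scale`
computes the factor for arbitrary kinetics by root bracketing on the
closed-form peaks; the package never hard-codes 0.556.

**Compound-ORN aggregation.** A whole ORN population of size N_ORN firing at
the single-cell rate λ_s is emulated by one compound Poisson source of rate
λ = λ_s·N_ORN. The compound synapse tracks the *population-mean* activation:
its transmitter drive per spike is 1/N_ORN of a unit synapse's. This keeps
the mean activation graded in λ_s (⟨T⟩ = λ_s·t_release regardless of N) and
makes the convergence rate act purely on the input's signal-to-noise ratio —
the role anatomy assigns it. With raw summed counts instead, a
convergence-1000 synapse would sit at T ≈ 10–100 and the saturating kinetics
would pin S ≈ 1 across the entire stimulus grid, erasing the ratio
information the circuit is supposed to read; the two descriptions would also
cease to be equivalent at any operating point beyond a single spike.

### Conductances

The five free synaptic strengths are g_ORN→LNsp, g_ORN→LNgen and the inter-LN
triplet g_LNi (specialist→generalist), g_LNt (specialist→specialist), g_LNo
(generalist→specialist); the symmetric 1:1 target fixes
g_ORNa→LNa = g_ORNb→LNb and g_ORNa→LNc = g_ORNb→LNc. The disinhibition
pathway is fixed at g_LNc→LNi = g_LNi→PN = 0.5 µS — strong enough that tonic
LNi firing silences the PN and a winning generalist silences LNi; these two
strengths are not published and only need to be suprathreshold for their
targets.

The package's reference set for the population experiments is
g_ORN→LNsp = 0.103 µS with g_ORN→LNgen = 0.059 µS (ratio 1.75 — the stated
optimal band of ≈1.7–1.8; the ratio controls where the generalist's summed
drive g_gen·(S_a+S_b) overtakes the stronger specialist's g_sp·max(S_a,S_b),
and hence the width of the detected band: ratio r accepts inputs within
−log₁.₃(r−1) grid steps of the diagonal, ≈1 step at r = 1.75), and balanced
inter-LN strengths g_LNi = g_LNo = 0.44 µS, g_LNt = 0.389 µS (balance of the
inbound and outbound strengths is itself one of the model's findings). The
perturbation experiment defaults to its own annealed baseline (see below).

### Integration engine

All neuron and synapse equations form one coupled ODE system integrated with
an embedded Dormand–Prince 5(4) Runge–Kutta pair under a per-step accuracy
goal ε (component scale 100 mV for voltages, 1 for gating and activations),
with the step confined to [10⁻⁶, 0.5] ms. Steps are additionally clipped so
they do not cross a transmitter-window edge, keeping the piecewise-constant
drive exact per step; compound-ORN event times snap up to a 0.1 ms lattice
(windows then share edges) and the clipping has a 0.02 ms floor — without
these, the stepper ratchets down to the spacing of past Poisson events.

Poisson counts q ~ Poisson(λ·Δt) are sampled once per *accepted* step and
enter the drive from the end of that step; rejected trial steps consume no
randomness, so a (network, rates, seed, ε) combination reproduces
bit-identically. Spikes are detected online as upward 0 mV crossings
(linearly interpolated, 1 ms refractory guard) and feed the cell's outgoing
synapses. Desk-scale runs use ε = 10⁻⁴–10⁻⁶ (the refinement test bounds the
spike-time effect of halving ε below 0.1 ms); single-synapse oracle checks
use 10⁻¹⁰.

### Stimulus protocol and scoring

Single-ORN rates λ_i = 0.01·1.3^i ms⁻¹, i = 0…9 (10–106 Hz); all 100 (λ_a,
λ_b) pairs are presented for 250 ms with 250 ms silent gaps on one continuous
clock, after a 250 ms lead-in that settles the tonic LNi/PN state. The PN
response matrix holds the spike density function f(t) = Σ exp(−(t−t_i)²/σ²),
σ = 400 ms (no normalization, literal kernel), evaluated at each presentation
midpoint over the full spike record — adjacent presentations deliberately
leak in, since σ exceeds the window. The trial cost is s(r) = −Σ r_ij·ř_ij
against a target profile ř_ij = a·(exp(−(d_ij/b)²) − c) with a = 18,
b = 1.25, c = 0.3, where d_ij is the geometric-step distance from the
target-ratio ridge C_j = R·C_i on the concentration scale C_i = 2·1.3^i
(the published constants; the functional form is this package's
reconstruction satisfying the three published design goals: diagonal maximal,
graded near-ridge punishment, constant strong punishment −a·c far off the
ridge).

**Presentation order.** The order of the 100 pairs is not a published
constant; the package sweeps them row-major, the order the response-matrix
axes suggest. Synaptic tails decay with β ≈ (40–50 ms)⁻¹, so ≈0.2–0.7% of
peak activation survives the 250 ms gap, and because each window's
competition is decided in its first tens of milliseconds while drives are
still small, that residue couples consecutive presentations. A seeded
permutation of the order is available for sensitivity analyses
(``StimulusGrid.pairs(order_seed=...)``); under permuted order the
near-threshold diagonal detections degrade markedly, because a diagonal
window then typically follows a far-off-diagonal window whose decisive winner
leaves a strong one-sided residue.

**Decision latency.** Time from stimulus onset to the first spike of a
stable, unbroken train: no inter-spike interval above 50 ms and the train
reaching within 50 ms of stimulus offset (both ≈2× the slow synaptic decay
constant; exposed as parameters). Windows with no train or a truncated train
yield no data point; windows in which more than one LN group sustains a train
("multiple winners") are omitted too. The rule is applied literally — a train
whose activity persists from the previous presentation still counts from its
first in-window spike (``decision_latency(require_fresh=True)`` switches on
the stricter fresh-train reading). In population arrangements a group's train
is the merged spike train of its LNs. The PN latency of a fresh correct
detection is dominated by the decay of the LNi→PN activation after LNi is
silenced (≈3/β ≈ 130–150 ms), which is why it is much longer than the LN
competition latencies (10–40 ms); the grand mean over a protocol mixes these
with the shorter latencies of windows in which the previous response
persists.

### Population arrangements

*Stacked*: n independent elementary LN triplets, each with its own pair of
compound ORN sources (independent noise), converging on one shared LNi/PN;
only g_LNc→LNi is downscaled by n, so a unanimous vote reproduces the
elementary disinhibition drive. *Grouped*: three glomeruli of n like LNs with
directed all-to-all inhibition between (not within) glomeruli, each edge at
1/n of the elementary strength — the total inhibition an LN receives from a
rival glomerulus is conserved — while every LN keeps a full-strength,
independently noisy ORN drive (each generalist receives one source per
component). Within-glomerulus inhibition is available behind a switch,
default off (the published description connects glomeruli, not cells within
one).

### Simplex annealing

The five free conductances are optimized by the downhill-simplex/simulated
annealing hybrid: thermally perturbed vertex ranking (each stored cost gets
+T·(−ln u), each trial cost −T·(−ln u)), geometric cooling (factor 0.9 every
10 sweeps; T₀ defaults to 20% of the initial cost spread), termination when
the simplex's mean edge length shrinks to 0.01% of its initial value or at
the iteration cap (40 000 by default; desk runs use 500). Proposals are
projected onto the box [0, 2] µS; aborted or over-budget simulations score
+∞. Every evaluation is logged for cloud analyses. At T = 0 the procedure is
plain Nelder–Mead (verified against a quadratic bowl). The simplex starts at
the hand-tuned working point (specialist drive about twice the generalist
drive, inter-LN strengths 0.3 µS) — hand adjustment before annealing is how
the published optimization was seeded too; from a neutral equal-drive start a
desk-scale run cannot cross the broad plateau of silent configurations that
separates it from the selective optimum.

A desk-scale annealing run (convergence 200, 6×6 grid, 500 evaluations, one
realization per evaluation) keeps the ORN conductance ratio in the stated
1.7–1.8 band's vicinity with transverse inter-LN strength near 0.2 µS; the
perturbation experiment uses a uniform 0.22 µS inter-LN baseline from this
annealed scale (cf. the published uniform-baseline rerun at 0.18 µS).

### Rate-based reduction

The published derivation of the rate model is in supplementary material that
is not available; the reduction here is reconstructed functionally. Each cell
becomes a rate unit relaxing toward the tabulated f-I value of its total
current with the resting membrane time constant (τ = C/g_L = 10 ms); each
synapse carries the mean activation dS̄/dt = α·ν_pre·t_release·(1−S̄) − β·S̄;
driving forces use a fixed effective potential V_eff = −60 mV; compound ORN
sources enter through λ_s·t_release with the same α̃ rescaling. The f-I table
is measured from the spiking neuron (0–3 nA, 1.5 s per point). The readout is
the generalist's rate averaged over each presentation in place of the SDF.
The model is deterministic — no first-spike lock-in — so its validation
surface is agreement of single-cell fixed points and mean synaptic
activations with the spiking model (both tested), plus qualitative diagonal
dominance; no equation-level fidelity to the unavailable derivation is
claimed.

## What the synthetic inputs do and do not emulate

ORN spike trains are homogeneous Poisson processes with rectangular 250 ms
rate steps — no ORN adaptation, no receptor-binding kinetics, no plume
intermittency, and "durationless" spikes reduced to integer counts feeding
the synaptic drive. Dose–response is a log-linear map anchored at
10⁻⁸ µg/s → 10 Hz and 10⁻² µg/s → 300 Hz, refusing extrapolation. Passing
tests therefore demonstrate properties of the competition circuit under
idealized input statistics, not performance on real sensillum recordings.

## Desk-scale problem sizes

The test suite and the acceptance script scale the published experiments to
desk size as the package's own choice of problem size: 6×6 rate grids
(indices 0,2,4,5,7,9) where the full 10×10 is not required, 3 protocol trials
for the perturbation table, 50 repetitions per first-spike point, 10–20
grouped-model trials for latency and correlation statistics, 500-iteration
annealing sanity runs at one realization per evaluation, and ε = 10⁻⁵–3·10⁻⁵.
Published statistics quoted for context used 100–120 trials and 40 000
annealing iterations, so sample-noise on our side is correspondingly larger.

## Known limitations

* Several constants the behaviour depends on are not published (HH densities
  and membrane area, E_rev of the synapse classes, t_release, disinhibition
  strengths, presentation order, the exact compound-ORN aggregation and the
  target-profile formula); all are reconstructed as documented above and
  exposed in the API. Quantities that depend on them in detail (e.g. absolute
  cost values) are not reproduced, only their orderings and bands.
* The printed conv-1000 ORN conductance pair (ratio 1.39) contradicts the
  stated optimal ratio 1.7–1.8; this package follows the stated ratio (see
  the conductance section). With 1.39 the generalist wins a ±3.6-step band
  and selectivity collapses — in any reconstruction with graded synaptic
  drive, not just this one.
* Synaptic-tail carryover couples consecutive presentations; shuffling makes
  it unbiased but it still adds variance relative to isolated presentations.
* The stacked arrangement inherits the elementary unit's first-spike errors
  per unit; multiple-winner omissions are correspondingly frequent there.
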