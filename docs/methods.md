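# Methods

## Model

### Single mass

A region is a two-population (excitatory/inhibitory) alpha-rhythm neural
mass.  State per population: average membrane potential (mV) and pulse
density (spikes/s).  Potential → pulse density is the logistic sigmoid
`S(V) = q / (1 + exp(r (V_d − V)))`; pulse density → potential is a
critically damped second-order filter, `h(t) = G γ t e^{−γt}` with
`(G, γ) = (A, a)` for excitatory and `(B, b)` for inhibitory synapses
(DC gain `G/γ`, impulse peak `G/e` at `t = 1/γ`).  The closed loop is

- excitatory drive: `P(t) + g Σ_j W_ij E_j(t − T) − C2·I`,
- inhibitory drive: `C1·E`,

with `P(t)` i.i.d. Gaussian pulse density truncated at zero.  The
threshold potentials `V_d1` (excitatory) and `V_d2` (inhibitory) are the
sole intervention handles: lowering a threshold increases excitability.

### Default parameters

| parameter | value | units | meaning / why |
|---|---|---|---|
| A, a | 3.25, 120 | mV, 1/s | excitatory synaptic gain and rate |
| B, b | 22, 34 | mV, 1/s | inhibitory synaptic gain and rate |
| C1, C2 | 4.3, 81 | – | E→I and I→E intra-mass coupling |
| q, r | 5, 0.7 | 1/s, 1/mV | sigmoid ceiling and steepness |
| V_d1 = V_d2 | 7 | mV | baseline thresholds (interventions move these) |
| P_mean, P_sd | 238, 35 | 1/s | thalamic input |
| g, T | 4.2, 40 | –, ms | global coupling gain and uniform delay |
| dt, fs | 1 ms, 500 Hz | | Heun (explicit 2nd-order) integration; analysis rate |
| cycle | 4 s (0.5 s transient discarded) | | per unit of virtual time |

These constants are this package's own calibration of the model family
(the originals are unpublished); they were chosen, before any outcome
testing, to satisfy the intended operating regime:

1. the *coupled healthy network* oscillates at ≈ 9.2 Hz with ≈ 0.80 of
   its 0.5–30 Hz power in the lower alpha band (8–10 Hz) and a global
   mean PLI of ≈ 0.5–0.6;
2. an *isolated mass* sits just below the oscillation (Hopf) threshold:
   it shows a genuine alpha-band spectral resonance but, lacking network
   drive, its integrated lower-alpha fraction is only ≈ 0.15–0.2 — this
   **is** the collapsed end state of the degeneration arm, matching the
   post-collapse power level rather than the healthy one (the two
   requirements cannot both be met by one operating point; we prioritise
   the collapse level, which is the quantitative anchor);
3. a moderate threshold change (|ΔV_d| ≤ 2 mV) shifts pulse densities by
   a factor ≈ e^{rΔV} ≈ 2–4, not into hard saturation, so the printed
   intervention settings behave as *interventions*, not as lesions, and
   thresholds outside 4–10 mV produce non-functional states.

The steepness r is the load-bearing choice in (3): a steep sigmoid makes
the oscillator easier to tune but turns V_d1 = 5 into instant
saturation.  r = 0.7 mV⁻¹ with the gain recovered through C2 keeps both.

The conduction delay T = 40 ms is a lumped phenomenological delay.  It
is deliberately larger than single-pathway conduction times: in this
filter family, network-level phase-lagged synchronization at ~9 Hz
requires roughly this loop phase, and the lags it induces are what the
PLI (blind to zero-lag sync) can see.

### Coupling gain across network sizes

The dynamical operating point is set by the typical summed coupling
input per mass, `g·⟨degree⟩·E`.  The synthetic-connectome generator
therefore auto-calibrates `g = 43.2 / ⟨degree⟩` so that down-scaled
test networks (e.g. 20 nodes) sit at the same operating point as the
78-node default.  A user-supplied matrix gets an explicit `g`.

## Degeneration

After every cycle each weight decays multiplicatively,
`W_ij ← W_ij (1 − λ L(s_ij))`, `L(s) = e^{k (s − s_ref)}`, with `s_ij`
the mean excitatory spike density of the endpoints (a `source` mode
applies each endpoint's loss separately; both preserve symmetry).
Defaults λ = 0.03, k = 0.5 s, s_ref = 1.45 s⁻¹, w_floor = 0: every edge
decays by ≈ 3 %/cycle near the reference density, more where activity is
higher.  Consequences at default calibration (78 nodes):

- functional breakdown (power and PLI dropping below control) at cycles
  ≈ 8–14, i.e. the therapy start at cycle 11 falls inside the
  transition; the relative lower-alpha level then creeps down to
  ≈ 0.19–0.21 by cycle 40 and the peak frequency slows from 9.2 toward
  7.5 Hz;
- hub vulnerability emerges without being built in: hubs aggregate more
  input, fire more, and lose proportionally more strength, so the slope
  of normalized node strength vs original degree is negative.

`ADDParams.intra_fraction` (default 0) additionally erodes each node's
intra-mass excitatory→inhibitory synapses at `intra_fraction` times the
long-range rate.  This reconstructs the "all excitatory synapses
degenerate" reading of the mechanism: it produces disinhibition-driven
hyperactivity (mean spike density rising ~35 % before decline), deeper
collapse (relative alpha ≈ 0.12) and stronger slowing (peak ≈ 5 Hz).
It is off by default because destroying the local oscillator also
suppresses the response to excitability interventions, which is the
phenomenon the trial machinery exists to measure.

## Interventions

Strategies set `V_d1/V_d2` of every node, uniformly and permanently,
from `start_cycle` (default 11, i.e. after ten untreated cycles; cycles
are 1-based).  Built-ins: global stimulation (6, 6), global inhibition
(8, 8), stimulation of excitatory neurons (5, 7), stimulation of
inhibitory neurons (7, 5), inhibition of excitatory neurons (8, 7),
inhibition of inhibitory neurons (7, 6.5); `control` (degeneration off)
and `no_intervention` (degeneration on) complete the grid.  Values
outside 4–10 mV are refused without an explicit override.  In this
calibration, stimulation of excitatory neurons raises pulse density
~2-fold, which compensates the decaying weights in the coupling drive
`g·W·E` and visibly rescues power and PLI for several cycles after
therapy start — at the cost of faster structural decay (higher `L(s)`),
the same trade-off the in-silico trial is meant to expose.

## Outcome measures

- **Spectral**: Welch periodograms (1 s Hann segments, 50 % overlap,
  4× zero-padding → 0.25 Hz grid, constant detrend) of each node's
  excitatory membrane potential.  Relative power = band(8–10) /
  band(0.5–30); peak frequency = argmax in 1–30 Hz.  Note the Hann main
  lobe (±2 Hz at 1 s segments) leaves a few percent of even an on-band
  line outside 8–10 Hz; tests use estimator-realistic tolerances.
- **PLI**: phases from the analytic signal of the 4–13 Hz band-passed
  trace (4th-order Butterworth, zero-phase), 10 % of samples trimmed at
  each edge; `PLI = |mean(sign(sin Δφ))|` per pair, averaged over the
  upper triangle for the global value.  Exact zeros of `sin Δφ` count in
  the denominator.
- **Topology**, all on the full weighted PLI matrix (no thresholding):
  geometric-mean weighted clustering (weights rescaled by the maximum),
  normalized by the mean over 20–50 edge-weight-permutation surrogates
  (γ); Newman modularity of the best of 10 seeded Louvain restarts;
  algebraic connectivity λ₂ of `D − W`; leaf number of the maximum-weight
  spanning tree (Kruskal, ties broken toward smaller node indices),
  raw and as a fraction of n − 1.
- **Structure**: normalized node strength = current / original summed
  incident weight (NaN for originally isolated nodes).

## Statistics and scores

Ten runs per condition by default (tests and examples use fewer; the
methods are identical).  Run *r* of every condition draws its noise from
the same seed (common random numbers, switchable), so conditions are
coupled and identical until dynamics diverge.  Per cycle and measure a
two-tailed two-sample t-test (equal variances, α = 0.05, no
multiple-testing correction) compares condition runs to control runs; a
measure is **normal** when not significantly *lower* than control (zero
variance in both groups falls back to comparing means).  The
performance score of a category (oscillatory: relative alpha + peak
frequency; connectivity: PLI; topology: γ, Q, λ₂, leaf number) counts
normal cycles from the intervention start onward, summed over the
category's measures, divided by the no-intervention count; a zero
denominator reports infinity.

## What the synthetic data does and does not show

The synthetic connectome reproduces the gross character of a cortical
DTI network — 78 regions, ~0.13 density, six planted modules, eight
hubs, identical initial edge strengths — but not its exact degree
sequence, geometry or inter-individual variability; quantitative cycle
counts (e.g. breakdown near cycle 10 rather than 20) are calibration-
and topology-dependent and should be read as ordinal, not literal.
Virtual time has no defined mapping to real time.  Reduced-scale runs
(20 nodes, 2–3 runs) used in the test suite sit at the same operating
point by gain scaling but are more synchronized (denser graphs), so
their control levels differ slightly from the 78-node ones.

## Known limitations

- **No pre-collapse hypersynchronization.**  In this calibration the
  untreated arm's global PLI declines from the first damaged cycle;
  the transiently *elevated* functional connectivity reported for
  activity-dependent degeneration is not reproduced.  Three mechanisms
  were explored: pure edge loss (damage only ever lowers the coupling
  drive, hence sync), hub-saturation relief at high gain (the
  synchronized network state is barely degraded by saturation, leaving
  no headroom), and disinhibition via `intra_fraction` (raises activity
  but weakens the local oscillator faster than it boosts coupling).
  The corresponding acceptance test is left failing by design rather
  than weakened.
- **No functional modularity in the healthy state.**  The healthy
  network synchronizes globally: within- and between-module PLI are
  equal, so functional-network modularity is ≈ 0.01–0.04 in control
  while a collapsed (noise) PLI matrix scores a spurious ≈ 0.07.
  Normalized clustering, algebraic connectivity and leaf number all
  decline with degeneration as expected; the modularity-decline test is
  likewise left failing with this analysis.
- Masses are homogeneous (identical parameters except connectivity and
  per-node thresholds); no plasticity or repair; spatial effects beyond
  the single uniform delay are ignored; interventions are global and
  continuous only (region-selective or adaptive schemes can be built
  through the custom-strategy hook).

## Numerical notes

Fixed-step Heun integration at dt = 1 ms (stable for rate constants up
to ~200 s⁻¹; divergence is detected and reported with the offending node
and step).  The delay is a ring buffer of past spike densities,
pre-filled with the initial state's value; the initial potential is set
at the excitatory threshold so the network starts on its active branch,
and each cycle discards a 0.5 s transient.  Carrying states and one RNG
across cycles is sample-exact equivalent to one long run.  The inner
loop is numba-compiled; all randomness flows through
`numpy.random.Generator` seeded per (trial, run), making every result
bit-reproducible for a given seed.
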