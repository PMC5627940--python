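# vtrial — virtual intervention trials on degenerating brain networks

`vtrial` simulates "virtual clinical trials" on a brain-like network of
coupled alpha-rhythm neural masses.  The network is progressively damaged
by **activity-dependent degeneration** (ADD) — synaptic coupling weakens
faster where excitatory firing is higher, the regime thought to drive
Alzheimer-like network breakdown — while **excitability interventions**
(raising or lowering the spike-threshold potential of excitatory and/or
inhibitory populations, globally and continuously) try to keep the
network functioning.  It is aimed at computational neuroscientists who
want a desk-scale, fully reproducible test ground for such intervention
hypotheses.

## The model

Each of *N* cortical regions is a lumped neural mass: an excitatory and
an inhibitory population with average membrane potentials *Vₑ, Vᵢ* and
pulse densities *E, I*.  Potentials convert to pulse densities through a
logistic sigmoid with threshold *V_d*,

&nbsp;&nbsp;&nbsp;&nbsp;S(V) = q / (1 + exp(r·(V_d − V))),

and pulse densities convert back to potentials through critically damped
second-order synaptic filters with kernels A·a·t·e^(−a·t) (excitatory)
and B·b·t·e^(−b·t) (inhibitory).  The excitatory population receives
truncated-Gaussian thalamic input P(t) and delayed excitatory input
g·Σⱼ W[i,j]·Eⱼ(t − T) from connected regions; the inhibitory population
is driven by the local excitatory one.  With the default parameters a
coupled network oscillates at ~9 Hz; an isolated mass sits just below
the oscillation threshold.

After every cycle of virtual time, ADD erodes each coupling weight:

&nbsp;&nbsp;&nbsp;&nbsp;W[i,j] ← max(w_floor, W[i,j]·(1 − λ·exp(k·(s_ij − s_ref)))),

where s_ij is the mean excitatory spike density of the edge's endpoints —
every edge is damaged, but low-activity edges exponentially less.

Network health is tracked per cycle by: relative spectral power in the
lower alpha band (8–10 Hz) and peak frequency; global mean **Phase Lag
Index** (PLI = |⟨sign sin Δφ(t)⟩|, insensitive to zero-lag coupling);
and four weighted-graph measures of the PLI network (normalized
clustering γ, modularity Q, algebraic connectivity λ₂, and the leaf
number of the maximum spanning tree).  Each intervention arm is compared
cycle-by-cycle to a healthy control with two-tailed t-tests over runs; a
measure is "normal" while not significantly lower than control, and each
metric category gets a **performance ratio** = (condition's normal-cycle
count) / (no-intervention's normal-cycle count).

The 78-region cortical connectome the reference topology is based on is
not redistributable, so the package ships a synthetic generator for
sparse, modular, hub-bearing binary graphs of any size (plus a CSV/TSV
loader for your own matrix).

## Worked example

```python
import vtrial as vt

conn = vt.generate_synthetic_connectome(n_nodes=20, n_modules=4,
                                        hub_count=3, seed=3)
trial = vt.VirtualTrial(conn, n_runs=3, n_cycles=25, base_seed=42,
                        n_surrogates=10)
res = trial.fit(strategies=["stim_excitatory", "global_inhib"])
print(res.summary())
```

prints

```
Virtual trial summary
============================================================
runs: 3, cycles: 25, base seed: 42

Performance ratios vs no intervention (> 1 means longer normal function):
category         connectivity  oscillatory  topology
condition
global_inhib              inf          inf     1.000
stim_excitatory           inf          inf     1.367

network means over the final cycle (25):
metric           algebraic_connectivity  gamma  leaf_number  modularity  peak_freq    pli  rel_alpha
condition
control                          11.531  1.002       16.333       0.001      9.246  0.850      0.870
global_inhib                      2.037  0.999       10.000       0.083      6.883  0.149      0.163
no_intervention                   2.062  0.999        9.667       0.089      7.962  0.158      0.254
stim_excitatory                   2.374  1.012       10.000       0.101      8.917  0.216      0.543
```

Reading it: the healthy control keeps ~0.87 of its spectral power in the
lower alpha band with high synchrony (PLI 0.85), while the untreated
degeneration arm has collapsed (relative alpha 0.25, PLI 0.16, algebraic
connectivity down from 11.5 to 2.1).  Stimulating excitatory neurons
(threshold lowered to V_d1 = 5 mV from cycle 11) keeps spectral power at
0.54 and topology healthy for longer (ratio 1.37).  An `inf` ratio means
the no-intervention arm had *zero* normal cycles in that category after
therapy start, while the intervention still had some.
`res.metrics` holds the tidy per-run/per-cycle table, `res.comparisons`
the t-tests, and `res.plot_trajectories("pli")` the familiar
mean ± sd trajectory plot.

The same trials run from the shell:

```bash
vtrial run --strategy stim_excitatory --runs 10 --cycles 50 --out results/
vtrial sweep --family global_stim --values 4,4.5,5,5.5,6,6.5
vtrial timing --strategy stim_excitatory --starts 0,10,20
```

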