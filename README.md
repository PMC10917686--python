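# engramsim

A spiking-network model of hippocampal memory engrams: how a memory
is encoded by a set of highly active neurons, how its cellular
composition turns over during consolidation, and why the memory
becomes *selective* — recallable by cues of the learned stimulus but
not of similar novel ones — only after consolidation.

The model is a conductance-based leaky integrate-and-fire network
(stimulus population → recurrent excitatory/inhibitory hippocampal
network) with four interacting plasticity systems:

* short-term depression/facilitation (per presynaptic neuron),
* long-term excitatory plasticity: triplet STDP
  (`Δw = η·A·z⁺_j·z_slow_i` per post-spike, `−η·B_i·z⁻_i` per
  pre-spike with a homeostatically regulated LTD rate
  `B_i = A·min(C_i, 1)`), heterosynaptic decay
  `−β (w−w̃)(z⁻_i)³` toward a slowly consolidating reference weight
  `w̃` (double-well dynamics), and a transmitter-induced increment
  `+δ` per pre-spike,
* reference-weight consolidation on a bistable double-well landscape,
* inhibitory STDP gated by a global activity factor `G = H − γ`
  (depression-only below the network's activity target, Hebbian
  above it).

The protocol drives the network through burn-in, training (a square
pattern on the input grid), and a consolidation phase with stochastic
replay of the training stimulus; at sampled consolidation times,
offline probing and recall branches identify the current engram
(rate threshold 10 Hz, or rank-1 NMF of binned spike counts) and
measure recall of half-pattern cues of the training square and of
three novel shapes (circle, pentagon, hexagon, with decreasing
overlap).  Memory selectivity is the discrimination index
`(recall_train − recall_novel)/(recall_train + recall_novel)`.

A companion imaging layer identifies engram cells in longitudinal
ΔF/F recordings (threshold on a per-cell home-vs-training
discrimination index, or rank-1 NMF of a home-cage-normalized ΔF/F
matrix) and ships a synthetic generator for the eight-session
longitudinal design.

## Worked example

```python
from engramsim.experiments import run_experiment

run = run_experiment(seed=101)          # desk preset, ~1 min on 1 CPU
tl = run.timeline()
print("training-activated engram cells:", len(run.record.training_engram))
print("overlap with training engram per probe:",
      [round(v, 2) for v in tl.overlap_with_training("setA")])
t = tl.sample_times[-1]
print("final recall:", {s: round(v, 2) for s, v in tl.recall[t].items()})
print("final discrimination:",
      {s: round(v, 2) for s, v in tl.discrimination[t].items()})
```

prints (seed 101):

```
training-activated engram cells: 70
overlap with training engram per probe: [0.9, 0.64, 0.64, 0.64]
final recall: {'square': 1.0, 'circle': 1.0, 'pentagon': 0.0, 'hexagon': 0.0, 'artificial_reactivation': 1.0}
final discrimination: {'circle': 0.0, 'pentagon': 1.0, 'hexagon': 1.0}
```

Right after training the engram recalls from *any* of the four cues
(unselective memory).  Over consolidation, about a third of the
training-activated cells drop out of the engram (overlap 0.9 → 0.64)
while consecutive probing ensembles stay strongly overlapping, and
the lower-overlap novel cues (pentagon, hexagon) stop activating the
engram — discrimination becomes positive — while the training cue
keeps recalling perfectly.  The highest-overlap novel stimulus
(circle) remains hardest to discriminate, and the cue-free session in
which the training-activated cells are driven directly
(`artificial_reactivation`) recalls in every interval.

The same pipeline is scriptable from the shell:

```
engramsim run --preset desk --seed 1 --out out/
engramsim analyze --record out/record.h5 --out analysis/
engramsim report --analysis analysis/ --out report/
```

Manipulations mirror the optogenetic/chemogenetic experiments, e.g.
`--manipulation block_neurons:recall:inh` (silence all interneurons
during recall) or `--manipulation block_inhibitory_plasticity:consolidation`.

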