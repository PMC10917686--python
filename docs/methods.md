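# Model and methods

`engramsim` simulates the formation, consolidation and recall of a
hippocampal memory engram in a recurrent spiking network, and provides
the analysis layer that identifies engram cells and quantifies memory
selectivity — in simulation (spike rasters) and in longitudinal
calcium-imaging data (ΔF/F traces).

## Network model

A stimulus population of `N_stim` Poisson units, laid out on a square
grid, projects to a recurrent network of `N_exc` excitatory and
`N_inh` inhibitory leaky integrate-and-fire neurons.  The membrane of
neuron *i* follows

    tau_m dU_i/dt = (U_rest − U_i) + g_exc,i (U_exc − U_i)
                    + (g_gaba,i + g_a,i)(U_inh − U_i)

with conductance-based synapses: GABA and spike-triggered adaptation
conductances decay exponentially and jump on (pre- or own) spikes;
the excitatory conductance is a mixture `alpha·g_ampa +
(1−alpha)·g_nmda`, where the AMPA conductance jumps on presynaptic
spikes by `w_ij · u_j x_j` (the short-term-plasticity release factor)
and the NMDA conductance low-pass filters it.  A spike fires when `U`
strictly exceeds an adaptive threshold, which then jumps to
`theta_spike` and relaxes (relative refractoriness); `U` resets to
rest.  Integration is forward Euler at `dt = 0.1 ms` with a one-step
synaptic delay.

Connectivity: recurrent projections are i.i.d. Bernoulli(`eps_rec`)
without self-connections, with uniformly jittered initial weights;
each excitatory neuron receives feedforward input from the stimulus
units inside a circular receptive field of radius `R_hpc` around a
uniformly random grid centre (plane geometry — stimuli live on a
bounded canvas, so no wrap-around).

## Plasticity

Four systems act simultaneously (all can be blocked per phase):

* **Short-term plasticity** per presynaptic excitatory neuron
  (depression `x`, facilitation `u`, release probability `U_stp`),
  shared across that neuron's efferent synapses.
* **Long-term excitatory plasticity** on stim→E and E→E synapses:
  triplet STDP — potentiation `eta·A·z+_j·z_slow_i` per postsynaptic
  spike, depression `eta·B_i·z−_i` per presynaptic spike, where the
  LTD rate `B_i = A·min(C_i, 1)` is homeostatically regulated by a
  low-passed square of the postsynaptic rate; heterosynaptic decay
  `beta (w − w̃) (z−_i)³` per postsynaptic spike toward a reference
  weight; and a transmitter-induced increment `delta` per presynaptic
  spike that keeps silent inputs from dying.  Traces obey the
  "epsilon" convention: an update triggered by a spike reads trace
  values that exclude that spike.
* **Reference-weight consolidation**: `w̃` relaxes toward `w` while
  descending a double-well potential (midpoint `w_P = 0.5`,
  magnitude `P`), updated on a slow tick `dt_long = 1.2 s` (0.3 s in
  the desk preset).  This gives synapses a bistable consolidated
  state: at `w_P = 0.5` the wells sit at 0 and near `w ≈ w̃`.
* **Inhibitory STDP** on I→E synapses, gated by a global factor
  `G = H − gamma`, where `H` low-pass filters the total excitatory
  spike count (time constant `tau_H`): per presynaptic spike
  `eta_inh·G·(z_post + 1)`, per postsynaptic spike
  `eta_inh·G·z_pre`.  Below the activity target the rule is
  depression-only; above it, Hebbian.  An alternative
  presynaptic-only variant (`inhibitory_variant = "pre_only"`) keeps
  only the `eta_inh·G` term per presynaptic spike.

E→I synapses carry short-term plasticity only; I→I synapses are
static.  Weights are clipped to configured bounds after every update
(never reached in normal runs).

## Protocol

burn-in → training → consolidation.  The training stimulus (a filled
square covering a quarter of the grid) is presented in random on/off
intervals with exponentially distributed lengths; stimulus units fire
at `nu_stim` during presentations and `nu_bg` otherwise.  During
consolidation the training stimulus is stochastically reactivated
(sleep-like replay).  At every sampled consolidation time the full
state is snapshotted and offline sessions are branched from
independent copies with their own random streams: one probing session
(full training stimulus, used only to identify the current engram)
and four recall sessions (half-pattern cues of the training square
and of three novel shapes — circle, pentagon, hexagon — rasterized
with equal unit counts and placed so their overlap with the square is
ordered circle > pentagon > hexagon).  Branches never perturb the
main trajectory.

Manipulations are declared per phase: blocking neuron sets (output
and all efferent synapses silenced, which also silences
presynaptically gated plasticity), blocking individual plasticity
terms, suppressing consolidation reactivation, forcing engram cells
to fire (artificial reactivation), and blocking one interneuron class
in the two-interneuron-type variant (a configurable fraction of
inhibitory neurons with plastic efferents, the remainder static).

## Engram identification and recall metrics

A neuron is an engram cell if its mean stimulus-evoked rate (over
stimulus-on time) strictly exceeds `zeta_thr = 10 Hz` in the
identification window — the last `dt_eng` of training (training+) or
a whole probing session (probing+; both windows have equal length by
construction).  The population-based variant factorizes the 10 ms
spike-count matrix with rank-1 NMF (seeded, nndsvda initialization;
the single feature is normalized to unit maximum so coefficients are
comparable to the 0.5 threshold) and thresholds the coefficient
vector.

An ensemble is *activated* by a cue presentation if its population
rate exceeds `zeta_thr` during the presentation; *recall* is the
fraction of presentations that activate the ensemble, *recall rate*
the cue-evoked ensemble rate averaged over presentations, and the
*discrimination index* between training- and novel-cue recall is
`(q1 − q2)/(q1 + q2)` (NaN when both vanish; excluded from
averages).  A probing+ cell counts as *reactivated* during recall if
its own session-mean cue-evoked rate exceeds `zeta_thr`.
Uncertainty on all mean metrics uses a 99 % percentile bootstrap.

For imaging data, a cell is an engram cell when the discrimination
index of its mean ΔF/F between training-context and prior home-cage
session exceeds 0.2; the population variant normalizes the
training-context ΔF/F matrix against the home-cage session (subtract
the per-cell home mean, divide by home + training means, shift to
non-negative), then applies rank-1 NMF with membership above the
99 % coefficient quantile.

## Synthetic ΔF/F generator

`imaging.synthesize_dff` emulates the eight-session longitudinal
structure (home cage + training; home/neutral/training after 1 h and
after 24 h) at 20 Hz: cells emit Poisson calcium transients
(exponential decay kernel) at a per-cell baseline event rate, cells
planted as engram members have their training-context rate multiplied
by the effect size (default 3, i.e. a ΔF/F discrimination of ~0.5),
and a configurable fraction of the planted ensemble turns over
between time points.  It reproduces session structure, elevated
training-context activity and trace variability; it does **not**
model motion artefacts, neighbour cross-talk or photobleaching, so
passing recovery tests demonstrates correctness of the identification
pipeline, not robustness to those real-data nuisances.

## Presets and numerical choices

`paper_scale` carries the published geometry (4096 stimulus units on
a 64×64 grid, 4096 excitatory, 1024 inhibitory neurons; 300 s
training; 24 h consolidation sampled hourly).  Constants that the
available text does not specify numerically (membrane/synaptic time
constants, reversal potentials, rates, learning rates) carry
documented defaults from the standard conductance-based LIF
literature; every one is configurable.

`desk` is the reduced preset used by the test suite and the
acceptance script: 256/256/64 neurons on a 16×16 grid, 20 s training,
1200 s consolidation sampled every 400 s, 30 s probing/recall
sessions, with unitary weights raised to compensate the small
in-degrees and slow constants compressed (tau_cons = 600 s,
tau_hom = 60 s, dt_long = 0.3 s).  Two desk choices deserve note:

* *Training is short relative to consolidation.*  The inhibitory
  homeostat moves little during the 20 s encoding phase (the fresh
  memory is permissive: every partial cue, including the
  lowest-overlap hexagon, completes to the engram — discrimination
  starts near zero) and then tightens over the 1200 s replay phase
  toward the activity target `gamma` (1.25 Hz population rate), which
  progressively raises the completion threshold so low-overlap cues
  fail first.  Feedforward specialization (LTD prunes non-square
  inputs onto engram cells while square inputs are sustained by
  replay) separates the cue drives that the rising threshold then
  discriminates.
* *Plasticity is frozen inside probing/recall branches.*  Branches
  are discarded copies; at compressed timescales a 30 s session at
  desk learning rates would substantially retrain the network it is
  measuring, which is purely an artifact of time compression (at
  paper scale, 60 s of learning is negligible against 24 h).
  `paper_scale` keeps plasticity on everywhere.

Numerical details: forward Euler throughout; trace decays as
`(1 − dt/tau)` per step (the event-driven test oracles reproduce this
factor in closed form, so agreement is to 1e-9 and better); strict
`>` spike and threshold comparisons; weight clipping after each
update; stimulus Poisson spikes drawn as per-rate-class Binomial
counts with uniform member assignment (jointly identical to
independent Bernoulli draws); per-phase/branch/purpose random streams
derived from the master seed via `SeedSequence`, so branching cannot
reorder main-trajectory draws; all-zero activity matrices yield an
empty engram with a warning; undefined discriminations propagate as
NaN.

## Validation scope and known limitations

The test suite checks, on the desk preset: necessity and sufficiency
of training-activated cells (blocking them abolishes cued recall;
forcing them at the stimulus rate yields full recall without cues),
engram turnover with stable hour-to-hour overlap, the emergence of
selectivity with consolidation and its ablations (blocking inhibition
during recall, inhibitory plasticity during consolidation, or LTP
during consolidation), the alternative inhibitory rule, homeostatic
rate control (probed in a strongly driven configuration with a raised
inhibitory learning rate, where the loop has enough authority to
settle within a 200 s run), and the statistical layer against
independent oracles.  Protocol-level tests use 5 control and 3
ablation seeds; the acceptance script replays the headline numbers at
10 trials.

Known desk-scale deviations: the fraction of probing+ cells
reactivated by the half cue runs high (~0.75–0.9 versus ~0.5 at full
scale) because the receptive-field radius spans a quarter of the
8-row training square (the half cue directly drives most engram
receptive fields) and because the homeostatic sweep prunes the
probing+ ensemble toward strongly driven cells; and the
highest-overlap novel stimulus (circle, 0.69 overlap) often recalls
at ceiling throughout, so its discrimination increase can be ~0 while
pentagon and hexagon show the increase robustly.  Both are
scale-reduction effects, not properties of the rules.
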