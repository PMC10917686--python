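"""Model parameters.

Single source of truth for every constant of the neuron, synapse,
plasticity, network, protocol and analysis layers.  All times are in
seconds, rates in Hz, voltages in mV, conductances dimensionless
(scaled by the reversal-potential driving force).

Two presets are shipped:

``paper_scale``
    The published network geometry (4096 stimulus, 4096 excitatory and
    1024 inhibitory neurons on a 64x64 stimulus grid) with a 24 h
    consolidation phase.  Kinetic constants not printed in the source
    text carry documented defaults chosen from the standard
    conductance-based LIF literature; every one is configurable.

``desk``
    A reduced network (256/256/64 on a 16x16 grid) with a compressed
    consolidation phase (minutes instead of hours) and proportionally
    raised learning rates, intended for laptop-scale experimentation
    and for the test suite.  All qualitative behaviours of the model
    (engram formation, turnover, emergence of selectivity) are
    preserved at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

__all__ = [
    "NeuronParams",
    "PlasticityParams",
    "NetworkParams",
    "ProtocolParams",
    "AnalysisParams",
    "ModelParams",
    "desk",
    "paper_scale",
    "PRESETS",
]


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire neuron with adaptive threshold.

    The membrane relaxes to ``U_rest`` and is pushed toward ``U_exc``
    by the excitatory conductance and toward ``U_inh`` by the GABA and
    adaptation conductances.  A spike fires when the voltage strictly
    exceeds the moving threshold; the voltage then resets to ``U_rest``
    and the threshold jumps to ``theta_spike``, decaying back to
    ``theta_rest`` with ``tau_thr`` (relative refractoriness).
    """

    tau_m: float = 20e-3          # membrane time constant (s)
    U_rest: float = -70.0         # resting potential (mV)
    U_exc: float = 0.0            # excitatory reversal potential (mV)
    U_inh: float = -80.0          # inhibitory reversal potential (mV)
    theta_rest: float = -50.0     # resting firing threshold (mV)
    theta_spike: float = 0.0      # post-spike threshold (mV)
    tau_thr: float = 5e-3         # threshold decay constant (s)
    tau_gaba: float = 10e-3       # GABA conductance decay (s)
    tau_a: float = 100e-3         # adaptation conductance decay (s)
    tau_ampa: float = 5e-3        # AMPA conductance decay (s)
    tau_nmda: float = 100e-3      # NMDA low-pass constant (s)
    Delta_a: float = 0.1          # adaptation increment per spike (cond. units)
    alpha: float = 0.5            # AMPA weight in the AMPA/NMDA mixture
    dt: float = 1e-4              # integration step (s); 0.1 ms

    def validate(self) -> None:
        for name in ("tau_m", "tau_thr", "tau_gaba", "tau_a", "tau_ampa",
                     "tau_nmda", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"NeuronParams.{name} must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("NeuronParams.alpha must lie in [0, 1]")
        if not self.theta_spike > self.theta_rest:
            raise ValueError("theta_spike must exceed theta_rest")
        if not (self.U_inh <= self.U_rest < self.theta_rest < self.U_exc):
            raise ValueError(
                "potentials must satisfy U_inh <= U_rest < theta_rest < U_exc")


@dataclass
class PlasticityParams:
    """Constants of the four plasticity systems.

    * Short-term plasticity (per presynaptic excitatory neuron):
      depression/facilitation with initial release probability
      ``U_stp``.
    * Long-term excitatory plasticity: triplet STDP (rate ``A``,
      homeostatically regulated LTD rate ``B``), heterosynaptic decay
      toward a consolidating reference weight (strength ``beta``), and
      a transmitter-induced increment ``delta`` per presynaptic spike.
    * Reference weights follow the negative gradient of a double well
      (magnitude ``P``, midpoint ``w_P``) with constant ``tau_cons``,
      updated every ``dt_long`` for efficiency.
    * Inhibitory STDP scaled by the global factor G = H - gamma, where
      H low-pass filters the excitatory population spike count.
    """

    # short-term plasticity
    tau_d: float = 200e-3         # depression recovery (s)
    tau_f: float = 600e-3         # facilitation decay (s)
    U_stp: float = 0.2            # initial release probability

    # long-term excitatory plasticity
    eta_exc: float = 1.0          # excitatory learning-rate multiplier
    A: float = 1e-3               # LTP rate (triplet)
    beta: float = 5e-2            # heterosynaptic strength
    delta: float = 2e-5           # transmitter-induced increment
    tau_plus: float = 20e-3       # presynaptic trace (s)
    tau_minus: float = 20e-3      # fast postsynaptic trace (s)
    tau_slow: float = 100e-3      # slow postsynaptic trace (s)

    # reference-weight consolidation
    tau_cons: float = 1200.0      # consolidation time constant (s)
    P: float = 20.0               # double-well magnitude
    w_P: float = 0.5              # double-well midpoint
    dt_long: float = 1.2          # reference-weight update period (s)

    # homeostatic LTD-rate regulation
    tau_hom: float = 1200.0       # C_i relaxation (s)
    tau_ht: float = 100e-3        # z_ht trace (s)

    # inhibitory plasticity
    eta_inh: float = 1e-4         # inhibitory learning rate
    gamma: float = 163840.0       # target of H (spikes filtered over tau_H)
    tau_H: float = 10.0           # global-factor filter (s)
    tau_istdp: float = 20e-3      # inhibitory pre/post trace (s)
    inhibitory_variant: str = "full"   # "full" (Hebbian + pre) or "pre_only"

    # weight bounds
    w_exc_min: float = 0.0
    w_exc_max: float = 5.0
    w_inh_min: float = 0.0
    w_inh_max: float = 5.0

    def validate(self) -> None:
        for name in ("tau_d", "tau_f", "tau_plus", "tau_minus", "tau_slow",
                     "tau_cons", "tau_hom", "tau_ht", "tau_H", "tau_istdp",
                     "dt_long"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PlasticityParams.{name} must be > 0")
        if not 0.0 < self.U_stp <= 1.0:
            raise ValueError("U_stp must lie in (0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.w_exc_min >= self.w_exc_max:
            raise ValueError("w_exc_min must be < w_exc_max")
        if self.w_inh_min >= self.w_inh_max:
            raise ValueError("w_inh_min must be < w_inh_max")
        if self.inhibitory_variant not in ("full", "pre_only"):
            raise ValueError("inhibitory_variant must be 'full' or 'pre_only'")

    def target_rate(self, n_exc: int) -> float:
        """Per-neuron excitatory rate implied by gamma (Hz).

        At steady state H ~= n_exc * rate * tau_H, so the homeostatic
        set point of the mean excitatory rate is gamma / (n_exc tau_H).
        """
        return self.gamma / (n_exc * self.tau_H)


@dataclass
class NetworkParams:
    """Population sizes, connectivity and initial weights.

    Synapse classes and their plasticity:

    =========  =======================================
    stim->E    short-term + long-term excitatory
    E->E       short-term + long-term excitatory
    E->I       short-term only
    I->E       inhibitory STDP
    I->I       static
    =========  =======================================
    """

    N_stim: int = 4096
    N_exc: int = 4096
    N_inh: int = 1024
    grid_side: int = 64           # stimulus grid is grid_side x grid_side
    eps_rec: float = 0.1          # recurrent connection probability
    R_hpc: float = 8.0            # receptive-field radius (grid units)
    w_EE: float = 0.1             # initial E->E weight
    w_EI: float = 0.3             # initial E->I weight
    w_II: float = 0.3             # initial I->I weight
    w_IE: float = 0.3             # initial I->E weight
    w_stim: float = 0.4           # initial feedforward weight
    init_uniform_jitter: float = 1.0   # recurrent init ~ U(0, 2*jitter*w)?? see build
    wtilde_init_equal: bool = True     # w~ starts equal to w (else 0)
    # optional two-interneuron-type variant: fraction of inhibitory
    # neurons with plastic efferent synapses (CCK-like); the remainder
    # have static efferents (PV-like).  None -> single homogeneous
    # plastic population.
    interneuron_split: Optional[float] = None

    def validate(self) -> None:
        for name in ("N_stim", "N_exc", "N_inh", "grid_side"):
            if getattr(self, name) <= 0:
                raise ValueError(f"NetworkParams.{name} must be > 0")
        if self.N_stim != self.grid_side ** 2:
            raise ValueError("N_stim must equal grid_side**2")
        if not 0.0 < self.eps_rec <= 1.0:
            raise ValueError("eps_rec must lie in (0, 1]")
        if self.R_hpc > self.grid_side / 2:
            raise ValueError("R_hpc may not exceed half the grid side")
        if self.interneuron_split is not None and not (
                0.0 <= self.interneuron_split <= 1.0):
            raise ValueError("interneuron_split must lie in [0, 1]")
        for name in ("w_EE", "w_EI", "w_II", "w_IE", "w_stim"):
            if getattr(self, name) < 0:
                raise ValueError(f"NetworkParams.{name} must be >= 0")


@dataclass
class ProtocolParams:
    """Phase schedule of a full simulation.

    burn-in -> training -> consolidation; at every sampled consolidation
    time point the state is snapshotted and offline probing/recall
    sessions are branched from the snapshot.  Stimulus-off and -on
    interval lengths are exponentially distributed within each phase.
    """

    T_burn: float = 30.0
    T_training: float = 300.0
    T_consolidation: float = 86400.0   # 24 h
    T_probing: float = 60.0
    T_recall: float = 60.0
    sample_every: float = 3600.0       # consolidation sampling grid (s)
    # (off, on) exponential means per phase (s)
    train_off_mean: float = 3.0
    train_on_mean: float = 2.0
    cons_off_mean: float = 60.0
    cons_on_mean: float = 2.0
    probe_off_mean: float = 2.0
    probe_on_mean: float = 2.0
    recall_off_mean: float = 2.0
    recall_on_mean: float = 2.0
    nu_bg: float = 5.0                 # stimulus background rate (Hz)
    nu_stim: float = 35.0              # stimulus-on rate (Hz)
    nu_reactivation: float = 35.0      # forced rate for artificial reactivation
    cue_fraction: float = 0.5
    # Freeze plasticity inside probing/recall branches.  Branches are
    # discarded, so at full scale this is immaterial (60 s of learning
    # at 24 h-calibrated rates moves nothing); presets with compressed
    # time and raised learning rates set this so that measurement
    # sessions do not retrain the network they are measuring.
    freeze_branch_plasticity: bool = False

    def validate(self) -> None:
        for name in ("T_burn", "T_training", "T_probing", "T_recall",
                     "sample_every", "train_off_mean", "train_on_mean",
                     "cons_off_mean", "cons_on_mean", "probe_off_mean",
                     "probe_on_mean", "recall_off_mean", "recall_on_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ProtocolParams.{name} must be > 0")
        if self.T_consolidation < 0:
            raise ValueError("T_consolidation must be >= 0")
        if not 0.0 < self.cue_fraction <= 1.0:
            raise ValueError("cue_fraction must lie in (0, 1]")
        for name in ("nu_bg", "nu_stim", "nu_reactivation"):
            if getattr(self, name) < 0:
                raise ValueError(f"ProtocolParams.{name} must be >= 0")


@dataclass
class AnalysisParams:
    """Engram-identification and recall-metric constants."""

    zeta_thr: float = 10.0        # engram activation threshold (Hz)
    dt_eng: float = 60.0          # training-phase identification window (s)
    nmf_bin: float = 10e-3        # spike-count bin for NMF (s)
    zeta_nmf: float = 0.5         # NMF coefficient threshold
    zeta_disc: float = 0.2        # dF/F discrimination threshold
    nmf_quantile: float = 0.99    # imaging-NMF membership quantile
    bootstrap_level: float = 0.99
    bootstrap_reps: int = 1000
    rate_bin: float = 10e-3       # population-rate resolution (s)

    def validate(self) -> None:
        for name in ("zeta_thr", "dt_eng", "nmf_bin", "zeta_nmf",
                     "zeta_disc", "rate_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"AnalysisParams.{name} must be > 0")
        if not 0.0 < self.nmf_quantile < 1.0:
            raise ValueError("nmf_quantile must lie in (0, 1)")
        if not 0.0 < self.bootstrap_level < 1.0:
            raise ValueError("bootstrap_level must lie in (0, 1)")


@dataclass
class ModelParams:
    """Bundle of all parameter blocks."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    preset: str = "paper_scale"

    def validate(self) -> "ModelParams":
        self.neuron.validate()
        self.plasticity.validate()
        self.network.validate()
        self.protocol.validate()
        self.analysis.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            neuron=NeuronParams(**d.get("neuron", {})),
            plasticity=PlasticityParams(**d.get("plasticity", {})),
            network=NetworkParams(**d.get("network", {})),
            protocol=ProtocolParams(**d.get("protocol", {})),
            analysis=AnalysisParams(**d.get("analysis", {})),
            preset=d.get("preset", "custom"),
        )


def paper_scale() -> ModelParams:
    """Published network geometry and 24 h consolidation schedule."""
    mp = ModelParams(preset="paper_scale")
    # gamma implies a ~4 Hz population target at this size
    mp.plasticity.gamma = 4.0 * mp.network.N_exc * mp.plasticity.tau_H
    return mp.validate()


def desk() -> ModelParams:
    """Reduced preset for desk-scale runs and tests.

    256 excitatory / 64 inhibitory neurons driven by a 16x16 stimulus
    grid; consolidation compressed to 10 simulated minutes sampled
    every 5, with learning rates and slow time constants rescaled so
    that engram formation, turnover and the emergence of selectivity
    unfold within the compressed schedule.
    """
    mp = ModelParams(preset="desk")
    n = mp.network
    n.N_stim = 256
    n.N_exc = 256
    n.N_inh = 64
    n.grid_side = 16
    n.eps_rec = 0.2
    n.R_hpc = 2.0
    # few inputs per neuron at this scale -> larger unitary weights
    n.w_stim = 2.8
    n.w_EE = 0.15
    n.w_EI = 1.2
    n.w_IE = 0.1
    n.w_II = 0.5
    p = mp.protocol
    # short, intense encoding followed by a long replay phase: the
    # inhibitory homeostat barely moves during training (permissive,
    # unselective memory) and then tightens over consolidation
    p.T_burn = 10.0
    p.T_training = 20.0
    p.T_consolidation = 1200.0
    p.sample_every = 400.0
    p.T_probing = 30.0
    p.T_recall = 30.0
    p.train_off_mean = 2.0
    p.train_on_mean = 2.0
    p.cons_off_mean = 10.0
    p.cons_on_mean = 2.0
    p.probe_off_mean = 1.5
    p.probe_on_mean = 1.5
    p.recall_off_mean = 2.0
    p.recall_on_mean = 2.0
    p.nu_stim = 60.0
    p.nu_reactivation = 60.0
    p.freeze_branch_plasticity = True
    pl = mp.plasticity
    # compressed timescales: slow constants shortened, rates raised
    pl.A = 8e-3
    pl.beta = 0.1
    pl.delta = 3e-5
    pl.tau_cons = 600.0
    pl.tau_hom = 60.0
    pl.dt_long = 0.3
    pl.eta_exc = 1.0
    # G = H - gamma is O(N_exc * tau_H); eta_inh scales it down to
    # per-spike weight changes of ~1e-3
    pl.eta_inh = 1e-6
    pl.tau_H = 2.0
    pl.gamma = 1.25 * n.N_exc * pl.tau_H   # 1.25 Hz population target
    a = mp.analysis
    a.dt_eng = 20.0
    a.bootstrap_reps = 500
    return mp.validate()


PRESETS = {"desk": desk, "paper_scale": paper_scale}
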