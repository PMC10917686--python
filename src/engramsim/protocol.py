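"""Simulation protocol: burn-in, training, consolidation, probing, recall.

A run advances the network through a burn-in under background input, a
training phase in which the training stimulus is presented in random
on/off intervals (exponentially distributed lengths), and a
consolidation phase in which the training stimulus is stochastically
reactivated (emulating sleep-dependent sensory replay).  At every
sampled consolidation time point the full network state is
snapshotted, and offline sessions are branched from the snapshot:

* one probing session (training stimulus, used only to identify the
  current engram membership), and
* four parallel recall sessions (partial cue of the training stimulus
  and of each of three novel stimuli),

each on an independent copy of the state with its own random stream,
so branches never perturb the main trajectory or each other.

Manipulations (blocking neurons, blocking individual plasticity terms,
suppressing consolidation reactivation, artificial reactivation of
engram cells) are declared per phase and applied inside the affected
phases/branches only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np

from .engine import NetworkState, init_state, run_interval
from .network import Network
from .stimuli import StimulusPattern, make_cue, make_stimulus, stimulus_rates

__all__ = [
    "Manipulation",
    "SessionResult",
    "SimulationRecord",
    "run_protocol",
    "NOVEL_STIMULI",
]

NOVEL_STIMULI = ("circle", "pentagon", "hexagon")

PHASES = ("burn_in", "training", "consolidation", "probing", "recall")

_KINDS = (
    "block_neurons",
    "block_excitatory_ltp",
    "block_hebbian",
    "block_heterosynaptic",
    "block_transmitter",
    "block_inhibitory_plasticity",
    "block_reactivation",
    "artificial_reactivation",
    "block_interneuron_class",
)


@dataclass
class Manipulation:
    """A protocol-level intervention.

    ``kind`` selects the mechanism; ``phases`` the phases it applies
    to.  ``target`` names a neuron set for block_neurons /
    artificial_reactivation: explicit excitatory indices, one of the
    population strings {"exc", "inh", "stim"}, the string
    "training_engram" (resolved to the training-activated engram cells
    after the training phase), or for block_interneuron_class one of
    {"cck", "pv"} (plastic-efferent / static-efferent interneurons).
    """

    kind: str
    phases: Sequence[str] = ("consolidation",)
    target: Union[None, str, Sequence[int]] = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown manipulation kind {self.kind!r}")
        for ph in self.phases:
            if ph not in PHASES:
                raise ValueError(f"unknown phase {ph!r}")


@dataclass
class SessionResult:
    """Recordings of one phase segment or offline branch session."""

    kind: str                     # training_window | probing | recall
    stimulus: str                 # pattern/cue presented
    t_cons: float                 # consolidation time of the branch (s)
    on_time: float                # total stimulus-on time (s)
    counts_on: np.ndarray         # per-exc-neuron spikes during on intervals
    interval_counts: List[np.ndarray] = field(default_factory=list)
    interval_durations: List[float] = field(default_factory=list)
    bins_on: Optional[np.ndarray] = None   # (bins, N_exc) during on intervals
    pop_rate: Optional[np.ndarray] = None  # exc population rate per 10 ms

    def evoked_rates(self) -> np.ndarray:
        """Per-neuron mean stimulus-evoked firing rate (Hz)."""
        if self.on_time <= 0:
            raise ValueError("session has no stimulus-on time")
        return self.counts_on / self.on_time


@dataclass
class SimulationRecord:
    """Everything a protocol run produces."""

    seed: int
    phases: List[dict] = field(default_factory=list)
    intervals: List[dict] = field(default_factory=list)
    training_window: Optional[SessionResult] = None
    sessions: List[SessionResult] = field(default_factory=list)
    weight_snapshots: dict = field(default_factory=dict)
    training_engram: Optional[np.ndarray] = None
    sample_times: List[float] = field(default_factory=list)
    pop_rate_trace: List[np.ndarray] = field(default_factory=list)

    def sessions_at(self, t_cons: float, kind: Optional[str] = None
                    ) -> List[SessionResult]:
        out = [s for s in self.sessions if abs(s.t_cons - t_cons) < 1e-9]
        if kind is not None:
            out = [s for s in out if s.kind == kind]
        return out


def _draw_intervals(rng: np.random.Generator, total: float,
                    off_mean: float, on_mean: float,
                    suppress_on: bool = False) -> List[tuple]:
    """Alternating (duration, on?) schedule filling ``total`` seconds.

    Starts with an off interval; the final interval is truncated at
    the phase end.  With ``suppress_on`` the whole phase is a single
    off interval (reactivation blocked).
    """
    if suppress_on:
        return [(total, False)]
    out = []
    t = 0.0
    on = False
    while t < total:
        mean = on_mean if on else off_mean
        d = float(rng.exponential(mean))
        d = max(d, 1e-3)
        if t + d > total:
            d = total - t
        out.append((d, on))
        t += d
        on = not on
    return out


def _seed_for(master: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master)] + [int(k) for k in key])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _resolve_target(target, record: SimulationRecord, net: Network
                    ) -> np.ndarray:
    n_exc = net.params.network.N_exc
    if isinstance(target, str):
        if target == "training_engram":
            if record.training_engram is None:
                raise ValueError("training engram not identified yet")
            return record.training_engram
        raise ValueError(f"cannot resolve target {target!r} to exc indices")
    return np.asarray(list(target), dtype=np.int64)


class _PhaseContext:
    """Resolved per-phase flags and masks from the manipulation list."""

    def __init__(self, net: Network, manips: Sequence[Manipulation],
                 phase: str, record: SimulationRecord):
        n = net.params.network
        self.plasticity = {"exc": True, "ltp": True, "ltd": True,
                           "het": True, "transmitter": True, "istdp": True}
        self.blocked_stim = np.zeros(n.N_stim, dtype=bool)
        self.blocked_exc = np.zeros(n.N_exc, dtype=bool)
        self.blocked_inh = np.zeros(n.N_inh, dtype=bool)
        self.forced_exc: Optional[np.ndarray] = None
        self.suppress_on = False
        for m in manips:
            if phase not in m.phases:
                continue
            if m.kind == "block_excitatory_ltp":
                self.plasticity["ltp"] = False
            elif m.kind == "block_hebbian":
                self.plasticity["ltp"] = False
                self.plasticity["ltd"] = False
            elif m.kind == "block_heterosynaptic":
                self.plasticity["het"] = False
            elif m.kind == "block_transmitter":
                self.plasticity["transmitter"] = False
            elif m.kind == "block_inhibitory_plasticity":
                self.plasticity["istdp"] = False
            elif m.kind == "block_reactivation":
                if phase != "consolidation":
                    raise ValueError(
                        "block_reactivation applies to consolidation")
                self.suppress_on = True
            elif m.kind == "block_interneuron_class":
                if m.target == "cck":
                    self.blocked_inh |= net.inh_plastic_mask
                elif m.target == "pv":
                    self.blocked_inh |= ~net.inh_plastic_mask
                else:
                    raise ValueError("target must be 'cck' or 'pv'")
            elif m.kind == "block_neurons":
                if m.target == "exc":
                    self.blocked_exc[:] = True
                elif m.target == "inh":
                    self.blocked_inh[:] = True
                elif m.target == "stim":
                    self.blocked_stim[:] = True
                else:
                    idx = _resolve_target(m.target, record, net)
                    self.blocked_exc[idx] = True
            elif m.kind == "artificial_reactivation":
                idx = _resolve_target(m.target, record, net)
                forced = np.zeros(n.N_exc, dtype=bool)
                forced[idx] = True
                self.forced_exc = forced
        if self.forced_exc is not None and np.any(
                self.blocked_exc & self.forced_exc):
            raise ValueError("contradictory manipulations: neurons both "
                             "blocked and artificially reactivated")


def _run_session(net: Network, state: NetworkState, *, kind: str,
                 stimulus: Optional[StimulusPattern], t_cons: float,
                 duration: float, off_mean: float, on_mean: float,
                 ctx: _PhaseContext, master_seed: int, phase_id: int,
                 branch_id: int, record_bins: bool,
                 record: SimulationRecord, log_intervals: bool = False,
                 t_offset: float = 0.0, nu_reactivation: float = 0.0,
                 ) -> SessionResult:
    """Run one on/off-scheduled session on ``state`` (mutating it)."""
    mp = net.params
    pp = mp.protocol
    rng = np.random.default_rng(np.random.SeedSequence(
        [master_seed, phase_id, branch_id, 7]))
    sched = _draw_intervals(rng, duration, off_mean, on_mean,
                            ctx.suppress_on)
    n_exc = mp.network.N_exc
    sess = SessionResult(kind=kind,
                         stimulus=stimulus.name if stimulus else "none",
                         t_cons=t_cons, on_time=0.0,
                         counts_on=np.zeros(n_exc, dtype=np.int64))
    bins_parts = []
    rate_parts = []
    bg = stimulus_rates(None, mp.network.N_stim, pp.nu_bg, pp.nu_stim)
    on_rates = bg if stimulus is None else stimulus_rates(
        stimulus, mp.network.N_stim, pp.nu_bg, pp.nu_stim)
    t = t_offset
    for k, (d, on) in enumerate(sched):
        seed_k = _seed_for(master_seed, phase_id, branch_id, 11, k)
        res = run_interval(
            net, state, d, on_rates if on else bg, seed_k,
            plasticity=ctx.plasticity,
            blocked_stim=ctx.blocked_stim, blocked_exc=ctx.blocked_exc,
            blocked_inh=ctx.blocked_inh,
            forced_exc=ctx.forced_exc if on else None,
            forced_rate=nu_reactivation,
            record_bins=record_bins and on)
        if log_intervals:
            record.intervals.append(
                {"phase": kind, "t0": t, "t1": t + d, "on": on})
        rate_parts.append(res.pop_bins)
        if on:
            sess.on_time += d
            sess.counts_on += res.counts_e
            sess.interval_counts.append(res.counts_e)
            sess.interval_durations.append(d)
            if record_bins and res.bins_e is not None:
                bins_parts.append(res.bins_e)
        t += d
    if bins_parts:
        sess.bins_on = np.concatenate(bins_parts, axis=0)
    bin_s = mp.analysis.rate_bin
    if rate_parts:
        sess.pop_rate = np.concatenate(rate_parts) / (n_exc * bin_s)
    return sess


def run_protocol(net: Network, seed: int,
                 manipulations: Iterable[Manipulation] = (),
                 state: Optional[NetworkState] = None,
                 ) -> SimulationRecord:
    """Execute the full protocol; returns the simulation record.

    Deterministic given (network, seed, manipulations).  Branch
    sessions run on copies of the state under independent random
    streams, so the main trajectory is identical whether or not
    branches exist.
    """
    mp = net.params
    pp = mp.protocol
    ap = mp.analysis
    manips = list(manipulations)
    record = SimulationRecord(seed=int(seed))
    if state is None:
        state = init_state(net)
    training = make_stimulus("square", mp.network.grid_side)

    # ---- burn-in ---------------------------------------------------
    ctx = _PhaseContext(net, manips, "burn_in", record)
    t = 0.0
    record.phases.append({"name": "burn_in", "t0": t, "t1": pp.T_burn})
    bg = stimulus_rates(None, mp.network.N_stim, pp.nu_bg, pp.nu_stim)
    run_interval(net, state, pp.T_burn, bg, _seed_for(seed, 1, 0, 11, 0),
                 plasticity=ctx.plasticity, blocked_stim=ctx.blocked_stim,
                 blocked_exc=ctx.blocked_exc, blocked_inh=ctx.blocked_inh)
    t += pp.T_burn

    # ---- training --------------------------------------------------
    ctx = _PhaseContext(net, manips, "training", record)
    record.phases.append({"name": "training", "t0": t,
                          "t1": t + pp.T_training})
    head = max(0.0, pp.T_training - ap.dt_eng)
    if head > 0:
        # run the portion of training before the identification window
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2, 0, 7]))
        sched = _draw_intervals(rng, pp.T_training, pp.train_off_mean,
                                pp.train_on_mean)
        # split schedule at the window boundary
        pre, post, acc = [], [], 0.0
        for d, on in sched:
            if acc + d <= head:
                pre.append((d, on))
            elif acc >= head:
                post.append((d, on))
            else:
                pre.append((head - acc, on))
                post.append((acc + d - head, on))
            acc += d
        for k, (d, on) in enumerate(pre):
            res = run_interval(
                net, state, d,
                stimulus_rates(training, mp.network.N_stim, pp.nu_bg,
                               pp.nu_stim) if on else bg,
                _seed_for(seed, 2, 0, 11, k),
                plasticity=ctx.plasticity, blocked_stim=ctx.blocked_stim,
                blocked_exc=ctx.blocked_exc, blocked_inh=ctx.blocked_inh)
            record.intervals.append({"phase": "training", "t0": t,
                                     "t1": t + d, "on": on})
            record.pop_rate_trace.append(res.pop_bins)
            t += d
        window_sched = post
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2, 0, 7]))
        window_sched = _draw_intervals(rng, pp.T_training,
                                       pp.train_off_mean, pp.train_on_mean)
    # identification window: last dt_eng of training, binned recording
    sess = SessionResult(kind="training_window", stimulus=training.name,
                         t_cons=-1.0, on_time=0.0,
                         counts_on=np.zeros(mp.network.N_exc,
                                            dtype=np.int64))
    bins_parts = []
    on_rates = stimulus_rates(training, mp.network.N_stim, pp.nu_bg,
                              pp.nu_stim)
    for k, (d, on) in enumerate(window_sched):
        res = run_interval(
            net, state, d, on_rates if on else bg,
            _seed_for(seed, 2, 1, 11, k),
            plasticity=ctx.plasticity, blocked_stim=ctx.blocked_stim,
            blocked_exc=ctx.blocked_exc, blocked_inh=ctx.blocked_inh,
            record_bins=on)
        record.intervals.append({"phase": "training", "t0": t,
                                 "t1": t + d, "on": on})
        record.pop_rate_trace.append(res.pop_bins)
        if on:
            sess.on_time += d
            sess.counts_on += res.counts_e
            sess.interval_counts.append(res.counts_e)
            sess.interval_durations.append(d)
            if res.bins_e is not None:
                bins_parts.append(res.bins_e)
        t += d
    if bins_parts:
        sess.bins_on = np.concatenate(bins_parts, axis=0)
    record.training_window = sess
    if sess.on_time > 0:
        rates = sess.evoked_rates()
        record.training_engram = np.nonzero(rates > ap.zeta_thr)[0]
    else:
        record.training_engram = np.zeros(0, dtype=np.int64)
    record.weight_snapshots["end_training"] = _snapshot(state)

    # ---- consolidation with sampled offline sessions ---------------
    n_samples = int(np.floor(pp.T_consolidation / pp.sample_every)) \
        if pp.T_consolidation > 0 else 0
    sample_times = [i * pp.sample_every for i in range(n_samples + 1)]
    record.sample_times = sample_times
    cons_ctx = _PhaseContext(net, manips, "consolidation", record)
    record.phases.append({"name": "consolidation", "t0": t,
                          "t1": t + pp.T_consolidation})
    for si, t_cons in enumerate(sample_times):
        _branch_sessions(net, state, record, manips, seed, t_cons, si)
        if si < len(sample_times) - 1:
            seg = sample_times[si + 1] - t_cons
            ctx = cons_ctx
            sess = _run_session(
                net, state, kind="consolidation", stimulus=training,
                t_cons=t_cons, duration=seg,
                off_mean=pp.cons_off_mean, on_mean=pp.cons_on_mean,
                ctx=ctx, master_seed=seed, phase_id=3, branch_id=si,
                record_bins=False, record=record, log_intervals=True,
                t_offset=t)
            if sess.pop_rate is not None:
                record.pop_rate_trace.append(
                    (sess.pop_rate * mp.network.N_exc
                     * mp.analysis.rate_bin).astype(np.int64))
            t += seg
    tail = pp.T_consolidation - (sample_times[-1] if sample_times else 0.0)
    if tail > 1e-9:
        _run_session(net, state, kind="consolidation", stimulus=training,
                     t_cons=sample_times[-1], duration=tail,
                     off_mean=pp.cons_off_mean, on_mean=pp.cons_on_mean,
                     ctx=cons_ctx, master_seed=seed, phase_id=3,
                     branch_id=len(sample_times), record_bins=False,
                     record=record, log_intervals=True, t_offset=t)
    record.weight_snapshots["end_consolidation"] = _snapshot(state)
    return record


def _branch_sessions(net: Network, state: NetworkState,
                     record: SimulationRecord,
                     manips: Sequence[Manipulation], seed: int,
                     t_cons: float, si: int) -> None:
    """Probing + four recall sessions branched from a state snapshot."""
    mp = net.params
    pp = mp.protocol
    training = make_stimulus("square", mp.network.grid_side)

    frozen = {"exc": False, "ltp": False, "ltd": False, "het": False,
              "transmitter": False, "istdp": False}

    # probing: full training stimulus, engram identification only
    ctx = _PhaseContext(net, manips, "probing", record)
    if pp.freeze_branch_plasticity:
        ctx.plasticity = dict(frozen)
    probe_state = state.copy()
    sess = _run_session(
        net, probe_state, kind="probing", stimulus=training,
        t_cons=t_cons, duration=pp.T_probing,
        off_mean=pp.probe_off_mean, on_mean=pp.probe_on_mean,
        ctx=ctx, master_seed=seed, phase_id=4, branch_id=si,
        record_bins=True, record=record)
    record.sessions.append(sess)

    # recall: training cue + three novel cues, each on its own branch;
    # artificial reactivation gets a separate cue-free session instead
    # of forcing inside the cue sessions
    arts = [m for m in manips if m.kind == "artificial_reactivation"
            and "recall" in m.phases]
    cue_manips = [m for m in manips if m not in arts]
    ctx = _PhaseContext(net, cue_manips, "recall", record)
    if pp.freeze_branch_plasticity:
        ctx.plasticity = dict(frozen)
    for bi, name in enumerate(("square",) + NOVEL_STIMULI):
        stim = make_stimulus(name, mp.network.grid_side)
        cue = make_cue(stim, pp.cue_fraction)
        recall_state = state.copy()
        sess = _run_session(
            net, recall_state, kind="recall", stimulus=cue,
            t_cons=t_cons, duration=pp.T_recall,
            off_mean=pp.recall_off_mean, on_mean=pp.recall_on_mean,
            ctx=ctx, master_seed=seed, phase_id=5, branch_id=si * 8 + bi,
            record_bins=False, record=record)
        record.sessions.append(sess)
    if arts:
        # additional cue-free session with forced engram firing
        art_ctx = _PhaseContext(net, manips, "recall", record)
        if pp.freeze_branch_plasticity:
            art_ctx.plasticity = dict(frozen)
        recall_state = state.copy()
        sess = _run_session(
            net, recall_state, kind="recall", stimulus=None,
            t_cons=t_cons, duration=pp.T_recall,
            off_mean=pp.recall_off_mean, on_mean=pp.recall_on_mean,
            ctx=art_ctx, master_seed=seed, phase_id=5, branch_id=si * 8 + 7,
            record_bins=False, record=record,
            nu_reactivation=pp.nu_reactivation)
        sess.stimulus = "artificial_reactivation"
        record.sessions.append(sess)


def _snapshot(state: NetworkState) -> dict:
    return {k: state.__dict__[k].copy()
            for k in ("w_ff", "w_ee", "w_ie", "wt_ff", "wt_ee")}
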