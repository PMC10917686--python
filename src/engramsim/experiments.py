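"""Canned experiments: control protocol runs and branch probes.

These helpers bundle the protocol, analysis and manipulation layers
into the experiment designs used throughout the package's validation:
a control run with an added artificial-reactivation session, offline
recall branches replayed from the end-of-consolidation state (with
optional blocking of neuron sets), and the engram/recall summary
statistics derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .engine import NetworkState, init_state
from .engram import (EngramTimeline, build_timeline, identify_engram_rate,
                     recall_metrics, reactivated_fraction)
from .network import Network, build_network
from .params import ModelParams, desk
from .protocol import (Manipulation, SimulationRecord, _PhaseContext,
                       _run_session, make_cue, make_stimulus)

__all__ = [
    "ControlRun",
    "run_experiment",
    "recall_branch",
    "sufficiency_recall",
    "necessity_recall",
    "final_reactivated_fraction",
    "blocked_inhibition_discrimination",
]

_FROZEN = {"exc": False, "ltp": False, "ltd": False, "het": False,
           "transmitter": False, "istdp": False}


@dataclass
class ControlRun:
    """One protocol run plus its end-of-consolidation state."""

    mp: ModelParams
    net: Network
    record: SimulationRecord
    state: NetworkState
    seed: int

    @property
    def t_final(self) -> float:
        return self.record.sample_times[-1]

    def timeline(self, method: str = "rate") -> EngramTimeline:
        return build_timeline(self.record, self.mp.analysis,
                              self.mp.network.N_exc, method=method)

    def probing_members(self, t_cons: float) -> np.ndarray:
        probe = self.record.sessions_at(t_cons, "probing")[0]
        return identify_engram_rate(probe.counts_on, probe.on_time,
                                    self.mp.analysis.zeta_thr)


def run_experiment(seed: int, mp: Optional[ModelParams] = None,
                   manipulations: Sequence[Manipulation] = (),
                   artificial_reactivation: bool = True) -> ControlRun:
    """Run the full protocol on the desk preset (or ``mp``).

    With ``artificial_reactivation`` a cue-free recall session in
    which the training-activated engram cells are forced to fire at
    the reactivation rate is added at every sampled time point.
    """
    mp = mp if mp is not None else desk()
    from .protocol import run_protocol
    manips = list(manipulations)
    if artificial_reactivation:
        manips.append(Manipulation(kind="artificial_reactivation",
                                   phases=("recall",),
                                   target="training_engram"))
    net = build_network(mp, seed)
    state = init_state(net)
    record = run_protocol(net, seed, manips, state=state)
    return ControlRun(mp=mp, net=net, record=record, state=state,
                      seed=seed)


def recall_branch(run: ControlRun, cue_of: str, *,
                  blocked_exc: Optional[Sequence[int]] = None,
                  block_inhibition: bool = False,
                  branch_tag: int = 0):
    """Replay one recall session from the end-of-consolidation state.

    The branch runs on a copy of the state with plasticity frozen
    (offline measurement), optionally with a set of excitatory neurons
    or the whole inhibitory population blocked.
    """
    mp = run.mp
    pp = mp.protocol
    stim = make_stimulus(cue_of, mp.network.grid_side)
    cue = make_cue(stim, pp.cue_fraction)
    ctx = _PhaseContext(run.net, [], "recall", run.record)
    ctx.plasticity = dict(_FROZEN)
    if blocked_exc is not None:
        ctx.blocked_exc[np.asarray(list(blocked_exc), dtype=np.int64)] = True
    if block_inhibition:
        ctx.blocked_inh[:] = True
    state = run.state.copy()
    return _run_session(
        run.net, state, kind="recall", stimulus=cue, t_cons=run.t_final,
        duration=pp.T_recall, off_mean=pp.recall_off_mean,
        on_mean=pp.recall_on_mean, ctx=ctx, master_seed=run.seed,
        phase_id=13, branch_id=branch_tag, record_bins=False,
        record=SimulationRecord(seed=run.seed))


def sufficiency_recall(run: ControlRun) -> float:
    """Recall of the cue-free artificial-reactivation session at the
    final consolidation point, measured on the training-activated
    engram ensemble (the cells being driven)."""
    arts = [s for s in run.record.sessions_at(run.t_final, "recall")
            if s.stimulus == "artificial_reactivation"]
    if not arts:
        raise ValueError("run has no artificial-reactivation session")
    recall, _ = recall_metrics(arts[0], run.record.training_engram,
                               run.mp.analysis.zeta_thr)
    return recall


def necessity_recall(run: ControlRun) -> float:
    """Recall of a training-cue session at the final point with the
    training-activated engram cells blocked, measured on the current
    (probing-activated) ensemble."""
    sess = recall_branch(run, "square",
                         blocked_exc=run.record.training_engram,
                         branch_tag=1)
    members = run.probing_members(run.t_final)
    recall, _ = recall_metrics(sess, members, run.mp.analysis.zeta_thr)
    return recall


def final_reactivated_fraction(run: ControlRun) -> float:
    """Fraction of probing-activated engram cells at the final point
    whose mean training-cue-evoked rate exceeds the threshold."""
    members = run.probing_members(run.t_final)
    square = [s for s in run.record.sessions_at(run.t_final, "recall")
              if s.stimulus == "square_cue"][0]
    return reactivated_fraction(square, members,
                                run.mp.analysis.zeta_thr)


def blocked_inhibition_discrimination(run: ControlRun
                                      ) -> Dict[str, Dict[str, float]]:
    """Discrimination indices at the final point with and without the
    inhibitory population blocked during recall."""
    from .engram import discrimination_index
    members = run.probing_members(run.t_final)
    zeta = run.mp.analysis.zeta_thr
    out: Dict[str, Dict[str, float]] = {"control": {}, "blocked": {}}
    for cond, blocked in (("control", False), ("blocked", True)):
        rc = {}
        for k, name in enumerate(("square", "circle", "pentagon",
                                  "hexagon")):
            sess = recall_branch(run, name, block_inhibition=blocked,
                                 branch_tag=16 + 2 * k + int(blocked))
            rc[name], _ = recall_metrics(sess, members, zeta)
        for name in ("circle", "pentagon", "hexagon"):
            out[cond][name] = discrimination_index(rc["square"], rc[name])
    return out
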