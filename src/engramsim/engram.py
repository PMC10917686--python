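"""Engram identification and recall metrics.

A neuron is an *engram cell* at a given time point if its mean
stimulus-evoked firing rate (computed over stimulus-on time only)
strictly exceeds the activation threshold (10 Hz by default) in the
identification window: the last part of the training phase
(training-activated, training+) or an entire probing session
(probing-activated, probing+).  An alternative population-based
variant factorizes the 10 ms spike-count matrix with rank-1
non-negative matrix factorization and thresholds the coefficient
vector.

Recall of a partial cue is the fraction of cue presentations in which
the engram-ensemble population rate exceeds the threshold; the recall
rate is the cue-evoked ensemble rate averaged over presentations.
Selectivity is summarized by the discrimination index
(q1 - q2) / (q1 + q2) between training- and novel-cue recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from .params import AnalysisParams
from .protocol import NOVEL_STIMULI, SessionResult, SimulationRecord

__all__ = [
    "identify_engram_rate",
    "identify_engram_nmf",
    "ensemble_overlap",
    "recall_metrics",
    "discrimination_index",
    "bootstrap_ci",
    "EngramTimeline",
    "build_timeline",
]


def identify_engram_rate(counts_on: np.ndarray, on_time: float,
                         zeta_thr: float = 10.0) -> np.ndarray:
    """Rate-threshold engram identification.

    ``counts_on`` are per-neuron spike counts accumulated over the
    stimulus-on intervals of the identification window whose total
    duration is ``on_time``.  Membership requires a mean evoked rate
    strictly above ``zeta_thr``.
    """
    if on_time <= 0:
        raise ValueError("empty identification window")
    rates = np.asarray(counts_on, dtype=float) / on_time
    return np.nonzero(rates > zeta_thr)[0]


def identify_engram_nmf(count_matrix: np.ndarray, zeta_nmf: float = 0.5,
                        seed: int = 0, max_iter: int = 500,
                        tol: float = 1e-6) -> np.ndarray:
    """Population-based engram identification by rank-1 NMF.

    ``count_matrix`` has one row per 10 ms bin and one column per
    neuron.  The matrix is factorized as V ~= W H with a single
    feature; W is normalized to unit maximum so the H coefficients
    share a common scale, and membership is H > ``zeta_nmf``.
    """
    V = np.asarray(count_matrix, dtype=float)
    if V.ndim != 2:
        raise ValueError("count matrix must be 2-D (bins x neurons)")
    if np.any(V < 0):
        raise ValueError("count matrix must be non-negative")
    if not np.any(V > 0):
        warnings.warn("all-zero activity matrix: empty engram",
                      RuntimeWarning, stacklevel=2)
        return np.zeros(0, dtype=np.int64)
    model = NMF(n_components=1, init="nndsvda", random_state=int(seed),
                max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        W = model.fit_transform(V)
    H = model.components_[0]
    scale = W.max()
    if scale > 0:
        H = H * scale             # normalize W to unit maximum
    return np.nonzero(H > zeta_nmf)[0]


def ensemble_overlap(a: Sequence[int], b: Sequence[int],
                     denominator: str = "setA",
                     n_neurons: Optional[int] = None) -> float:
    """|a ∩ b| as a fraction of |a|, |b| or all neurons."""
    sa, sb = set(int(i) for i in a), set(int(i) for i in b)
    inter = len(sa & sb)
    if denominator == "setA":
        return inter / len(sa) if sa else np.nan
    if denominator == "setB":
        return inter / len(sb) if sb else np.nan
    if denominator == "all_neurons":
        if not n_neurons:
            raise ValueError("all_neurons denominator requires n_neurons")
        return inter / n_neurons
    raise ValueError(f"unknown denominator {denominator!r}")


def recall_metrics(session: SessionResult, engram: Sequence[int],
                   zeta_thr: float = 10.0) -> Tuple[float, float]:
    """(recall, recall rate) of an engram ensemble in a recall session.

    recall: fraction of cue presentations in which the ensemble
    population rate exceeds ``zeta_thr``; recall rate: ensemble
    population rate averaged across presentations (Hz).
    """
    idx = np.asarray(list(engram), dtype=np.int64)
    if idx.size == 0:
        return 0.0, 0.0
    if not session.interval_counts:
        raise ValueError("session has no cue presentations")
    rates = [c[idx].mean() / d for c, d in
             zip(session.interval_counts, session.interval_durations)]
    rates = np.asarray(rates)
    return float(np.mean(rates > zeta_thr)), float(rates.mean())


def reactivated_fraction(session: SessionResult, engram: Sequence[int],
                         zeta_thr: float = 10.0) -> float:
    """Fraction of engram cells reactivated during recall.

    A cell counts as reactivated if its own mean cue-evoked rate over
    the session exceeds ``zeta_thr``.
    """
    idx = np.asarray(list(engram), dtype=np.int64)
    if idx.size == 0:
        return np.nan
    rates = session.evoked_rates()[idx]
    return float(np.mean(rates > zeta_thr))


def discrimination_index(q1: float, q2: float) -> float:
    """(q1 - q2) / (q1 + q2); NaN when both quantities vanish."""
    if q1 + q2 <= 0:
        return np.nan
    return (q1 - q2) / (q1 + q2)


def bootstrap_ci(samples: Sequence[float], level: float = 0.99,
                 reps: int = 1000, seed: int = 0) -> Tuple[float, float]:
    """Percentile bootstrap confidence interval of the mean."""
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(reps, x.size))
    means = x[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(means, lo)),
            float(np.quantile(means, 1.0 - lo)))


@dataclass
class EngramTimeline:
    """Engram membership and recall statistics across consolidation."""

    sample_times: List[float]
    n_neurons: int
    training_engram: np.ndarray
    membership: Dict[float, np.ndarray] = field(default_factory=dict)
    # per time point: stimulus -> metric
    recall: Dict[float, Dict[str, float]] = field(default_factory=dict)
    recall_rate: Dict[float, Dict[str, float]] = field(default_factory=dict)
    discrimination: Dict[float, Dict[str, float]] = field(
        default_factory=dict)
    reactivated: Dict[float, Dict[str, float]] = field(default_factory=dict)

    def overlap_with_training(self, denominator: str = "setA"
                              ) -> List[float]:
        """Overlap(training+, probing+) per time point.

        ``setA`` = fraction of training+, ``setB`` = of probing+,
        ``all_neurons`` = of the whole network.
        """
        return [ensemble_overlap(self.training_engram, self.membership[t],
                                 denominator, self.n_neurons)
                for t in self.sample_times]

    def hour_to_hour_overlap(self) -> List[float]:
        """Overlap of consecutive probing+ ensembles as a fraction of
        the earlier one."""
        out = []
        for a, b in zip(self.sample_times[:-1], self.sample_times[1:]):
            out.append(ensemble_overlap(self.membership[a],
                                        self.membership[b], "setA"))
        return out

    def ensemble_fraction(self) -> List[float]:
        """Probing+ ensemble size as a fraction of all neurons."""
        return [len(self.membership[t]) / self.n_neurons
                for t in self.sample_times]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.sample_times:
            for stim in self.recall.get(t, {}):
                rows.append({
                    "t_cons": t, "stimulus": stim,
                    "recall": self.recall[t][stim],
                    "recall_rate": self.recall_rate[t][stim],
                    "discrimination":
                        self.discrimination[t].get(stim, np.nan),
                    "reactivated": self.reactivated[t].get(stim, np.nan),
                })
        return pd.DataFrame(rows)


def build_timeline(record: SimulationRecord, ap: AnalysisParams,
                   n_neurons: int, method: str = "rate",
                   nmf_seed: int = 0) -> EngramTimeline:
    """Compute the engram timeline of one protocol run.

    ``method`` selects rate-threshold ("rate") or population-based
    ("nmf") identification for training+ and probing+ ensembles.
    Recall metrics at each time point use the probing+ ensemble of
    that time point.
    """
    tw = record.training_window
    if tw is None:
        raise ValueError("record has no training window")
    if method == "rate":
        training_set = identify_engram_rate(tw.counts_on, tw.on_time,
                                            ap.zeta_thr)
    elif method == "nmf":
        training_set = identify_engram_nmf(tw.bins_on, ap.zeta_nmf,
                                           seed=nmf_seed)
    else:
        raise ValueError(f"unknown identification method {method!r}")
    tl = EngramTimeline(sample_times=list(record.sample_times),
                        n_neurons=n_neurons,
                        training_engram=np.asarray(training_set))
    for t in record.sample_times:
        probes = record.sessions_at(t, "probing")
        if not probes:
            continue
        probe = probes[0]
        if method == "rate":
            members = identify_engram_rate(probe.counts_on, probe.on_time,
                                           ap.zeta_thr)
        else:
            members = identify_engram_nmf(probe.bins_on, ap.zeta_nmf,
                                          seed=nmf_seed)
        tl.membership[t] = members
        tl.recall[t] = {}
        tl.recall_rate[t] = {}
        tl.discrimination[t] = {}
        tl.reactivated[t] = {}
        for sess in record.sessions_at(t, "recall"):
            stim = sess.stimulus.replace("_cue", "")
            rc, rr = recall_metrics(sess, members, ap.zeta_thr)
            tl.recall[t][stim] = rc
            tl.recall_rate[t][stim] = rr
            tl.reactivated[t][stim] = reactivated_fraction(
                sess, members, ap.zeta_thr)
        for stim in NOVEL_STIMULI:
            if stim in tl.recall[t] and "square" in tl.recall[t]:
                tl.discrimination[t][stim] = discrimination_index(
                    tl.recall[t]["square"], tl.recall[t][stim])
    return tl
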