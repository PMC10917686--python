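"""Longitudinal calcium-imaging analysis layer.

Identifies engram cells from ΔF/F traces recorded across a
longitudinal session structure (home cage / training context /
neutral context over a 24 h period), with the same two flavours as
the spiking analysis:

* threshold variant: a cell is an engram cell at a time point if the
  discrimination index between its mean ΔF/F in the training context
  and in the prior home-cage session exceeds 0.2;
* population variant: the training-context ΔF/F matrix is normalized
  against the home-cage session (subtract the home-cage cell mean,
  divide by the sum of home and training cell means, shift to
  non-negative), factorized by rank-1 NMF, and cells above the 99 %
  coefficient quantile are members.

A synthetic generator stands in for real microendoscope recordings:
it emulates the eight-session structure with planted engram ensembles
whose composition turns over between time points.  It reproduces the
session structure, elevated training-context activity of engram
cells, and shot-to-shot variability of ΔF/F traces; it does not model
movement artefacts, cross-talk between neighbouring cells, or slow
photobleaching trends of real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from .engram import discrimination_index

__all__ = [
    "DffDataset",
    "synthesize_dff",
    "imaging_engram_threshold",
    "imaging_engram_nmf",
    "SESSION_ORDER",
]

# eight sessions across 24 h: home cage + fear training; after 1 h,
# home cage, neutral and training contexts; after 23 more hours the
# same triplet again
SESSION_ORDER = (
    "home_0", "training_0",
    "home_1h", "neutral_1h", "training_1h",
    "home_24h", "neutral_24h", "training_24h",
)
TIME_POINTS = ("0", "1h", "24h")


@dataclass
class DffDataset:
    """Synthetic longitudinal ΔF/F recordings.

    ``sessions`` maps a session name to a (frames x cells) matrix;
    ``planted`` maps a time point to the indices of the cells planted
    as engram members at that time point.
    """

    sessions: Dict[str, np.ndarray]
    cell_ids: List[str]
    planted: Dict[str, np.ndarray]
    fs: float = 20.0

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frames(self) -> Dict[str, pd.DataFrame]:
        """Sessions as DataFrames with a timestamp index and cell-ID
        header, the CSV exchange format."""
        out = {}
        for name, m in self.sessions.items():
            idx = np.arange(m.shape[0]) / self.fs
            out[name] = pd.DataFrame(m, columns=self.cell_ids,
                                     index=pd.Index(idx, name="time_s"))
        return out


def _transient_trace(rng: np.random.Generator, n_frames: int, rate: float,
                     fs: float, tau: float = 0.5, amp: float = 1.0
                     ) -> np.ndarray:
    """Poisson calcium transients convolved with an exponential decay."""
    events = rng.random(n_frames) < rate / fs
    kernel = amp * np.exp(-np.arange(int(tau * fs * 5)) / (tau * fs))
    tr = np.convolve(events.astype(float), kernel)[:n_frames]
    return tr


def synthesize_dff(n_cells: int = 400, n_sessions: int = 8,
                   planted_engrams_per_timepoint: int = 5,
                   effect_size: float = 3.0, noise: float = 0.3,
                   turnover: float = 0.4, seed: int = 0,
                   duration: float = 60.0, fs: float = 20.0) -> DffDataset:
    """Generate longitudinal ΔF/F sessions with a planted engram.

    Cells fire calcium transients at a baseline event rate in every
    session; cells planted as engram members at a time point have
    their training-context event rate multiplied by ``effect_size``
    (so their home-vs-training discrimination index is positive; with
    the default 3.0 it is about 0.5).  Between consecutive time points
    a ``turnover`` fraction of the planted ensemble is replaced by
    fresh cells.  ``noise`` is the amplitude of additive measurement
    noise (folded normal, keeping traces non-negative).
    """
    if n_sessions != len(SESSION_ORDER):
        raise ValueError(f"the session structure has {len(SESSION_ORDER)} "
                         "sessions")
    if not 0.0 <= turnover <= 1.0:
        raise ValueError("turnover must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * fs))
    k = planted_engrams_per_timepoint
    if k > n_cells:
        raise ValueError("more planted cells than cells")

    planted: Dict[str, np.ndarray] = {}
    current = rng.choice(n_cells, size=k, replace=False)
    planted["0"] = np.sort(current)
    for tp in TIME_POINTS[1:]:
        n_swap = int(round(turnover * k))
        keep = rng.choice(current, size=k - n_swap, replace=False)
        pool = np.setdiff1d(np.arange(n_cells), keep)
        new = rng.choice(pool, size=n_swap, replace=False)
        current = np.concatenate([keep, new])
        planted[tp] = np.sort(current)

    base_rate = rng.uniform(0.5, 1.5, size=n_cells)    # events / s
    sessions: Dict[str, np.ndarray] = {}
    for name in SESSION_ORDER:
        tp = name.split("_")[-1] if "_" in name else "0"
        tp = {"0": "0", "1h": "1h", "24h": "24h"}[tp]
        m = np.empty((n_frames, n_cells))
        boost = np.ones(n_cells)
        if name.startswith("training"):
            boost[planted[tp]] = effect_size
        for c in range(n_cells):
            m[:, c] = _transient_trace(rng, n_frames,
                                       base_rate[c] * boost[c], fs)
        m += np.abs(rng.normal(0.0, noise, size=m.shape)) * 0.05
        sessions[name] = m
    ids = [f"cell_{i:04d}" for i in range(n_cells)]
    return DffDataset(sessions=sessions, cell_ids=ids, planted=planted,
                      fs=fs)


def imaging_engram_threshold(dff_training: np.ndarray,
                             dff_home: np.ndarray,
                             zeta_disc: float = 0.2) -> np.ndarray:
    """Threshold-variant engram identification from ΔF/F sessions.

    Both arguments are (frames x cells) matrices of the same width;
    membership requires the per-cell discrimination index between the
    training-context and home-cage session means to exceed
    ``zeta_disc``.
    """
    if dff_training.shape[1] != dff_home.shape[1]:
        raise ValueError("sessions have mismatched neuron columns")
    m_t = np.asarray(dff_training).mean(axis=0)
    m_h = np.asarray(dff_home).mean(axis=0)
    disc = np.array([discrimination_index(a, b)
                     for a, b in zip(m_t, m_h)])
    with np.errstate(invalid="ignore"):
        return np.nonzero(disc > zeta_disc)[0]


def imaging_engram_nmf(dff_training: np.ndarray, dff_home: np.ndarray,
                       nmf_quantile: float = 0.99, seed: int = 0
                       ) -> np.ndarray:
    """Population-variant engram identification from ΔF/F sessions.

    Normalization steps: subtract each cell's home-cage mean from its
    training-context trace; divide by the sum of home-cage and
    training means; subtract the global minimum to obtain a
    non-negative matrix; then factorize with rank-1 NMF and keep the
    cells whose coefficient exceeds the ``nmf_quantile`` quantile of
    the coefficient vector.
    """
    if dff_training.shape[1] != dff_home.shape[1]:
        raise ValueError("sessions have mismatched neuron columns")
    C_t = np.asarray(dff_training, dtype=float)
    m_h = np.asarray(dff_home, dtype=float).mean(axis=0)
    m_t = C_t.mean(axis=0)
    denom = m_h + m_t
    denom = np.where(denom > 0, denom, 1.0)
    C_norm = (C_t - m_h[None, :]) / denom[None, :]
    C_nn = C_norm - C_norm.min()
    if not np.any(C_nn > 0):
        warnings.warn("degenerate ΔF/F matrix: empty engram",
                      RuntimeWarning, stacklevel=2)
        return np.zeros(0, dtype=np.int64)
    model = NMF(n_components=1, init="nndsvda", random_state=int(seed),
                max_iter=500, tol=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit_transform(C_nn)
    H = model.components_[0]
    thr = np.quantile(H, nmf_quantile)
    return np.nonzero(H > thr)[0]
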