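"""Network construction: populations, connectivity and initial weights.

The model is a stimulus population of Poisson units (on the input
grid) projecting to a recurrent hippocampal network of excitatory and
inhibitory LIF neurons.  Five synapse classes exist:

==========  ==================  ==============================
projection  initial weight      plasticity
==========  ==================  ==============================
stim->E     w_stim (constant)   short-term + long-term excitatory
E->E        U(0, 2 w_EE)        short-term + long-term excitatory
E->I        U(0, 2 w_EI)        short-term only
I->E        U(0, 2 w_IE)        inhibitory STDP
I->I        U(0, 2 w_II)        static
==========  ==================  ==============================

Recurrent connectivity is i.i.d. Bernoulli(eps_rec) per ordered pair
without self-connections.  Each excitatory neuron receives feedforward
input from the stimulus units inside a circular receptive field of
radius ``R_hpc`` around a uniformly random centre on the grid (plane
geometry, no wrap-around).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams, NetworkParams

__all__ = ["Projection", "Network", "build_network"]


@dataclass
class Projection:
    """Static synapse table in presynaptic CSR layout.

    ``indptr``/``post`` list, for each presynaptic neuron, its target
    neurons; synapse ``k`` of the table is the k-th entry of ``post``.
    ``w_init`` holds the initial weights aligned with ``post``.  For
    projections that need postsynaptically indexed access (triplet LTP
    and heterosynaptic updates run over a neuron's incoming synapses),
    ``post_indptr``/``syn_of_post``/``pre_of_post`` give, per
    postsynaptic neuron, the synapse indices and presynaptic sources.
    """

    n_pre: int
    n_post: int
    indptr: np.ndarray            # (n_pre+1,) int64
    post: np.ndarray              # (n_syn,) int32
    w_init: np.ndarray            # (n_syn,) float64
    post_indptr: np.ndarray       # (n_post+1,) int64
    syn_of_post: np.ndarray       # (n_syn,) int64
    pre_of_post: np.ndarray       # (n_syn,) int32

    @property
    def n_syn(self) -> int:
        return int(self.post.shape[0])


def _make_projection(rng: np.random.Generator, n_pre: int, n_post: int,
                     p: float, w_mean: float, jitter: float,
                     no_self: bool) -> Projection:
    """Bernoulli(p) random projection with uniform initial weights."""
    mask = rng.random((n_pre, n_post)) < p
    if no_self:
        np.fill_diagonal(mask, False)
    pre_idx, post_idx = np.nonzero(mask)
    order = np.lexsort((post_idx, pre_idx))
    pre_idx = pre_idx[order]
    post_idx = post_idx[order].astype(np.int32)
    indptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.add.at(indptr, pre_idx + 1, 1)
    indptr = np.cumsum(indptr)
    lo = max(0.0, (1.0 - jitter) * w_mean)
    hi = (1.0 + jitter) * w_mean
    w = rng.uniform(lo, hi, size=post_idx.shape[0])
    return _with_post_index(n_pre, n_post, indptr, post_idx, w)


def _with_post_index(n_pre: int, n_post: int, indptr: np.ndarray,
                     post: np.ndarray, w: np.ndarray) -> Projection:
    n_syn = post.shape[0]
    pre_of_syn = np.repeat(np.arange(n_pre, dtype=np.int32),
                           np.diff(indptr))
    order = np.lexsort((pre_of_syn, post))
    post_indptr = np.zeros(n_post + 1, dtype=np.int64)
    np.add.at(post_indptr, post.astype(np.int64) + 1, 1)
    post_indptr = np.cumsum(post_indptr)
    return Projection(n_pre=n_pre, n_post=n_post, indptr=indptr,
                      post=post, w_init=w,
                      post_indptr=post_indptr,
                      syn_of_post=order.astype(np.int64),
                      pre_of_post=pre_of_syn[order])


def _make_feedforward(rng: np.random.Generator, np_: NetworkParams) -> tuple:
    """Circular receptive fields on the stimulus grid."""
    side = np_.grid_side
    centers = rng.uniform(0.0, side, size=(np_.N_exc, 2))  # (x, y)
    rows, cols = np.mgrid[0:side, 0:side]
    ux = (cols + 0.5).ravel()
    uy = (rows + 0.5).ravel()
    pre_list = []
    post_list = []
    for i in range(np_.N_exc):
        d2 = (ux - centers[i, 0]) ** 2 + (uy - centers[i, 1]) ** 2
        src = np.nonzero(d2 <= np_.R_hpc ** 2)[0]
        pre_list.append(src)
        post_list.append(np.full(src.shape[0], i, dtype=np.int32))
    pre_idx = np.concatenate(pre_list)
    post_idx = np.concatenate(post_list)
    order = np.lexsort((post_idx, pre_idx))
    pre_idx = pre_idx[order]
    post_idx = post_idx[order]
    indptr = np.zeros(np_.N_stim + 1, dtype=np.int64)
    np.add.at(indptr, pre_idx + 1, 1)
    indptr = np.cumsum(indptr)
    w = np.full(post_idx.shape[0], np_.w_stim, dtype=np.float64)
    proj = _with_post_index(np_.N_stim, np_.N_exc, indptr, post_idx, w)
    return proj, centers


@dataclass
class Network:
    """Static structure of one realized network.

    Holds the five projections, receptive-field centres, and the mask
    of inhibitory neurons with plastic efferent synapses (all of them
    in the single-interneuron-type model; a CCK-like subset when
    ``interneuron_split`` is set, the PV-like remainder being static).
    """

    params: ModelParams
    ff: Projection                # stim -> E
    ee: Projection                # E -> E
    ei: Projection                # E -> I
    ie: Projection                # I -> E
    ii: Projection                # I -> I
    rf_centers: np.ndarray        # (N_exc, 2) receptive-field centres
    inh_plastic_mask: np.ndarray  # (N_inh,) bool; efferent I->E plasticity
    seed: int = 0


def build_network(mp: ModelParams, seed: int) -> Network:
    """Sample a network realization from the model parameters.

    Deterministic given (params, seed).
    """
    mp.validate()
    np_ = mp.network
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    j = np_.init_uniform_jitter
    ee = _make_projection(rng, np_.N_exc, np_.N_exc, np_.eps_rec,
                          np_.w_EE, j, no_self=True)
    ei = _make_projection(rng, np_.N_exc, np_.N_inh, np_.eps_rec,
                          np_.w_EI, j, no_self=False)
    ie = _make_projection(rng, np_.N_inh, np_.N_exc, np_.eps_rec,
                          np_.w_IE, j, no_self=False)
    ii = _make_projection(rng, np_.N_inh, np_.N_inh, np_.eps_rec,
                          np_.w_II, j, no_self=True)
    ff, centers = _make_feedforward(rng, np_)
    if np_.interneuron_split is None:
        inh_plastic = np.ones(np_.N_inh, dtype=bool)
    else:
        n_plastic = int(round(np_.interneuron_split * np_.N_inh))
        inh_plastic = np.zeros(np_.N_inh, dtype=bool)
        idx = rng.permutation(np_.N_inh)[:n_plastic]
        inh_plastic[idx] = True
    return Network(params=mp, ff=ff, ee=ee, ei=ei, ie=ie, ii=ii,
                   rf_centers=centers, inh_plastic_mask=inh_plastic,
                   seed=int(seed))
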