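"""Clock-driven simulation engine.

One fused numba kernel advances the whole network — membrane dynamics,
conductances, short-term plasticity, triplet/heterosynaptic/
transmitter-induced excitatory plasticity, homeostatic LTD-rate
regulation, reference-weight consolidation and inhibitory STDP — with
a 0.1 ms forward-Euler step and a one-step synaptic delay.

The per-step order of operations matches the reference modules
:mod:`engramsim.dynamics` and :mod:`engramsim.plasticity` bit for bit:

1. decay all conductances, traces and STP variables; decay H and read
   the global factor G = H - gamma for this step;
2. deliver the spikes emitted in the previous step: weight updates
   triggered by presynaptic spikes (triplet LTD, transmitter-induced,
   inhibitory pre terms) and by postsynaptic spikes (triplet LTP,
   heterosynaptic, inhibitory post term), all reading the decayed
   traces (the epsilon convention); then conductance increments, STP
   jumps, trace increments and the H increment;
3. update the homeostatic variable C, advance membranes and detect
   spikes (strict U > theta), which are buffered for the next step;
4. draw stimulus-population Poisson spikes for the next step;
5. on the slow tick (every ``dt_long``) advance the reference weights.

Blocked neurons are reset when they cross threshold but emit nothing,
so their efferent synapses and efferent plasticity are silenced.
Neurons under artificial reactivation fire additional Poisson spikes
at the configured rate irrespective of their membrane state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .network import Network
from .params import ModelParams

__all__ = ["NetworkState", "init_state", "run_interval", "IntervalResult"]

_EMPTY_U8 = np.zeros((1, 1), dtype=np.uint8)
_EMPTY_I32 = np.zeros(0, dtype=np.int32)
_EMPTY_I64 = np.zeros(0, dtype=np.int64)


@dataclass
class NetworkState:
    """All dynamic variables of a simulation; cheap to snapshot."""

    # neuron state: excitatory population
    U_e: np.ndarray
    th_e: np.ndarray
    ga_e: np.ndarray
    gn_e: np.ndarray
    gg_e: np.ndarray
    gad_e: np.ndarray
    # neuron state: inhibitory population
    U_i: np.ndarray
    th_i: np.ndarray
    ga_i: np.ndarray
    gn_i: np.ndarray
    gg_i: np.ndarray
    gad_i: np.ndarray
    # short-term plasticity (per presynaptic excitatory source)
    u_s: np.ndarray
    x_s: np.ndarray
    u_e: np.ndarray
    x_e: np.ndarray
    # plasticity traces
    zp_s: np.ndarray              # z+ of stimulus units
    zp_e: np.ndarray              # z+ of excitatory neurons
    zm_e: np.ndarray              # z- (post, fast)
    zs_e: np.ndarray              # z_slow (post)
    zht_e: np.ndarray             # z_ht (post, homeostatic)
    C_e: np.ndarray               # homeostatic LTD variable
    zi_pre: np.ndarray            # inhibitory STDP pre trace
    zi_post: np.ndarray           # inhibitory STDP post trace
    H: np.ndarray                 # global low-pass activity, shape (1,)
    # plastic weights (aligned with the Projection tables)
    w_ff: np.ndarray
    wt_ff: np.ndarray
    w_ee: np.ndarray
    wt_ee: np.ndarray
    w_ei: np.ndarray
    w_ie: np.ndarray
    w_ii: np.ndarray
    # spike buffers (previous step), index lists + counts
    prev_s: np.ndarray
    prev_e: np.ndarray
    prev_i: np.ndarray
    prev_n: np.ndarray            # shape (3,): counts for s, e, i
    cons_countdown: np.ndarray    # shape (1,): steps until slow tick

    def copy(self) -> "NetworkState":
        return NetworkState(**{k: v.copy() for k, v in self.__dict__.items()})


def init_state(net: Network) -> NetworkState:
    """Fresh state: neurons at rest, STP recovered, traces zero,
    weights at their initial values, reference weights per config."""
    mp = net.params
    n = mp.network
    pn = mp.neuron
    pp = mp.plasticity

    def rest(sz):
        return np.full(sz, pn.U_rest, dtype=np.float64)

    def f64(x):
        return np.asarray(x, dtype=np.float64)

    wt_ff = net.ff.w_init.copy() if n.wtilde_init_equal else \
        np.zeros_like(net.ff.w_init)
    wt_ee = net.ee.w_init.copy() if n.wtilde_init_equal else \
        np.zeros_like(net.ee.w_init)
    return NetworkState(
        U_e=rest(n.N_exc), th_e=np.full(n.N_exc, float(pn.theta_rest)),
        ga_e=np.zeros(n.N_exc), gn_e=np.zeros(n.N_exc),
        gg_e=np.zeros(n.N_exc), gad_e=np.zeros(n.N_exc),
        U_i=rest(n.N_inh), th_i=np.full(n.N_inh, float(pn.theta_rest)),
        ga_i=np.zeros(n.N_inh), gn_i=np.zeros(n.N_inh),
        gg_i=np.zeros(n.N_inh), gad_i=np.zeros(n.N_inh),
        u_s=np.full(n.N_stim, float(pp.U_stp)), x_s=np.ones(n.N_stim),
        u_e=np.full(n.N_exc, float(pp.U_stp)), x_e=np.ones(n.N_exc),
        zp_s=np.zeros(n.N_stim), zp_e=np.zeros(n.N_exc),
        zm_e=np.zeros(n.N_exc), zs_e=np.zeros(n.N_exc),
        zht_e=np.zeros(n.N_exc), C_e=np.zeros(n.N_exc),
        zi_pre=np.zeros(n.N_inh), zi_post=np.zeros(n.N_exc),
        H=np.array([float(pp.gamma)]),  # start at target; avoids a kick
        w_ff=f64(net.ff.w_init).copy(), wt_ff=f64(wt_ff),
        w_ee=net.ee.w_init.copy(), wt_ee=wt_ee,
        w_ei=net.ei.w_init.copy(),
        w_ie=net.ie.w_init.copy(),
        w_ii=net.ii.w_init.copy(),
        prev_s=np.zeros(n.N_stim, dtype=np.int32),
        prev_e=np.zeros(n.N_exc, dtype=np.int32),
        prev_i=np.zeros(n.N_inh, dtype=np.int32),
        prev_n=np.zeros(3, dtype=np.int64),
        cons_countdown=np.array(
            [max(1, int(round(pp.dt_long / pn.dt)))], dtype=np.int64),
    )


@dataclass
class IntervalResult:
    """Per-interval recordings returned by :func:`run_interval`."""

    n_steps: int
    counts_e: np.ndarray                      # exc spike count per neuron
    pop_bins: np.ndarray                      # exc population spikes per bin
    bins_e: Optional[np.ndarray] = None       # (n_bins, N_exc) counts
    spikes: Optional[np.ndarray] = None       # (n, 2): step, global id
    counts_i: Optional[np.ndarray] = None


@njit(cache=True)
def _run_kernel(n_steps, seed, cn, cp, flg, dt_long_steps,
                # connectivity
                ff_indptr, ff_post, ff_pip, ff_sop, ff_pop,
                ee_indptr, ee_post, ee_pip, ee_sop, ee_pop,
                ei_indptr, ei_post,
                ie_indptr, ie_post, ie_pip, ie_sop, ie_pop,
                ii_indptr, ii_post,
                inh_plastic,
                # weights
                w_ff, wt_ff, w_ee, wt_ee, w_ei, w_ie, w_ii,
                # neuron state
                U_e, th_e, ga_e, gn_e, gg_e, gad_e,
                U_i, th_i, ga_i, gn_i, gg_i, gad_i,
                # plasticity state
                u_s, x_s, u_e, x_e, zp_s, zp_e, zm_e, zs_e, zht_e, C_e,
                zi_pre, zi_post, H, cons_countdown,
                # spike buffers
                prev_s, prev_e, prev_i, prev_n,
                # inputs
                rates_dt, cls_p, cls_members, cls_ptr,
                scripted, blocked_s, blocked_e, blocked_i,
                forced_e, forced_p,
                # recording
                counts_e_out, counts_i_out, pop_bins, bins_e, bin_steps,
                spk_step, spk_id, spk_n):
    np.random.seed(seed)
    dt = cn[0]; tau_m = cn[1]; U_rest = cn[2]; U_exc = cn[3]; U_inh = cn[4]
    th_rest = cn[5]; th_spike = cn[6]; tau_thr = cn[7]; tau_gaba = cn[8]
    tau_a = cn[9]; tau_ampa = cn[10]; tau_nmda = cn[11]; Delta_a = cn[12]
    alpha = cn[13]

    tau_d = cp[0]; tau_f = cp[1]; U_stp = cp[2]; eta_exc = cp[3]; A = cp[4]
    beta = cp[5]; delta = cp[6]; tau_plus = cp[7]; tau_minus = cp[8]
    tau_slow = cp[9]; tau_ht = cp[10]; tau_hom = cp[11]; eta_inh = cp[12]
    gamma = cp[13]; tau_H = cp[14]; tau_istdp = cp[15]
    w_exc_min = cp[16]; w_exc_max = cp[17]
    w_inh_min = cp[18]; w_inh_max = cp[19]
    tau_cons = cp[20]; Pdw = cp[21]; w_P = cp[22]; dt_long = cp[23]

    ltp_on = flg[0] == 1
    ltd_on = flg[1] == 1
    het_on = flg[2] == 1
    transmitter_on = flg[3] == 1
    istdp_on = flg[4] == 1
    istdp_pre_only = flg[5] == 1
    use_scripted = flg[6] == 1
    record_bins = flg[7] == 1
    record_spikes = flg[8] == 1
    forced_on = flg[9] == 1
    exc_plast_on = flg[10] == 1   # master switch for long-term exc plasticity

    N_stim = rates_dt.shape[0]
    N_exc = U_e.shape[0]
    N_inh = U_i.shape[0]

    d_gaba = 1.0 - dt / tau_gaba
    d_a = 1.0 - dt / tau_a
    d_ampa = 1.0 - dt / tau_ampa
    d_plus = 1.0 - dt / tau_plus
    d_minus = 1.0 - dt / tau_minus
    d_slow = 1.0 - dt / tau_slow
    d_ht = 1.0 - dt / tau_ht
    d_istdp = 1.0 - dt / tau_istdp
    d_H = 1.0 - dt / tau_H
    d_hom = 1.0 - dt / tau_hom
    k_d = dt / tau_d
    k_f = dt / tau_f
    k_nmda = dt / tau_nmda
    k_m = dt / tau_m
    k_thr = dt / tau_thr
    k_cons = dt_long / tau_cons

    for step in range(n_steps):
        # ---- (1) decay continuous variables -------------------------
        # one simple loop per array so the compiler can vectorize
        for i in range(N_exc):
            ga_e[i] *= d_ampa
        for i in range(N_exc):
            gg_e[i] *= d_gaba
        for i in range(N_exc):
            gad_e[i] *= d_a
        for i in range(N_exc):
            zp_e[i] *= d_plus
        for i in range(N_exc):
            zm_e[i] *= d_minus
        for i in range(N_exc):
            zs_e[i] *= d_slow
        for i in range(N_exc):
            zht_e[i] *= d_ht
        for i in range(N_exc):
            zi_post[i] *= d_istdp
        for i in range(N_exc):
            x_e[i] += k_d * (1.0 - x_e[i])
        for i in range(N_exc):
            u_e[i] += k_f * (U_stp - u_e[i])
        for i in range(N_inh):
            ga_i[i] *= d_ampa
        for i in range(N_inh):
            gg_i[i] *= d_gaba
        for i in range(N_inh):
            gad_i[i] *= d_a
        for i in range(N_inh):
            zi_pre[i] *= d_istdp
        for j in range(N_stim):
            zp_s[j] *= d_plus
        for j in range(N_stim):
            x_s[j] += k_d * (1.0 - x_s[j])
        for j in range(N_stim):
            u_s[j] += k_f * (U_stp - u_s[j])
        H[0] *= d_H
        G = H[0] - gamma

        n_s = prev_n[0]
        n_e = prev_n[1]
        n_i = prev_n[2]

        # ---- (2a) presynaptic-spike weight updates + conductances ---
        # stimulus -> E
        for a_ in range(n_s):
            j = prev_s[a_]
            rel = u_s[j] * x_s[j]
            for s in range(ff_indptr[j], ff_indptr[j + 1]):
                i = ff_post[s]
                ga_e[i] += w_ff[s] * rel
                if exc_plast_on:
                    w = w_ff[s]
                    if ltd_on:
                        Bi = A * min(C_e[i], 1.0)
                        w -= eta_exc * Bi * zm_e[i]
                    if transmitter_on:
                        w += delta
                    if w < w_exc_min:
                        w = w_exc_min
                    elif w > w_exc_max:
                        w = w_exc_max
                    w_ff[s] = w
        # E -> E and E -> I
        for a_ in range(n_e):
            j = prev_e[a_]
            rel = u_e[j] * x_e[j]
            for s in range(ee_indptr[j], ee_indptr[j + 1]):
                i = ee_post[s]
                ga_e[i] += w_ee[s] * rel
                if exc_plast_on:
                    w = w_ee[s]
                    if ltd_on:
                        Bi = A * min(C_e[i], 1.0)
                        w -= eta_exc * Bi * zm_e[i]
                    if transmitter_on:
                        w += delta
                    if w < w_exc_min:
                        w = w_exc_min
                    elif w > w_exc_max:
                        w = w_exc_max
                    w_ee[s] = w
            for s in range(ei_indptr[j], ei_indptr[j + 1]):
                ga_i[ei_post[s]] += w_ei[s] * rel
            gad_e[j] += Delta_a          # own previous spike: adaptation
        # I -> E and I -> I
        for a_ in range(n_i):
            j = prev_i[a_]
            for s in range(ie_indptr[j], ie_indptr[j + 1]):
                i = ie_post[s]
                gg_e[i] += w_ie[s]
                if istdp_on and inh_plastic[j]:
                    if istdp_pre_only:
                        dw = eta_inh * G
                    else:
                        dw = eta_inh * G * (zi_post[i] + 1.0)
                    w = w_ie[s] + dw
                    if w < w_inh_min:
                        w = w_inh_min
                    elif w > w_inh_max:
                        w = w_inh_max
                    w_ie[s] = w
            for s in range(ii_indptr[j], ii_indptr[j + 1]):
                gg_i[ii_post[s]] += w_ii[s]
            gad_i[j] += Delta_a

        # ---- (2b) postsynaptic-spike weight updates -----------------
        for a_ in range(n_e):
            i = prev_e[a_]
            if exc_plast_on:
                zm3 = zm_e[i] * zm_e[i] * zm_e[i]
                for t in range(ff_pip[i], ff_pip[i + 1]):
                    s = ff_sop[t]
                    j = ff_pop[t]
                    w = w_ff[s]
                    if ltp_on:
                        w += eta_exc * A * zp_s[j] * zs_e[i]
                    if het_on:
                        w -= beta * (w - wt_ff[s]) * zm3
                    if w < w_exc_min:
                        w = w_exc_min
                    elif w > w_exc_max:
                        w = w_exc_max
                    w_ff[s] = w
                for t in range(ee_pip[i], ee_pip[i + 1]):
                    s = ee_sop[t]
                    j = ee_pop[t]
                    w = w_ee[s]
                    if ltp_on:
                        w += eta_exc * A * zp_e[j] * zs_e[i]
                    if het_on:
                        w -= beta * (w - wt_ee[s]) * zm3
                    if w < w_exc_min:
                        w = w_exc_min
                    elif w > w_exc_max:
                        w = w_exc_max
                    w_ee[s] = w
            if istdp_on and not istdp_pre_only:
                for t in range(ie_pip[i], ie_pip[i + 1]):
                    s = ie_sop[t]
                    j = ie_pop[t]
                    if inh_plastic[j]:
                        w = w_ie[s] + eta_inh * G * zi_pre[j]
                        if w < w_inh_min:
                            w = w_inh_min
                        elif w > w_inh_max:
                            w = w_inh_max
                        w_ie[s] = w

        # ---- (2c) trace, STP and H increments -----------------------
        for a_ in range(n_s):
            j = prev_s[a_]
            rel = u_s[j] * x_s[j]
            x_s[j] -= rel
            u_s[j] += U_stp * (1.0 - u_s[j])
            zp_s[j] += 1.0
        for a_ in range(n_e):
            i = prev_e[a_]
            rel = u_e[i] * x_e[i]
            x_e[i] -= rel
            u_e[i] += U_stp * (1.0 - u_e[i])
            zp_e[i] += 1.0
            zm_e[i] += 1.0
            zs_e[i] += 1.0
            zht_e[i] += 1.0
            zi_post[i] += 1.0
        for a_ in range(n_i):
            zi_pre[prev_i[a_]] += 1.0
        H[0] += n_e

        # ---- (3) homeostatic C, membranes, spike detection ----------
        bin_idx = step // bin_steps
        for i in range(N_exc):
            C_e[i] = C_e[i] * d_hom + dt * zht_e[i] * zht_e[i]
        for i in range(N_exc):
            gn_e[i] += k_nmda * (ga_e[i] - gn_e[i])
        for i in range(N_inh):
            gn_i[i] += k_nmda * (ga_i[i] - gn_i[i])
        ne_new = 0
        for i in range(N_exc):
            gex = alpha * ga_e[i] + (1.0 - alpha) * gn_e[i]
            U = U_e[i] + k_m * ((U_rest - U_e[i])
                                + gex * (U_exc - U_e[i])
                                + (gg_e[i] + gad_e[i]) * (U_inh - U_e[i]))
            th = th_e[i] + k_thr * (th_rest - th_e[i])
            if not np.isfinite(U):
                return step
            fire = U > th
            if forced_on and forced_e[i]:
                if np.random.random() < forced_p:
                    fire = True
            if fire:
                U = U_rest
                th = th_spike
                if not blocked_e[i]:
                    prev_e[ne_new] = i
                    ne_new += 1
                    counts_e_out[i] += 1
                    pop_bins[bin_idx] += 1
                    if record_bins:
                        bins_e[bin_idx, i] += 1
                    if record_spikes and spk_n[0] < spk_step.shape[0]:
                        spk_step[spk_n[0]] = step
                        spk_id[spk_n[0]] = N_stim + i
                        spk_n[0] += 1
            U_e[i] = U
            th_e[i] = th
        ni_new = 0
        for i in range(N_inh):
            gex = alpha * ga_i[i] + (1.0 - alpha) * gn_i[i]
            U = U_i[i] + k_m * ((U_rest - U_i[i])
                                + gex * (U_exc - U_i[i])
                                + (gg_i[i] + gad_i[i]) * (U_inh - U_i[i]))
            th = th_i[i] + k_thr * (th_rest - th_i[i])
            if not np.isfinite(U):
                return step
            if U > th:
                U = U_rest
                th = th_spike
                if not blocked_i[i]:
                    prev_i[ni_new] = i
                    ni_new += 1
                    counts_i_out[i] += 1
                    if record_spikes and spk_n[0] < spk_step.shape[0]:
                        spk_step[spk_n[0]] = step
                        spk_id[spk_n[0]] = N_stim + N_exc + i
                        spk_n[0] += 1
            U_i[i] = U
            th_i[i] = th

        # ---- (4) stimulus spikes for the next step ------------------
        # Poisson drive drawn per rate class: a Binomial(n, p) count
        # plus a uniform distinct-member choice is jointly identical
        # to independent per-neuron Bernoulli(p) draws, at a fraction
        # of the random-number cost.
        ns_new = 0
        if use_scripted:
            for j in range(N_stim):
                if scripted[step, j] != 0 and not blocked_s[j]:
                    prev_s[ns_new] = j
                    ns_new += 1
                    if record_spikes and spk_n[0] < spk_step.shape[0]:
                        spk_step[spk_n[0]] = step
                        spk_id[spk_n[0]] = j
                        spk_n[0] += 1
        else:
            for c in range(cls_ptr.shape[0] - 1):
                lo = cls_ptr[c]
                n_c = cls_ptr[c + 1] - lo
                if n_c == 0:
                    continue
                k = np.random.binomial(n_c, cls_p[c])
                for _ in range(k):
                    while True:
                        cand = cls_members[
                            lo + int(np.random.random() * n_c)]
                        dup = False
                        for q in range(ns_new):
                            if prev_s[q] == cand:
                                dup = True
                                break
                        if not dup:
                            break
                    prev_s[ns_new] = cand
                    ns_new += 1
                    if record_spikes and spk_n[0] < spk_step.shape[0]:
                        spk_step[spk_n[0]] = step
                        spk_id[spk_n[0]] = cand
                        spk_n[0] += 1
        prev_n[0] = ns_new
        prev_n[1] = ne_new
        prev_n[2] = ni_new

        # ---- (5) reference-weight slow tick -------------------------
        cons_countdown[0] -= 1
        if cons_countdown[0] <= 0:
            cons_countdown[0] = dt_long_steps
            if exc_plast_on:
                for s in range(w_ff.shape[0]):
                    wt = wt_ff[s]
                    wt_ff[s] = wt + k_cons * (
                        w_ff[s] - wt
                        - Pdw * wt * (w_P / 2.0 - wt) * (w_P - wt))
                for s in range(w_ee.shape[0]):
                    wt = wt_ee[s]
                    wt_ee[s] = wt + k_cons * (
                        w_ee[s] - wt
                        - Pdw * wt * (w_P / 2.0 - wt) * (w_P - wt))
    return -1


def _const_arrays(mp: ModelParams):
    pn, pp = mp.neuron, mp.plasticity
    cn = np.array([pn.dt, pn.tau_m, pn.U_rest, pn.U_exc, pn.U_inh,
                   pn.theta_rest, pn.theta_spike, pn.tau_thr, pn.tau_gaba,
                   pn.tau_a, pn.tau_ampa, pn.tau_nmda, pn.Delta_a,
                   pn.alpha])
    cp = np.array([pp.tau_d, pp.tau_f, pp.U_stp, pp.eta_exc, pp.A, pp.beta,
                   pp.delta, pp.tau_plus, pp.tau_minus, pp.tau_slow,
                   pp.tau_ht, pp.tau_hom, pp.eta_inh, pp.gamma, pp.tau_H,
                   pp.tau_istdp, pp.w_exc_min, pp.w_exc_max, pp.w_inh_min,
                   pp.w_inh_max, pp.tau_cons, pp.P, pp.w_P, pp.dt_long])
    return cn, cp


def run_interval(net: Network, state: NetworkState, duration: float,
                 rates: np.ndarray, seed: int, *,
                 plasticity: Optional[dict] = None,
                 blocked_stim: Optional[np.ndarray] = None,
                 blocked_exc: Optional[np.ndarray] = None,
                 blocked_inh: Optional[np.ndarray] = None,
                 forced_exc: Optional[np.ndarray] = None,
                 forced_rate: float = 0.0,
                 scripted_stim: Optional[np.ndarray] = None,
                 record_bins: bool = False,
                 record_spikes: bool = False,
                 max_spikes: int = 0) -> IntervalResult:
    """Advance the network ``duration`` seconds under fixed drive.

    ``rates`` is the per-stimulus-neuron Poisson rate vector (Hz);
    ``plasticity`` may switch off individual update terms
    (keys: exc, ltp, ltd, het, transmitter, istdp); blocked masks
    silence neuron output; ``forced_exc``/``forced_rate`` implement
    artificial reactivation.  Mutates ``state`` in place.
    """
    mp = net.params
    n = mp.network
    pn = mp.neuron
    pp = mp.plasticity
    n_steps = int(round(duration / pn.dt))
    pl = {"exc": True, "ltp": True, "ltd": True, "het": True,
          "transmitter": True, "istdp": True}
    if plasticity:
        pl.update(plasticity)
    cn, cp = _const_arrays(mp)
    flg = np.array([
        1 if pl["ltp"] else 0,
        1 if pl["ltd"] else 0,
        1 if pl["het"] else 0,
        1 if pl["transmitter"] else 0,
        1 if pl["istdp"] else 0,
        1 if pp.inhibitory_variant == "pre_only" else 0,
        1 if scripted_stim is not None else 0,
        1 if record_bins else 0,
        1 if record_spikes else 0,
        1 if forced_exc is not None else 0,
        1 if pl["exc"] else 0,
    ], dtype=np.int64)
    dt_long_steps = max(1, int(round(pp.dt_long / pn.dt)))
    bin_steps = max(1, int(round(mp.analysis.rate_bin / pn.dt)))
    n_bins = max(1, (n_steps + bin_steps - 1) // bin_steps)
    counts_e = np.zeros(n.N_exc, dtype=np.int64)
    counts_i = np.zeros(n.N_inh, dtype=np.int64)
    pop_bins = np.zeros(n_bins, dtype=np.int64)
    bins_e = np.zeros((n_bins if record_bins else 1, n.N_exc),
                      dtype=np.int32)
    if record_spikes:
        cap = max_spikes or int(duration * (n.N_stim + n.N_exc + n.N_inh)
                                * 100) + 1024
    else:
        cap = 0
    spk_step = np.zeros(cap, dtype=np.int64)
    spk_id = np.zeros(cap, dtype=np.int32)
    spk_n = np.zeros(1, dtype=np.int64)

    def mask(m, sz):
        return np.zeros(sz, dtype=bool) if m is None else \
            np.asarray(m, dtype=bool)

    scripted = scripted_stim.astype(np.uint8) if scripted_stim is not None \
        else _EMPTY_U8
    rates_dt = np.asarray(rates, dtype=np.float64) * pn.dt
    b_stim = mask(blocked_stim, n.N_stim)
    # group unblocked stimulus neurons by their (few) distinct rates
    free = np.nonzero(~b_stim)[0]
    vals, inv = np.unique(rates_dt[free], return_inverse=True)
    order = np.argsort(inv, kind="stable")
    cls_members = free[order].astype(np.int32)
    counts = np.bincount(inv, minlength=vals.shape[0])
    cls_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    cls_p = vals.astype(np.float64)
    st = state
    status = _run_kernel(
        n_steps, int(seed) & 0x7FFFFFFF, cn, cp, flg, dt_long_steps,
        net.ff.indptr, net.ff.post, net.ff.post_indptr,
        net.ff.syn_of_post, net.ff.pre_of_post,
        net.ee.indptr, net.ee.post, net.ee.post_indptr,
        net.ee.syn_of_post, net.ee.pre_of_post,
        net.ei.indptr, net.ei.post,
        net.ie.indptr, net.ie.post, net.ie.post_indptr,
        net.ie.syn_of_post, net.ie.pre_of_post,
        net.ii.indptr, net.ii.post,
        net.inh_plastic_mask,
        st.w_ff, st.wt_ff, st.w_ee, st.wt_ee, st.w_ei, st.w_ie, st.w_ii,
        st.U_e, st.th_e, st.ga_e, st.gn_e, st.gg_e, st.gad_e,
        st.U_i, st.th_i, st.ga_i, st.gn_i, st.gg_i, st.gad_i,
        st.u_s, st.x_s, st.u_e, st.x_e, st.zp_s, st.zp_e, st.zm_e,
        st.zs_e, st.zht_e, st.C_e, st.zi_pre, st.zi_post, st.H,
        st.cons_countdown,
        st.prev_s, st.prev_e, st.prev_i, st.prev_n,
        rates_dt, cls_p, cls_members, cls_ptr, scripted,
        b_stim, mask(blocked_exc, n.N_exc),
        mask(blocked_inh, n.N_inh),
        mask(forced_exc, n.N_exc), float(forced_rate) * pn.dt,
        counts_e, counts_i, pop_bins, bins_e, bin_steps,
        spk_step, spk_id, spk_n)
    if status >= 0:
        raise FloatingPointError(
            f"non-finite membrane voltage at step {int(status)}")
    spikes = None
    if record_spikes:
        m = int(spk_n[0])
        spikes = np.stack([spk_step[:m], spk_id[:m].astype(np.int64)],
                          axis=1)
    return IntervalResult(
        n_steps=n_steps, counts_e=counts_e, pop_bins=pop_bins,
        bins_e=bins_e if record_bins else None,
        spikes=spikes, counts_i=counts_i)
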