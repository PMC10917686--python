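"""The fused engine against a transparent Python mirror.

The mirror replays the engine's documented per-step contract with
plain Python loops over the same synapse tables, in the same order,
so the two paths must agree to floating-point identity on a scripted
stimulus.  This pins the compiled kernel to the reference semantics
of the dynamics and plasticity modules.
"""
import numpy as np
import pytest

from engramsim.engine import init_state, run_interval
from engramsim.network import build_network
from engramsim.stimuli import stimulus_rates

from conftest import tiny_params


def python_mirror(net, st, scripted, pl=None):
    """Advance a copy of ``st`` through ``scripted`` stimulus ticks."""
    mp = net.params
    pn, pp = mp.neuron, mp.plasticity
    n = mp.network
    dt = pn.dt
    pl = pl or {}
    ltp = pl.get("ltp", True)
    ltd = pl.get("ltd", True)
    het = pl.get("het", True)
    tra = pl.get("transmitter", True)
    istdp = pl.get("istdp", True)
    exc_on = pl.get("exc", True)

    lam = lambda tau: 1.0 - dt / tau
    d = {k: lam(getattr(pn, "tau_" + k))
         for k in ("gaba", "a", "ampa", "thr")}
    dz = {k: lam(getattr(pp, "tau_" + k))
          for k in ("plus", "minus", "slow", "ht", "istdp", "H", "hom")}
    k_nmda, k_m, k_thr = dt / pn.tau_nmda, dt / pn.tau_m, dt / pn.tau_thr
    k_d, k_f = dt / pp.tau_d, dt / pp.tau_f
    dt_long_steps = max(1, int(round(pp.dt_long / pn.dt)))
    k_cons = pp.dt_long / pp.tau_cons

    prev_s = list(np.asarray(st.prev_s[:st.prev_n[0]]))
    prev_e = list(np.asarray(st.prev_e[:st.prev_n[1]]))
    prev_i = list(np.asarray(st.prev_i[:st.prev_n[2]]))
    cons = int(st.cons_countdown[0])

    pre_of = {}
    for name, proj in (("ff", net.ff), ("ee", net.ee), ("ie", net.ie)):
        pre_of[name] = np.repeat(np.arange(proj.n_pre, dtype=np.int64),
                                 np.diff(proj.indptr))

    def clip_e(w):
        return min(max(w, pp.w_exc_min), pp.w_exc_max)

    def clip_i(w):
        return min(max(w, pp.w_inh_min), pp.w_inh_max)

    for step in range(scripted.shape[0]):
        # (1) decay
        st.ga_e *= d["ampa"]; st.gg_e *= d["gaba"]; st.gad_e *= d["a"]
        st.zp_e *= dz["plus"]; st.zm_e *= dz["minus"]
        st.zs_e *= dz["slow"]; st.zht_e *= dz["ht"]
        st.zi_post *= dz["istdp"]
        st.x_e += k_d * (1.0 - st.x_e); st.u_e += k_f * (pp.U_stp - st.u_e)
        st.ga_i *= d["ampa"]; st.gg_i *= d["gaba"]; st.gad_i *= d["a"]
        st.zi_pre *= dz["istdp"]
        st.zp_s *= dz["plus"]
        st.x_s += k_d * (1.0 - st.x_s); st.u_s += k_f * (pp.U_stp - st.u_s)
        st.H[0] *= dz["H"]
        G = st.H[0] - pp.gamma

        # (2a) presynaptic-spike pass
        for j in prev_s:
            rel = st.u_s[j] * st.x_s[j]
            for s in range(net.ff.indptr[j], net.ff.indptr[j + 1]):
                i = net.ff.post[s]
                st.ga_e[i] += st.w_ff[s] * rel
                if exc_on:
                    w = st.w_ff[s]
                    if ltd:
                        w -= pp.eta_exc * (pp.A * min(st.C_e[i], 1.0)) \
                            * st.zm_e[i]
                    if tra:
                        w += pp.delta
                    st.w_ff[s] = clip_e(w)
        for j in prev_e:
            rel = st.u_e[j] * st.x_e[j]
            for s in range(net.ee.indptr[j], net.ee.indptr[j + 1]):
                i = net.ee.post[s]
                st.ga_e[i] += st.w_ee[s] * rel
                if exc_on:
                    w = st.w_ee[s]
                    if ltd:
                        w -= pp.eta_exc * (pp.A * min(st.C_e[i], 1.0)) \
                            * st.zm_e[i]
                    if tra:
                        w += pp.delta
                    st.w_ee[s] = clip_e(w)
            for s in range(net.ei.indptr[j], net.ei.indptr[j + 1]):
                st.ga_i[net.ei.post[s]] += st.w_ei[s] * rel
            st.gad_e[j] += pn.Delta_a
        for j in prev_i:
            for s in range(net.ie.indptr[j], net.ie.indptr[j + 1]):
                i = net.ie.post[s]
                st.gg_e[i] += st.w_ie[s]
                if istdp and net.inh_plastic_mask[j]:
                    dw = pp.eta_inh * G * (st.zi_post[i] + 1.0) \
                        if pp.inhibitory_variant == "full" \
                        else pp.eta_inh * G
                    st.w_ie[s] = clip_i(st.w_ie[s] + dw)
            for s in range(net.ii.indptr[j], net.ii.indptr[j + 1]):
                st.gg_i[net.ii.post[s]] += st.w_ii[s]
            st.gad_i[j] += pn.Delta_a

        # (2b) postsynaptic-spike pass
        for i in prev_e:
            if exc_on:
                zm3 = st.zm_e[i] ** 3
                for name, proj, w_arr, wt_arr, zp in (
                        ("ff", net.ff, st.w_ff, st.wt_ff, st.zp_s),
                        ("ee", net.ee, st.w_ee, st.wt_ee, st.zp_e)):
                    for t in range(proj.post_indptr[i],
                                   proj.post_indptr[i + 1]):
                        s = proj.syn_of_post[t]
                        jj = proj.pre_of_post[t]
                        w = w_arr[s]
                        if ltp:
                            w += pp.eta_exc * pp.A * zp[jj] * st.zs_e[i]
                        if het:
                            w -= pp.beta * (w - wt_arr[s]) * zm3
                        w_arr[s] = clip_e(w)
            if istdp and pp.inhibitory_variant == "full":
                for t in range(net.ie.post_indptr[i],
                               net.ie.post_indptr[i + 1]):
                    s = net.ie.syn_of_post[t]
                    jj = net.ie.pre_of_post[t]
                    if net.inh_plastic_mask[jj]:
                        st.w_ie[s] = clip_i(
                            st.w_ie[s] + pp.eta_inh * G * st.zi_pre[jj])

        # (2c) increments
        for j in prev_s:
            rel = st.u_s[j] * st.x_s[j]
            st.x_s[j] -= rel
            st.u_s[j] += pp.U_stp * (1.0 - st.u_s[j])
            st.zp_s[j] += 1.0
        for i in prev_e:
            rel = st.u_e[i] * st.x_e[i]
            st.x_e[i] -= rel
            st.u_e[i] += pp.U_stp * (1.0 - st.u_e[i])
            st.zp_e[i] += 1.0
            st.zm_e[i] += 1.0
            st.zs_e[i] += 1.0
            st.zht_e[i] += 1.0
            st.zi_post[i] += 1.0
        for j in prev_i:
            st.zi_pre[j] += 1.0
        st.H[0] += len(prev_e)

        # (3) homeostatic C, membranes, detection
        new_e = []
        for i in range(n.N_exc):
            st.C_e[i] = st.C_e[i] * dz["hom"] + dt * st.zht_e[i] ** 2
            st.gn_e[i] += k_nmda * (st.ga_e[i] - st.gn_e[i])
            gex = pn.alpha * st.ga_e[i] + (1.0 - pn.alpha) * st.gn_e[i]
            U = st.U_e[i] + k_m * (
                (pn.U_rest - st.U_e[i])
                + gex * (pn.U_exc - st.U_e[i])
                + (st.gg_e[i] + st.gad_e[i]) * (pn.U_inh - st.U_e[i]))
            th = st.th_e[i] + k_thr * (pn.theta_rest - st.th_e[i])
            if U > th:
                U, th = pn.U_rest, pn.theta_spike
                new_e.append(i)
            st.U_e[i] = U
            st.th_e[i] = th
        new_i = []
        for i in range(n.N_inh):
            st.gn_i[i] += k_nmda * (st.ga_i[i] - st.gn_i[i])
            gex = pn.alpha * st.ga_i[i] + (1.0 - pn.alpha) * st.gn_i[i]
            U = st.U_i[i] + k_m * (
                (pn.U_rest - st.U_i[i])
                + gex * (pn.U_exc - st.U_i[i])
                + (st.gg_i[i] + st.gad_i[i]) * (pn.U_inh - st.U_i[i]))
            th = st.th_i[i] + k_thr * (pn.theta_rest - st.th_i[i])
            if U > th:
                U, th = pn.U_rest, pn.theta_spike
                new_i.append(i)
            st.U_i[i] = U
            st.th_i[i] = th

        # (4) scripted stimulus spikes for the next step
        prev_s = list(np.nonzero(scripted[step])[0])
        prev_e, prev_i = new_e, new_i

        # (5) reference-weight slow tick
        cons -= 1
        if cons <= 0:
            cons = dt_long_steps
            if exc_on:
                for w_arr, wt_arr in ((st.w_ff, st.wt_ff),
                                      (st.w_ee, st.wt_ee)):
                    for s in range(w_arr.shape[0]):
                        wt = wt_arr[s]
                        wt_arr[s] = wt + k_cons * (
                            w_arr[s] - wt
                            - pp.P * wt * (pp.w_P / 2.0 - wt)
                            * (pp.w_P - wt))
    st.prev_n[0] = len(prev_s)
    st.prev_s[:len(prev_s)] = prev_s
    st.prev_n[1] = len(prev_e)
    st.prev_e[:len(prev_e)] = prev_e
    st.prev_n[2] = len(prev_i)
    st.prev_i[:len(prev_i)] = prev_i
    st.cons_countdown[0] = cons
    return st


def scripted_stimulus(mp, n_steps, rate, seed):
    rng = np.random.default_rng(seed)
    return (rng.random((n_steps, mp.network.N_stim))
            < rate * mp.neuron.dt).astype(np.uint8)


@pytest.mark.parametrize("pl", [None, {"ltp": False, "istdp": False}])
def test_engine_matches_python_mirror(pl):
    """0.3 s of scripted drive: every state variable agrees between
    the compiled kernel and the Python mirror."""
    mp = tiny_params(**{"plasticity.A": 5e-3, "plasticity.eta_inh": 1e-4,
                        "plasticity.gamma": 50.0, "plasticity.tau_H": 0.5,
                        "network.w_stim": 3.0})
    mp.plasticity.dt_long = 0.05
    net = build_network(mp, 1)
    n_steps = 3000
    scripted = scripted_stimulus(mp, n_steps, 40.0, 9)

    st_engine = init_state(net)
    rates = stimulus_rates(None, mp.network.N_stim, 5.0, 35.0)
    res = run_interval(net, st_engine, n_steps * mp.neuron.dt, rates, 3,
                       scripted_stim=scripted, plasticity=pl)
    assert res.counts_e.sum() > 0, "test network must actually spike"

    st_mirror = python_mirror(net, init_state(net), scripted, pl)

    for name in ("U_e", "th_e", "ga_e", "gn_e", "gg_e", "gad_e",
                 "U_i", "ga_i", "gg_i", "u_s", "x_s", "u_e", "x_e",
                 "zp_s", "zp_e", "zm_e", "zs_e", "zht_e", "C_e",
                 "zi_pre", "zi_post", "H", "w_ff", "wt_ff", "w_ee",
                 "wt_ee", "w_ie"):
        a = getattr(st_engine, name)
        b = getattr(st_mirror, name)
        np.testing.assert_allclose(
            a, b, rtol=1e-12, atol=1e-12,
            err_msg=f"engine/mirror mismatch in {name}")


def test_engine_deterministic_given_seed():
    mp = tiny_params()
    net = build_network(mp, 2)
    rates = stimulus_rates(None, mp.network.N_stim, 8.0, 35.0)
    outs = []
    for _ in range(2):
        st = init_state(net)
        res = run_interval(net, st, 1.0, rates, 42)
        outs.append((res.counts_e.copy(), st.w_ee.copy(), st.U_e.copy()))
    assert np.array_equal(outs[0][0], outs[1][0])
    assert np.array_equal(outs[0][1], outs[1][1])
    assert np.array_equal(outs[0][2], outs[1][2])


def test_conductances_stay_nonnegative_under_drive():
    mp = tiny_params(**{"network.w_stim": 4.0})
    net = build_network(mp, 3)
    st = init_state(net)
    rates = stimulus_rates(None, mp.network.N_stim, 50.0, 50.0)
    run_interval(net, st, 2.0, rates, 5)
    for g in (st.ga_e, st.gn_e, st.gg_e, st.gad_e,
              st.ga_i, st.gn_i, st.gg_i, st.gad_i):
        assert np.all(g >= 0.0)


def test_silent_input_produces_no_spikes():
    mp = tiny_params()
    net = build_network(mp, 4)
    st = init_state(net)
    res = run_interval(net, st, 1.0,
                       np.zeros(mp.network.N_stim), 6)
    assert res.counts_e.sum() == 0
    assert res.counts_i.sum() == 0


def test_blocked_neurons_emit_nothing():
    mp = tiny_params(**{"network.w_stim": 4.0})
    net = build_network(mp, 5)
    st = init_state(net)
    rates = stimulus_rates(None, mp.network.N_stim, 50.0, 50.0)
    blocked = np.ones(mp.network.N_exc, dtype=bool)
    res = run_interval(net, st, 1.0, rates, 7, blocked_exc=blocked)
    assert res.counts_e.sum() == 0


def test_forced_neurons_fire_at_requested_rate():
    mp = tiny_params()
    net = build_network(mp, 6)
    st = init_state(net)
    forced = np.zeros(mp.network.N_exc, dtype=bool)
    forced[:8] = True
    res = run_interval(net, st, 10.0, np.zeros(mp.network.N_stim), 8,
                       forced_exc=forced, forced_rate=30.0)
    rate = res.counts_e[:8].mean() / 10.0
    assert rate == pytest.approx(30.0, rel=0.15)
    assert res.counts_e[8:].sum() == 0


def test_spike_recording_roundtrip():
    mp = tiny_params(**{"network.w_stim": 4.0})
    net = build_network(mp, 7)
    st = init_state(net)
    rates = stimulus_rates(None, mp.network.N_stim, 40.0, 40.0)
    res = run_interval(net, st, 1.0, rates, 9, record_spikes=True)
    spk = res.spikes
    assert spk is not None and spk.shape[0] > 0
    # counts derived from the raster agree with the counters
    n_stim = mp.network.N_stim
    exc_ids = spk[(spk[:, 1] >= n_stim)
                  & (spk[:, 1] < n_stim + mp.network.N_exc), 1] - n_stim
    counts = np.bincount(exc_ids, minlength=mp.network.N_exc)
    assert np.array_equal(counts, res.counts_e)
    # steps sorted within the raster
    assert np.all(np.diff(spk[:, 0]) >= 0)
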