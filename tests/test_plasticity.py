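"""Plasticity rules against event-driven closed-form oracles.

The clock-driven reference updates (one Euler step per 0.1 ms tick)
must agree with an independent event-driven implementation that jumps
between spike events using closed-form geometric decay of every trace
(lambda = 1 - dt/tau per tick, applied as lambda**n between events).
Agreement is to 1e-9 relative on scripted spike trains.
"""
import numpy as np
import pytest

from engramsim.params import PlasticityParams
from engramsim.plasticity import (consolidate_reference_step, decay_trace,
                                  excitatory_plasticity_step,
                                  global_factor_step,
                                  inhibitory_plasticity_step, ltd_rate,
                                  ltd_rate_step, stp_decay, stp_spike,
                                  stp_step)

DT = 1e-4


def random_train(rng, n_steps, rate_hz):
    return rng.random(n_steps) < rate_hz * DT


# --------------------------------------------------------------- STP

class StpOracle:
    """Event-driven STP with closed-form relaxation between spikes.

    Between spikes x relaxes to 1 and u to U with their Euler decay
    factors; a spike consumes u*x of the resource and facilitates u.
    """

    def __init__(self, p: PlasticityParams):
        self.p = p
        self.u, self.x = p.U_stp, 1.0
        self.lam_d = 1.0 - DT / p.tau_d
        self.lam_f = 1.0 - DT / p.tau_f

    def advance(self, n):
        self.x = 1.0 - (1.0 - self.x) * self.lam_d ** n
        self.u = self.p.U_stp - (self.p.U_stp - self.u) * self.lam_f ** n

    def spike(self):
        rel = self.u * self.x
        self.x -= rel
        self.u += self.p.U_stp * (1.0 - self.u)
        return rel


def test_stp_relaxes_to_fixed_point():
    p = PlasticityParams()
    u = np.array([0.9])
    x = np.array([0.1])
    for _ in range(int(16 * max(p.tau_d, p.tau_f) / DT)):
        u, x = stp_decay(u, x, p, DT)
    assert u[0] == pytest.approx(p.U_stp, abs=1e-6)
    assert x[0] == pytest.approx(1.0, abs=1e-6)


def test_stp_single_spike_jumps():
    p = PlasticityParams()
    u, x, rel = stp_spike(np.array([p.U_stp]), np.array([1.0]),
                          np.array([True]), p)
    assert rel[0] == pytest.approx(p.U_stp)
    assert x[0] == pytest.approx(1.0 - p.U_stp)
    assert u[0] == pytest.approx(p.U_stp + p.U_stp * (1 - p.U_stp))


def test_stp_50hz_train_matches_event_oracle():
    p = PlasticityParams()
    period = int(0.02 / DT)       # 50 Hz
    n_spikes = 12
    u = np.array([p.U_stp])
    x = np.array([1.0])
    oracle = StpOracle(p)
    releases, oracle_rel, xs = [], [], []
    step = 0
    for k in range(n_spikes):
        target = k * period
        while step < target:
            u, x = stp_decay(u, x, p, DT)
            step += 1
        u, x, r = stp_spike(u, x, np.array([True]), p)
        releases.append(r[0])
        xs.append(x[0])
        oracle.advance(period if k else 0)
        oracle_rel.append(oracle.spike())
    np.testing.assert_allclose(releases, oracle_rel, rtol=1e-9)
    # the available resource x is strictly depressed spike by spike
    assert all(b < a for a, b in zip(xs[:4], xs[1:5]))


# ------------------------------------------------- homeostatic LTD rate

def test_ltd_rate_branches():
    p = PlasticityParams()
    assert ltd_rate(np.array([2.0]), p)[0] == pytest.approx(p.A)
    assert ltd_rate(np.array([0.5]), p)[0] == pytest.approx(0.5 * p.A)


def test_silent_neuron_ltd_rate_decays_to_zero():
    p = PlasticityParams()
    C = np.array([3.0])
    z = np.array([0.0])
    for _ in range(int(12 * p.tau_hom / DT / 100)):
        # larger effective step for speed: decay 100 ticks at once
        C = C * (1.0 - DT / p.tau_hom) ** 100
    C, B = ltd_rate_step(C, z, p, DT)
    assert B[0] < 1e-4 * p.A


def test_homeostatic_variable_matches_closed_form():
    """With a silent trace decaying from z0, C follows the geometric
    convolution of z^2 exactly."""
    p = PlasticityParams(tau_hom=2.0, tau_ht=0.1)
    lam = 1.0 - DT / p.tau_ht
    mu = 1.0 - DT / p.tau_hom
    z0, C0, n = 2.0, 0.3, 5000
    C = np.array([C0])
    z = np.array([z0])
    for _ in range(n):
        z = decay_trace(z, p.tau_ht, DT)
        C, _ = ltd_rate_step(C, z, p, DT)
    expected = C0 * mu ** n + DT * z0 ** 2 * lam ** 2 * \
        (lam ** (2 * n) - mu ** n) / (lam ** 2 - mu)
    assert C[0] == pytest.approx(expected, rel=1e-9)


# ------------------------------------- long-term excitatory plasticity

class ExcOracle:
    """Event-driven triplet + heterosynaptic + transmitter oracle for
    one synapse, with closed-form trace decay between events.

    ``advance(n)`` jumps over n silent clock ticks in closed form
    (traces decay geometrically; the homeostatic integral C follows
    the geometric convolution of z_ht^2); ``event`` performs the one
    tick that contains the spikes, reading traces that exclude those
    spikes and completing the tick's C update afterwards.
    """

    def __init__(self, p: PlasticityParams, w0, wt0):
        self.p = p
        self.w, self.wt = w0, wt0
        self.zp = self.zm = self.zs = self.zht = 0.0
        self.C = 0.0
        self.lam = {x: 1.0 - DT / getattr(p, f"tau_{x}")
                    for x in ("plus", "minus", "slow", "ht", "hom")}

    def advance(self, n):
        lam, mu = self.lam["ht"], self.lam["hom"]
        if n > 0:
            self.C = self.C * mu ** n + DT * self.zht ** 2 * lam ** 2 * \
                (lam ** (2 * n) - mu ** n) / (lam ** 2 - mu)
            self.zp *= self.lam["plus"] ** n
            self.zm *= self.lam["minus"] ** n
            self.zs *= self.lam["slow"] ** n
            self.zht *= lam ** n

    def event(self, pre, post):
        p = self.p
        self.zp *= self.lam["plus"]     # the event tick's own decay
        self.zm *= self.lam["minus"]
        self.zs *= self.lam["slow"]
        self.zht *= self.lam["ht"]
        if pre:
            B = p.A * min(self.C, 1.0)
            self.w -= p.eta_exc * B * self.zm
            self.w += p.delta
            self.w = np.clip(self.w, p.w_exc_min, p.w_exc_max)
        if post:
            self.w += p.eta_exc * p.A * self.zp * self.zs
            self.w -= p.beta * (self.w - self.wt) * self.zm ** 3
            self.w = np.clip(self.w, p.w_exc_min, p.w_exc_max)
        if pre:
            self.zp += 1.0
        if post:
            self.zm += 1.0
            self.zs += 1.0
            self.zht += 1.0
        self.C = self.C * self.lam["hom"] + DT * self.zht ** 2


def clock_exc(p, pre_train, post_train, w0, wt0):
    """Clock-driven path composed from the reference per-step ops."""
    w = np.array([[w0]])
    wt = np.array([[wt0]])
    zp = np.zeros(1)
    zm = np.zeros(1)
    zs = np.zeros(1)
    zht = np.zeros(1)
    C = np.zeros(1)
    for s_pre, s_post in zip(pre_train, post_train):
        zp = decay_trace(zp, p.tau_plus, DT)
        zm = decay_trace(zm, p.tau_minus, DT)
        zs = decay_trace(zs, p.tau_slow, DT)
        zht = decay_trace(zht, p.tau_ht, DT)
        B = ltd_rate(C, p)
        w = excitatory_plasticity_step(
            w, wt, zp, zm, zs, B, np.array([s_pre]), np.array([s_post]), p)
        if s_pre:
            zp += 1.0
        if s_post:
            zm += 1.0
            zs += 1.0
            zht += 1.0
        C, _ = ltd_rate_step(C, zht, p, DT)
    return w[0, 0]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_excitatory_rule_matches_event_oracle(seed):
    """Random scripted pre/post trains: clock path equals the
    event-driven closed-form oracle to 1e-9 relative."""
    rng = np.random.default_rng(seed)
    p = PlasticityParams(A=5e-3, beta=0.05, delta=1e-4)
    n = 4000
    pre = random_train(rng, n, 40.0)
    post = random_train(rng, n, 40.0)
    w_clock = clock_exc(p, pre, post, 0.3, 0.3)

    oracle = ExcOracle(p, 0.3, 0.3)
    last = -1
    events = np.nonzero(pre | post)[0]
    for t in events:
        oracle.advance(t - last - 1)   # silent ticks between events
        last = t
        oracle.event(bool(pre[t]), bool(post[t]))
    assert w_clock == pytest.approx(oracle.w, rel=1e-9)


def test_paired_pre_post_at_10ms_potentiates():
    """Five 10 ms pre-then-post pairings at low rate potentiate."""
    p = PlasticityParams(A=5e-3, delta=0.0, beta=0.0)
    n = 5 * int(0.5 / DT)
    pre = np.zeros(n, dtype=bool)
    post = np.zeros(n, dtype=bool)
    for k in range(5):
        t0 = k * int(0.5 / DT)
        pre[t0] = True
        post[t0 + int(0.01 / DT)] = True
    assert clock_exc(p, pre, post, 0.3, 0.3) > 0.3


def test_isolated_pre_spike_adds_exactly_delta():
    p = PlasticityParams()
    w = excitatory_plasticity_step(
        np.array([[0.2]]), np.array([[0.2]]), np.zeros(1), np.zeros(1),
        np.zeros(1), np.zeros(1), np.array([True]), np.array([False]), p)
    assert w[0, 0] == pytest.approx(0.2 + p.delta)


def test_heterosynaptic_vanishes_at_reference():
    """A post spike with w = w~ leaves the heterosynaptic term inert."""
    p = PlasticityParams()
    w = excitatory_plasticity_step(
        np.array([[0.4]]), np.array([[0.4]]), np.zeros(1), np.full(1, 2.0),
        np.zeros(1), np.zeros(1), np.array([False]), np.array([True]), p,
        ltp_on=False)
    assert w[0, 0] == pytest.approx(0.4)


def test_missing_reference_weights_rejected():
    p = PlasticityParams()
    with pytest.raises(ValueError, match="reference"):
        excitatory_plasticity_step(
            np.array([[0.4]]), None, np.zeros(1), np.zeros(1),
            np.zeros(1), np.zeros(1), np.array([True]),
            np.array([False]), p)


def test_weights_never_leave_bounds():
    rng = np.random.default_rng(3)
    p = PlasticityParams(A=0.5, beta=0.5, delta=0.1,
                         w_exc_min=0.0, w_exc_max=1.0)
    w = np.full((2, 2), 0.5)
    wt = np.full((2, 2), 0.5)
    zp = np.zeros(2)
    zm = np.zeros(2)
    zs = np.zeros(2)
    for _ in range(500):
        zp = decay_trace(zp, p.tau_plus, DT) + rng.random(2)
        zm = decay_trace(zm, p.tau_minus, DT) + rng.random(2)
        zs = decay_trace(zs, p.tau_slow, DT) + rng.random(2)
        w = excitatory_plasticity_step(
            w, wt, zp, zm, zs, np.full(2, p.A), rng.random(2) < 0.5,
            rng.random(2) < 0.5, p)
        assert np.all((w >= 0.0) & (w <= 1.0))


# ------------------------------------------ reference-weight dynamics

def test_reference_weight_zero_is_fixed_point():
    p = PlasticityParams()
    wt = consolidate_reference_step(np.zeros(3), np.zeros(3), p)
    assert np.all(wt == 0.0)


def test_reference_weight_converges_to_cubic_root():
    """With w clamped far above w~, the reference weight settles at
    the high root of w - wt = P wt (wP/2 - wt)(wP - wt)."""
    p = PlasticityParams(tau_cons=100.0, dt_long=1.0, P=20.0, w_P=0.5)
    w = 0.8
    wt = 0.0
    for _ in range(5000):
        wt = consolidate_reference_step(np.array([w]),
                                        np.array([wt]), p)[0]
    roots = np.roots([p.P, -1.5 * p.P * p.w_P,
                      p.P * p.w_P ** 2 / 2.0 + 1.0, -w])
    real = roots[np.abs(roots.imag) < 1e-9].real
    high = real.max()
    assert wt == pytest.approx(high, rel=1e-6)


def test_reference_drift_follows_double_well():
    """With w = w~ the relaxation term vanishes and the cubic term
    alone sets the drift: w~ = w_P is a fixed point, values above the
    midpoint w_P/2 drift up toward it, values below drift to zero."""
    p = PlasticityParams()
    wP = p.w_P
    at_top = consolidate_reference_step(np.array([wP]), np.array([wP]), p)[0]
    assert at_top == pytest.approx(wP, abs=1e-15)
    hi = 0.6 * wP
    lo = 0.4 * wP
    assert consolidate_reference_step(np.array([hi]),
                                      np.array([hi]), p)[0] > hi
    assert consolidate_reference_step(np.array([lo]),
                                      np.array([lo]), p)[0] < lo


# --------------------------------------------- inhibitory plasticity

class InhOracle:
    """Event-driven oracle of the activity-gated inhibitory rule for
    one synapse; H is driven by a scripted excitatory population
    count per tick."""

    def __init__(self, p, w0, variant):
        self.p, self.w, self.variant = p, w0, variant
        self.zpre = self.zpost = 0.0
        self.lam = 1.0 - DT / p.tau_istdp

    def advance(self, n):
        self.zpre *= self.lam ** n
        self.zpost *= self.lam ** n

    def event(self, pre, post, G):
        p = self.p
        dw = 0.0
        if self.variant == "full":
            if pre:
                dw += p.eta_inh * G * (self.zpost + 1.0)
            if post:
                dw += p.eta_inh * G * self.zpre
        elif pre:
            dw += p.eta_inh * G
        self.w = np.clip(self.w + dw, p.w_inh_min, p.w_inh_max)
        if pre:
            self.zpre += 1.0
        if post:
            self.zpost += 1.0


@pytest.mark.parametrize("variant", ["full", "pre_only"])
def test_inhibitory_rule_matches_event_oracle(variant):
    rng = np.random.default_rng(7)
    p = PlasticityParams(eta_inh=1e-3, gamma=10.0, tau_H=0.5)
    n = 3000
    pre = random_train(rng, n, 30.0)
    post = random_train(rng, n, 30.0)
    exc_counts = rng.poisson(2.0, size=n)

    w = np.array([[0.5]])
    zpre = np.zeros(1)
    zpost = np.zeros(1)
    H = p.gamma
    oracle = InhOracle(p, 0.5, variant)
    last = 0
    for t in range(n):
        zpre = decay_trace(zpre, p.tau_istdp, DT)
        zpost = decay_trace(zpost, p.tau_istdp, DT)
        H = H * (1.0 - DT / p.tau_H)
        G = H - p.gamma
        w = inhibitory_plasticity_step(
            w, zpre, zpost, np.array([pre[t]]), np.array([post[t]]),
            G, p, variant)
        if pre[t] or post[t]:
            oracle.advance(t - last)
            last = t
            oracle.event(bool(pre[t]), bool(post[t]), G)
        if pre[t]:
            zpre += 1.0
        if post[t]:
            zpost += 1.0
        H += exc_counts[t]
        # keep oracle's trace clock aligned even without events
    oracle.advance(n - last)
    assert w[0, 0] == pytest.approx(oracle.w, rel=1e-9)


def test_zero_drive_freezes_inhibitory_weights():
    p = PlasticityParams()
    w = inhibitory_plasticity_step(
        np.full((1, 1), 0.5), np.ones(1), np.ones(1),
        np.array([True]), np.array([True]), 0.0, p)
    assert w[0, 0] == 0.5


def test_below_target_pre_spike_depresses():
    p = PlasticityParams(eta_inh=1e-3)
    w = inhibitory_plasticity_step(
        np.full((1, 1), 0.5), np.zeros(1), np.zeros(1),
        np.array([True]), np.array([False]), -5.0, p)
    assert w[0, 0] < 0.5


def test_above_target_coincidence_beats_pre_alone():
    p = PlasticityParams(eta_inh=1e-3)
    zpost = np.full(1, 0.8)
    w_pair = inhibitory_plasticity_step(
        np.full((1, 1), 0.5), np.zeros(1), zpost,
        np.array([True]), np.array([True]), 5.0, p)[0, 0]
    w_pre = inhibitory_plasticity_step(
        np.full((1, 1), 0.5), np.zeros(1), np.zeros(1),
        np.array([True]), np.array([False]), 5.0, p)[0, 0]
    assert w_pair > w_pre > 0.5


def test_global_factor_integrates_population_spikes():
    p = PlasticityParams(tau_H=1.0)
    H = 0.0
    for _ in range(100):
        H = global_factor_step(H, 3, p, DT)
    assert H == pytest.approx(
        3 * (1 - (1 - DT / p.tau_H) ** 100) / (DT / p.tau_H), rel=1e-9)
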