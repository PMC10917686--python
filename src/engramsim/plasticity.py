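"""Reference implementations of the four plasticity systems.

Dense, transparent numpy versions of the per-step updates:

* short-term plasticity (depression ``x`` / facilitation ``u``, per
  presynaptic excitatory neuron, shared across its efferent synapses);
* long-term excitatory plasticity: triplet STDP with a homeostatically
  regulated LTD rate, heterosynaptic decay toward a reference weight,
  and a transmitter-induced increment per presynaptic spike;
* reference-weight consolidation on a double-well landscape, applied
  on a slow tick of period ``dt_long``;
* inhibitory STDP scaled by the global activity factor G = H - gamma
  (full pre+post+pre-only form, or the presynaptic-only variant).

Trace convention (the "epsilon" convention): every weight update
triggered by a spike reads trace values that reflect history strictly
before that spike; the spike increments its own traces afterwards.
Concretely the per-step order is: decay traces -> apply spike-triggered
weight updates with the decayed traces -> increment traces of the
spiking neurons.

The production engine repeats this arithmetic verbatim in a numba
kernel; the event-driven oracles in the test suite check both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .params import PlasticityParams

__all__ = [
    "decay_trace",
    "stp_decay",
    "stp_spike",
    "stp_step",
    "excitatory_plasticity_step",
    "ltd_rate",
    "ltd_rate_step",
    "consolidate_reference_step",
    "inhibitory_plasticity_step",
    "global_factor_step",
]


def decay_trace(z: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """One Euler decay step of an exponential spike trace."""
    return z * (1.0 - dt / tau)


def stp_decay(u: np.ndarray, x: np.ndarray,
              p: PlasticityParams, dt: float) -> Tuple[np.ndarray, np.ndarray]:
    """Relaxation of the STP variables between spikes."""
    x = x + (dt / p.tau_d) * (1.0 - x)
    u = u + (dt / p.tau_f) * (p.U_stp - u)
    return u, x


def stp_spike(u: np.ndarray, x: np.ndarray, spiked: np.ndarray,
              p: PlasticityParams) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spike-triggered STP jumps; returns (u, x, release).

    The release factor u*x is evaluated before the jumps (the spike
    consumes resources and facilitates subsequent release).
    """
    s = spiked.astype(float)
    release = u * x * s
    x = x - release
    u = u + p.U_stp * (1.0 - u) * s
    return u, x, release


def stp_step(u: np.ndarray, x: np.ndarray, spiked: np.ndarray,
             p: PlasticityParams, dt: float
             ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full STP step: decay, then spike jumps.  Returns (u, x, release)."""
    u, x = stp_decay(u, x, p, dt)
    return stp_spike(u, x, spiked, p)


def ltd_rate(C: np.ndarray, p: PlasticityParams) -> np.ndarray:
    """Homeostatically regulated LTD rate: B = A * min(C, 1)."""
    return p.A * np.minimum(C, 1.0)


def ltd_rate_step(C: np.ndarray, z_ht: np.ndarray,
                  p: PlasticityParams, dt: float
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Advance the homeostatic variable C one step and return (C, B).

    ``z_ht`` is the post-trace after this step's spike increments.
    """
    C = C * (1.0 - dt / p.tau_hom) + dt * z_ht * z_ht
    return C, ltd_rate(C, p)


def excitatory_plasticity_step(w: np.ndarray, w_tilde: np.ndarray,
                               z_plus_pre: np.ndarray,
                               z_minus_post: np.ndarray,
                               z_slow_post: np.ndarray,
                               B_post: np.ndarray,
                               pre_spiked: np.ndarray,
                               post_spiked: np.ndarray,
                               p: PlasticityParams,
                               ltp_on: bool = True, ltd_on: bool = True,
                               het_on: bool = True,
                               transmitter_on: bool = True) -> np.ndarray:
    """Spike-triggered long-term excitatory updates on a dense matrix.

    ``w`` has shape (n_post, n_pre); traces are the decayed values of
    this step, before the increments of the triggering spikes.  The
    learning-rate multiplier scales only the triplet terms; the
    heterosynaptic and transmitter-induced terms stand outside it.
    """
    if w_tilde is None:
        raise ValueError("plastic excitatory synapses require reference "
                         "weights w_tilde")
    S_pre = pre_spiked.astype(float)
    S_post = post_spiked.astype(float)
    # presynaptic spike: triplet LTD + transmitter-induced increment
    if ltd_on:
        w = w - p.eta_exc * np.outer(B_post * z_minus_post, S_pre)
    if transmitter_on:
        w = w + p.delta * S_pre[None, :]
    w = np.clip(w, p.w_exc_min, p.w_exc_max)
    # postsynaptic spike: triplet LTP + heterosynaptic decay
    if ltp_on:
        w = w + p.eta_exc * p.A * np.outer(S_post * z_slow_post, z_plus_pre)
    if het_on:
        w = w - p.beta * (w - w_tilde) * (S_post * z_minus_post ** 3)[:, None]
    return np.clip(w, p.w_exc_min, p.w_exc_max)


def consolidate_reference_step(w: np.ndarray, w_tilde: np.ndarray,
                               p: PlasticityParams) -> np.ndarray:
    """One slow-tick Euler step of the reference weights.

    The reference weight relaxes toward the plastic weight while
    descending a double-well potential with midpoint ``w_P``; with the
    default midpoint 0.5 the wells sit near 0 and near w ~= w_tilde,
    giving synapses a bistable consolidated state.
    """
    drift = (w - w_tilde
             - p.P * w_tilde * (p.w_P / 2.0 - w_tilde) * (p.w_P - w_tilde))
    return w_tilde + (p.dt_long / p.tau_cons) * drift


def global_factor_step(H: float, n_exc_spikes: int,
                       p: PlasticityParams, dt: float) -> float:
    """Advance the low-pass-filtered excitatory population activity H."""
    return H * (1.0 - dt / p.tau_H) + n_exc_spikes


def inhibitory_plasticity_step(w: np.ndarray,
                               z_pre: np.ndarray, z_post: np.ndarray,
                               pre_spiked: np.ndarray,
                               post_spiked: np.ndarray,
                               G: float, p: PlasticityParams,
                               variant: str = "full") -> np.ndarray:
    """Network-activity-gated inhibitory STDP on a dense (post, pre) matrix.

    ``G = H - gamma`` is read before this step's spike increments.
    With the network below its activity target (G < 0) the rule is
    depression-only; above target it is Hebbian.  The ``pre_only``
    variant retains just the presynaptic-spike term.
    """
    S_pre = pre_spiked.astype(float)
    S_post = post_spiked.astype(float)
    if variant == "full":
        dw = (np.outer(S_post, z_pre)
              + np.outer(z_post, S_pre)
              + np.ones_like(z_post)[:, None] * S_pre[None, :])
    elif variant == "pre_only":
        dw = np.ones_like(z_post)[:, None] * S_pre[None, :]
    else:
        raise ValueError(f"unknown inhibitory variant {variant!r}")
    w = w + p.eta_inh * G * dw
    return np.clip(w, p.w_inh_min, p.w_inh_max)
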