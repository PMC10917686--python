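"""Reference clock-driven neuron dynamics.

These functions define the per-step semantics of the simulator on
plain numpy arrays: one forward-Euler step of the conductance-based
LIF model with adaptive threshold.  The production engine
(:mod:`engramsim.engine`) implements the identical arithmetic in a
fused numba kernel; a consistency test holds the two paths together.

Update contract for one step of length ``dt`` (spikes emitted in step
t are delivered in step t+1, i.e. a one-step synaptic delay):

1. conductances decay, then delivered spikes add their increments
   (AMPA/GABA jumps use the weights, and for excitatory synapses the
   short-term-plasticity release factor u*x evaluated before the
   spike's own STP update);
2. the NMDA conductance low-pass filters the updated AMPA conductance;
3. the membrane and threshold advance one Euler step;
4. neurons whose voltage strictly exceeds the threshold spike and are
   reset (U <- U_rest, theta <- theta_spike).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import NeuronParams

__all__ = ["NeuronStateArrays", "step_conductances", "step_membrane"]


@dataclass
class NeuronStateArrays:
    """Dynamic variables of one neuron population."""

    U: np.ndarray
    theta: np.ndarray
    g_ampa: np.ndarray
    g_nmda: np.ndarray
    g_gaba: np.ndarray
    g_a: np.ndarray
    spiked: np.ndarray = field(default=None)

    @classmethod
    def zeros(cls, n: int, p: NeuronParams) -> "NeuronStateArrays":
        return cls(U=np.full(n, p.U_rest), theta=np.full(n, p.theta_rest),
                   g_ampa=np.zeros(n), g_nmda=np.zeros(n),
                   g_gaba=np.zeros(n), g_a=np.zeros(n),
                   spiked=np.zeros(n, dtype=bool))


def step_conductances(state: NeuronStateArrays, p: NeuronParams,
                      exc_increment: Optional[np.ndarray] = None,
                      inh_increment: Optional[np.ndarray] = None,
                      own_prev_spiked: Optional[np.ndarray] = None,
                      ) -> NeuronStateArrays:
    """Advance all conductances one step.

    ``exc_increment`` is the summed AMPA jump per neuron,
    sum_j w_ij u_j x_j over delivered excitatory spikes;
    ``inh_increment`` is sum_j w_ij over delivered inhibitory spikes;
    ``own_prev_spiked`` marks neurons whose own spike of the previous
    step triggers the adaptation increment.

    Negative increments are rejected: weights of excitatory and
    inhibitory matrices are non-negative by construction.
    """
    dt = p.dt
    for inc in (exc_increment, inh_increment):
        if inc is not None and np.any(inc < 0):
            raise ValueError("negative synaptic increment: weights of an "
                             "excitatory/inhibitory matrix must be >= 0")
    state.g_gaba *= 1.0 - dt / p.tau_gaba
    state.g_a *= 1.0 - dt / p.tau_a
    state.g_ampa *= 1.0 - dt / p.tau_ampa
    if inh_increment is not None:
        state.g_gaba += inh_increment
    if own_prev_spiked is not None:
        state.g_a += p.Delta_a * own_prev_spiked
    if exc_increment is not None:
        state.g_ampa += exc_increment
    # NMDA low-pass filters the post-delivery AMPA conductance
    state.g_nmda += (dt / p.tau_nmda) * (state.g_ampa - state.g_nmda)
    return state


def step_membrane(state: NeuronStateArrays, p: NeuronParams,
                  step_index: int = 0) -> NeuronStateArrays:
    """One Euler step of membrane and threshold, with spike detection.

    Raises ``FloatingPointError`` (with the step index) if any state
    variable is non-finite, which indicates a diverged integration.
    """
    dt = p.dt
    g_exc = p.alpha * state.g_ampa + (1.0 - p.alpha) * state.g_nmda
    dU = ((p.U_rest - state.U)
          + g_exc * (p.U_exc - state.U)
          + (state.g_gaba + state.g_a) * (p.U_inh - state.U))
    state.U = state.U + (dt / p.tau_m) * dU
    state.theta = state.theta + (dt / p.tau_thr) * (p.theta_rest - state.theta)
    if not np.all(np.isfinite(state.U)):
        raise FloatingPointError(
            f"non-finite membrane voltage at step {step_index}")
    spiked = state.U > state.theta
    state.U = np.where(spiked, p.U_rest, state.U)
    state.theta = np.where(spiked, p.theta_spike, state.theta)
    state.spiked = spiked
    return state
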