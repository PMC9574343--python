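"""Membrane dynamics and spike-timing-dependent plasticity (STDP).

The readout neuron is a current-based leaky integrate-and-fire unit. Each
presynaptic spike injects a stereotyped excitatory postsynaptic potential
(EPSP), a peak-normalized double exponential with membrane time constant
``tau_m`` and synaptic rise time ``tau_s``:

    K(t) = c * (exp(-t / tau_m) - exp(-t / tau_s)),   t >= 0,

with ``c`` chosen so that ``max_t K(t) = 1``.  The membrane potential is the
weighted sum of EPSPs plus an optional tonic drive and an optional sinusoidal
subthreshold oscillation; a spike is emitted when the potential reaches
threshold outside the absolute refractory period, after which the synaptic
traces are cleared (spike reset) and input arriving during the refractory
period does not contribute to the potential.

Synaptic efficacies evolve under the classical additive STDP rule: a
presynaptic spike that precedes the postsynaptic spike by ``dt >= 0``
potentiates the synapse by ``a_plus * exp(-dt / tau_plus)``; the reverse
order depresses it by ``a_minus * exp(dt / tau_minus)`` (``dt < 0``).
Exact coincidence (``dt == 0``) is assigned to the potentiation branch.
Weights are hard-clipped to ``[w_min, w_max]``.  The default configuration
is depression-dominant (``a_minus * tau_minus > a_plus * tau_plus``), which
drives synapses from uncorrelated afferents down and lets only inputs that
consistently precede the postsynaptic spike survive -- the competitive
regime in which response latency tracks back toward the onset of a
recurring input pattern.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from numba import njit

from .input_synth import SpikeTrainSet

logger = logging.getLogger("stdpsync")

__all__ = [
    "Pairing",
    "STDPRule",
    "NeuronParams",
    "SynapticState",
    "epsp_kernel",
    "epsp_peak_time",
    "stdp_delta_w",
    "apply_weight_update",
    "initial_state",
    "run_neuron",
    "NeuronRun",
]


class Pairing(str, Enum):
    """Spike-pairing scheme for the STDP updates."""

    NEAREST_NEIGHBOR = "nearest_neighbor"
    ALL_PAIRS = "all_pairs"


@dataclass(frozen=True)
class STDPRule:
    """Additive STDP window.

    ``a_minus`` is stored positive and applied with negative sign.  The
    default amplitudes satisfy ``a_minus * tau_minus = 1.6 * a_plus *
    tau_plus`` (depression-dominant); weakening that inequality is allowed
    but logged, because without integral depression dominance uncorrelated
    afferents are not driven down and the latency-reduction mechanism
    stalls.
    """

    a_plus: float = 0.05
    a_minus: float = 1.6 * 0.05 * 16.0 / 32.0
    tau_plus: float = 16.0
    tau_minus: float = 32.0
    w_min: float = 0.0
    w_max: float = 1.0
    pairing: Pairing = Pairing.ALL_PAIRS

    def __post_init__(self) -> None:
        if not (self.a_plus > 0 and self.a_minus > 0):
            raise ValueError("STDP amplitudes must be positive")
        if not (self.tau_plus > 0 and self.tau_minus > 0):
            raise ValueError("STDP time constants must be positive")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be < w_max")
        if self.a_minus * self.tau_minus <= self.a_plus * self.tau_plus:
            logger.warning(
                "STDP rule is not depression-dominant "
                "(a_minus*tau_minus = %.4g <= a_plus*tau_plus = %.4g); "
                "weight competition may not stabilize",
                self.a_minus * self.tau_minus,
                self.a_plus * self.tau_plus,
            )


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire membrane parameters.

    Potentials are dimensionless, normalized so that the resting potential
    is 0 and a unit-weight EPSP peaks at 1.  All times are milliseconds.
    The optional sinusoidal drive models a slow subthreshold network
    oscillation; for smooth phase control its period should exceed the
    membrane time constant (logged warning otherwise).
    """

    tau_m: float = 10.0
    tau_s: float = 2.5
    threshold: float = 5.0
    refractory: float = 5.0
    reset: float = 0.0
    osc_amplitude: float = 0.0
    osc_period: float = 200.0
    tonic_drive: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau_m > self.tau_s > 0):
            raise ValueError("require tau_m > tau_s > 0")
        if self.refractory < 0:
            raise ValueError("refractory period must be >= 0")
        if not self.threshold > self.reset:
            raise ValueError("threshold must exceed the reset potential")
        if self.osc_amplitude > 0 and self.osc_period <= self.tau_m:
            logger.warning(
                "oscillation period %.3g ms does not exceed tau_m %.3g ms; "
                "phase control of spiking will be poor",
                self.osc_period,
                self.tau_m,
            )

    @property
    def kernel_norm(self) -> float:
        """Normalization constant c such that the EPSP kernel peaks at 1."""
        tp = epsp_peak_time(self)
        return 1.0 / (math.exp(-tp / self.tau_m) - math.exp(-tp / self.tau_s))


@dataclass
class SynapticState:
    """Per-afferent efficacies plus the spike-timing memory STDP needs."""

    weights: np.ndarray
    last_pre_times: np.ndarray
    last_post_time: float = -np.inf

    @property
    def n_afferents(self) -> int:
        return len(self.weights)

    def copy(self) -> "SynapticState":
        return SynapticState(
            self.weights.copy(), self.last_pre_times.copy(), self.last_post_time
        )


def initial_state(n_afferents: int, rule: STDPRule, seed: int) -> SynapticState:
    """Unbiased start: independent uniform weights on ``[w_min, w_max]``."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(rule.w_min, rule.w_max, size=n_afferents)
    return SynapticState(
        weights=w,
        last_pre_times=np.full(n_afferents, -np.inf),
        last_post_time=-np.inf,
    )


def epsp_peak_time(params: NeuronParams) -> float:
    """Time at which the double-exponential kernel reaches its maximum."""
    tm, ts = params.tau_m, params.tau_s
    return tm * ts / (tm - ts) * math.log(tm / ts)


def epsp_kernel(t, params: NeuronParams):
    """Peak-normalized double-exponential EPSP kernel; 0 for t < 0."""
    t = np.asarray(t, dtype=float)
    c = params.kernel_norm
    out = c * (np.exp(-t / params.tau_m) - np.exp(-t / params.tau_s))
    out = np.where(t < 0, 0.0, out)
    return out if out.ndim else float(out)


def stdp_delta_w(dt, rule: STDPRule):
    """Weight increment for a post-minus-pre lag ``dt`` (ms).

    ``dt >= 0`` (pre before or coincident with post) potentiates;
    ``dt < 0`` depresses.  Vectorized over ``dt``.
    """
    dt = np.asarray(dt, dtype=float)
    pot = rule.a_plus * np.exp(-np.maximum(dt, 0.0) / rule.tau_plus)
    dep = -rule.a_minus * np.exp(np.minimum(dt, 0.0) / rule.tau_minus)
    out = np.where(dt >= 0, pot, dep)
    return out if out.ndim else float(out)


def apply_weight_update(
    state: SynapticState, afferent: int, dw: float, rule: STDPRule
) -> SynapticState:
    """Return a new state with one weight incremented and hard-clipped."""
    if not 0 <= afferent < state.n_afferents:
        raise IndexError(f"afferent index {afferent} out of range")
    new = state.copy()
    new.weights[afferent] = min(
        max(new.weights[afferent] + dw, rule.w_min), rule.w_max
    )
    return new


# ---------------------------------------------------------------------------
# Clock-driven integration engine
# ---------------------------------------------------------------------------

@njit(cache=True)
def _integrate(
    ev_times,
    ev_units,
    weights,
    last_pre,
    last_post_in,
    n_steps,
    dt,
    tau_m,
    tau_s,
    c_norm,
    threshold,
    reset,
    refractory,
    tonic,
    osc_amp,
    osc_period,
    a_plus,
    a_minus,
    tau_plus,
    tau_minus,
    w_min,
    w_max,
    all_pairs,
    plasticity_on,
    snap_steps,
):  # pragma: no cover - exercised through run_neuron
    n_aff = weights.shape[0]
    decay_m = math.exp(-dt / tau_m)
    decay_s = math.exp(-dt / tau_s)
    decay_p = math.exp(-dt / tau_plus)
    decay_d = math.exp(-dt / tau_minus)

    n_snaps = n_steps // snap_steps + 1
    snaps = np.empty((n_snaps, n_aff))
    snap_times = np.empty(n_snaps)
    spike_buf = np.empty(n_steps // 8 + 16)
    n_spk = 0

    a_tr = 0.0  # tau_m synaptic trace
    b_tr = 0.0  # tau_s synaptic trace
    r_tr = 0.0  # reset trace (decays with tau_m)
    x_tr = np.zeros(n_aff)  # presynaptic traces (all-pairs scheme)
    y_tr = 0.0  # postsynaptic trace (all-pairs scheme)
    last_post = last_post_in
    refr_until = -1.0
    omega = 2.0 * math.pi / osc_period

    ev_i = 0
    n_ev = ev_times.shape[0]
    snap_i = 0
    nan_step = -1

    for step in range(n_steps):
        t = step * dt
        a_tr *= decay_m
        b_tr *= decay_s
        r_tr *= decay_m
        if all_pairs and plasticity_on:
            for u in range(n_aff):
                x_tr[u] *= decay_p
            y_tr *= decay_d

        # presynaptic events in [t, t + dt)
        while ev_i < n_ev and ev_times[ev_i] < t + dt:
            te = ev_times[ev_i]
            u = ev_units[ev_i]
            if plasticity_on:
                if all_pairs:
                    w_new = weights[u] - a_minus * y_tr
                    if w_new < w_min:
                        w_new = w_min
                    weights[u] = w_new
                    x_tr[u] += 1.0
                elif last_post > -1e300:
                    lag = last_post - te  # post minus pre, <= 0 here
                    if lag >= 0.0:
                        dw = a_plus * math.exp(-lag / tau_plus)
                    else:
                        dw = -a_minus * math.exp(lag / tau_minus)
                    w_new = weights[u] + dw
                    if w_new < w_min:
                        w_new = w_min
                    elif w_new > w_max:
                        w_new = w_max
                    weights[u] = w_new
            last_pre[u] = te
            if t >= refr_until:
                drive = weights[u] * c_norm
                a_tr += drive
                b_tr += drive
            ev_i += 1

        v = a_tr - b_tr + r_tr + tonic
        if osc_amp != 0.0:
            v += osc_amp * math.sin(omega * t)
        if not math.isfinite(v):
            nan_step = step
            break

        if v >= threshold and t >= refr_until:
            if n_spk >= spike_buf.shape[0]:
                bigger = np.empty(spike_buf.shape[0] * 2)
                bigger[: n_spk] = spike_buf[: n_spk]
                spike_buf = bigger
            spike_buf[n_spk] = t
            n_spk += 1
            refr_until = t + refractory
            a_tr = 0.0
            b_tr = 0.0
            r_tr = reset
            if plasticity_on:
                if all_pairs:
                    for u in range(n_aff):
                        w_new = weights[u] + a_plus * x_tr[u]
                        if w_new > w_max:
                            w_new = w_max
                        weights[u] = w_new
                    y_tr += 1.0
                else:
                    for u in range(n_aff):
                        lp = last_pre[u]
                        if lp > -1e300:
                            dw = a_plus * math.exp(-(t - lp) / tau_plus)
                            w_new = weights[u] + dw
                            if w_new > w_max:
                                w_new = w_max
                            weights[u] = w_new
            last_post = t

        if step % snap_steps == 0:
            snap_times[snap_i] = t
            snaps[snap_i] = weights
            snap_i += 1

    return (
        spike_buf[: n_spk].copy(),
        snap_times[: snap_i].copy(),
        snaps[: snap_i].copy(),
        last_post,
        nan_step,
    )


@dataclass
class NeuronRun:
    """Result of a single-neuron simulation."""

    spike_times: np.ndarray
    snapshot_times: np.ndarray
    weight_snapshots: np.ndarray
    final_state: SynapticState


def run_neuron(
    inputs: SpikeTrainSet,
    initial: Optional[SynapticState] = None,
    rule: STDPRule = STDPRule(),
    params: NeuronParams = NeuronParams(),
    dt_sim: float = 0.1,
    plasticity_on: bool = True,
    seed: int = 0,
    snapshot_interval: float = 1000.0,
) -> NeuronRun:
    """Simulate one STDP-equipped integrate-and-fire neuron.

    Parameters
    ----------
    inputs
        Afferent spike trains (sorted by time).  May be empty.
    initial
        Starting synaptic state.  When omitted, weights are drawn
        independently and uniformly on ``[w_min, w_max]`` using ``seed``.
    dt_sim
        Integration step (ms); must not exceed ``tau_s / 2`` so the kernel
        rise is resolved.
    plasticity_on
        With ``False`` the weights are frozen (control condition).

    Returns
    -------
    NeuronRun
        Output spike times, weight snapshots taken every
        ``snapshot_interval`` ms (including t = 0), and the final state.

    Notes
    -----
    Integration is clock-driven at fixed step; the spike time is the time of
    the step at which the threshold crossing is detected (no sub-step
    interpolation).  Given identical inputs, seed and configuration the
    output is bit-identical across runs.
    """
    if dt_sim <= 0 or dt_sim > params.tau_s / 2:
        raise ValueError(
            f"dt_sim = {dt_sim} must be in (0, tau_s/2 = {params.tau_s / 2}]"
        )
    if initial is None:
        initial = initial_state(inputs.n_units, rule, seed)
    if initial.n_afferents < inputs.n_units:
        raise ValueError(
            f"state has {initial.n_afferents} afferents but inputs use "
            f"{inputs.n_units} units"
        )

    ev = inputs.events
    n_steps = max(int(math.ceil(inputs.duration / dt_sim)), 1)
    snap_steps = max(int(round(snapshot_interval / dt_sim)), 1)
    weights = initial.weights.astype(float).copy()
    last_pre = initial.last_pre_times.astype(float).copy()

    spikes, snap_t, snaps, last_post, nan_step = _integrate(
        ev["time"].astype(float),
        ev["unit"].astype(np.int64),
        weights,
        last_pre,
        float(initial.last_post_time),
        n_steps,
        float(dt_sim),
        params.tau_m,
        params.tau_s,
        params.kernel_norm,
        params.threshold,
        params.reset,
        params.refractory,
        params.tonic_drive,
        params.osc_amplitude,
        params.osc_period,
        rule.a_plus,
        rule.a_minus,
        rule.tau_plus,
        rule.tau_minus,
        rule.w_min,
        rule.w_max,
        rule.pairing == Pairing.ALL_PAIRS,
        bool(plasticity_on),
        snap_steps,
    )
    if nan_step >= 0:
        raise FloatingPointError(
            f"membrane potential became non-finite at t = {nan_step * dt_sim}"
            f" ms; check neuron parameters"
        )
    final = SynapticState(weights, last_pre, last_post)
    return NeuronRun(spikes, snap_t, snaps, final)
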