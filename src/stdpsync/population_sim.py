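"""Population experiment: unconnected STDP readout neurons, coherent input.

The hypothesis's population-level claim is deliberately tested in its
strongest form: the readout neurons share no connections and no background
input -- all coordination that emerges must come from learning on coherent
afferent patterns.  Each neuron is simulated independently through
:func:`stdpsync.stdp_core.run_neuron`; the merged output spike trains (one
unit id per readout neuron) feed the pattern miner and the synchrony /
sparseness statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .analysis_metrics import LatencyTrajectory
from .input_synth import EmbeddedPattern, SpikeTrainSet
from .stdp_core import NeuronParams, NeuronRun, STDPRule, run_neuron

__all__ = [
    "PopulationConfig",
    "oscillation_gating_experiment",
    "SimulationResult",
    "run_population",
    "latency_per_presentation",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Shared configuration for a population of independent readout neurons."""

    n_neurons: int = 6
    params: NeuronParams = field(default_factory=NeuronParams)
    rule: STDPRule = field(default_factory=STDPRule)
    dt_sim: float = 0.1
    plasticity_on: bool = True
    snapshot_interval: float = 1000.0
    latency_window_margin: float = 25.0  # analysis window = pattern length + this
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")


@dataclass
class SimulationResult:
    """Merged output of a population run plus per-neuron records."""

    output: SpikeTrainSet  # unit ids = readout neuron ids
    runs: list[NeuronRun]  # per-neuron spikes and weight snapshots
    latencies: list[LatencyTrajectory]  # vs each neuron's own true onsets
    patterns: list[EmbeddedPattern]
    config: PopulationConfig
    seed: int


def latency_per_presentation(
    spike_times: Sequence[float],
    onsets: Sequence[float],
    window: float,
    duration: Optional[float] = None,
) -> LatencyTrajectory:
    """First-spike latency after each ground-truth pattern onset.

    For each onset the latency is the time from onset to the first output
    spike inside ``[onset, onset + window]``, or a miss (NaN) when no spike
    falls in the window.  The false-alarm rate counts spikes outside every
    window, per second of recording (requires ``duration``).
    """
    if window <= 0:
        raise ValueError("analysis window must be positive")
    t = np.asarray(spike_times, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    lat = np.full(len(onsets), np.nan)
    in_any_window = np.zeros(len(t), dtype=bool)
    for i, onset in enumerate(onsets):
        lo = np.searchsorted(t, onset, side="left")
        hi = np.searchsorted(t, onset + window, side="right")
        if hi > lo:
            lat[i] = t[lo] - onset
            in_any_window[lo:hi] = True
    hits = int(np.sum(~np.isnan(lat)))
    hit_rate = hits / len(onsets) if len(onsets) else float("nan")
    if duration and duration > 0:
        fa_rate = float(np.sum(~in_any_window)) / (duration / 1000.0)
    else:
        fa_rate = float("nan")
    return LatencyTrajectory(
        onsets=onsets,
        latencies=lat,
        window=window,
        hit_rate=hit_rate,
        false_alarm_rate=fa_rate,
    )


def run_population(
    config: PopulationConfig,
    inputs: Sequence[tuple[SpikeTrainSet, EmbeddedPattern]],
) -> SimulationResult:
    """Simulate every readout neuron independently and merge the outputs.

    ``inputs`` must hold one (afferent trains, ground-truth pattern) pair
    per neuron, all with the same recording duration.  Determinism: the
    per-neuron weight-initialization seeds are spawned from ``config.seed``
    by neuron index, so permuting neuron order permutes but does not alter
    per-neuron outputs.
    """
    if len(inputs) != config.n_neurons:
        raise ValueError(
            f"got {len(inputs)} input sets for {config.n_neurons} neurons"
        )
    durations = {trains.duration for trains, _pat in inputs}
    if len(durations) > 1:
        raise ValueError(f"input sets have mismatched durations: {durations}")
    duration = durations.pop()

    root = np.random.SeedSequence(config.seed)
    child_seeds = [
        int(s.generate_state(1)[0] % 2**31) for s in root.spawn(config.n_neurons)
    ]

    runs: list[NeuronRun] = []
    latencies: list[LatencyTrajectory] = []
    patterns: list[EmbeddedPattern] = []
    times_all = []
    units_all = []
    for k, (trains, pattern) in enumerate(inputs):
        run = run_neuron(
            trains,
            initial=None,
            rule=config.rule,
            params=config.params,
            dt_sim=config.dt_sim,
            plasticity_on=config.plasticity_on,
            seed=child_seeds[k],
            snapshot_interval=config.snapshot_interval,
        )
        runs.append(run)
        patterns.append(pattern)
        window = pattern.length + config.latency_window_margin
        latencies.append(
            latency_per_presentation(
                run.spike_times, pattern.onsets, window, duration
            )
        )
        times_all.append(run.spike_times)
        units_all.append(np.full(len(run.spike_times), k, dtype=np.int64))

    times = np.concatenate(times_all) if times_all else np.empty(0)
    units = np.concatenate(units_all) if units_all else np.empty(0, dtype=np.int64)
    # clock-driven spikes land on the step grid; the last step is < duration
    output = SpikeTrainSet.from_arrays(
        times, units, config.n_neurons, duration
    )
    return SimulationResult(
        output=output,
        runs=runs,
        latencies=latencies,
        patterns=patterns,
        config=config,
        seed=config.seed,
    )


def oscillation_gating_experiment(
    seed: int,
    osc_amplitude: float = 1.0,
    n_afferents: int = 20,
    rate: float = 10.0,
    duration: float = 60_000.0,
    weight: float = 0.5,
    tonic_drive: float = 3.8,
    threshold: float = 5.0,
    osc_period: float = 200.0,
):
    """Phase locking of a tonically driven neuron to a slow oscillation.

    The neuron receives fixed-weight Poisson input plus a tonic drive that
    puts its mean potential just above threshold; a slow sinusoidal
    subthreshold oscillation (period >> tau_m) then confines effective
    excitation to the depolarizing phase.  With ``osc_amplitude = 0`` the
    same protocol serves as the unmodulated control.  Returns the
    :class:`~stdpsync.analysis_metrics.PhaseLocking` of the output spikes
    on the oscillation cycle.
    """
    from .analysis_metrics import phase_locking
    from .input_synth import AfferentPopulationSpec, generate_afferents
    from .stdp_core import SynapticState

    spec = AfferentPopulationSpec(
        n_units=n_afferents,
        background_rate=rate,
        duration=duration,
        pattern_fraction=0.0,
        seed=seed,
    )
    trains, _ = generate_afferents(spec)
    state = SynapticState(
        np.full(n_afferents, weight), np.full(n_afferents, -np.inf)
    )
    params = NeuronParams(
        threshold=threshold,
        tonic_drive=tonic_drive,
        osc_amplitude=osc_amplitude,
        osc_period=osc_period,
    )
    run = run_neuron(trains, initial=state, params=params, plasticity_on=False, seed=seed)
    return phase_locking(run.spike_times, osc_period)
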