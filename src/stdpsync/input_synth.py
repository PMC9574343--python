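"""Synthetic afferent spike trains with embedded repeating patterns.

The generator emulates the input regime of the headline experiment: ``n``
independent Poisson background trains, a configurable fraction of which
additionally carry a frozen spatiotemporal pattern ~50 ms long that recurs
at irregular intervals.  Every generated dataset keeps its ground truth
(:class:`EmbeddedPattern`) alongside, so downstream pattern mining can be
scored for recall and latency analyses can reference the true onsets.

For population experiments, :func:`make_coherent_input_set` builds per-neuron
input sets that are *coherent but not identical*: all neurons' patterns share
the same occurrence onsets (optionally shifted per neuron) while the member
units and their relative spike times are drawn independently except for a
configurable shared fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("stdpsync")

EVENT_DTYPE = np.dtype([("time", "f8"), ("unit", "i8")])

__all__ = [
    "EVENT_DTYPE",
    "SpikeTrainSet",
    "EmbeddedPattern",
    "GapProcess",
    "EmbedMode",
    "AfferentPopulationSpec",
    "generate_background",
    "make_pattern",
    "embed_pattern",
    "generate_afferents",
    "make_coherent_input_set",
]


@dataclass(frozen=True)
class SpikeTrainSet:
    """A set of labelled spike events over a recording interval.

    ``events`` is a structured array with fields ``time`` (ms, in
    ``[0, duration)``) and ``unit`` (0-based id), sorted by time with ties
    broken by unit id.  Both afferent input and simulated output use this
    container.
    """

    events: np.ndarray
    n_units: int
    duration: float

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=EVENT_DTYPE)
        order = np.argsort(ev, order=("time", "unit"), kind="stable")
        ev = np.ascontiguousarray(ev[order])
        object.__setattr__(self, "events", ev)
        if len(ev):
            if ev["time"][0] < 0 or ev["time"][-1] >= self.duration:
                raise ValueError("event times must lie in [0, duration)")
            if ev["unit"].min() < 0 or ev["unit"].max() >= self.n_units:
                raise ValueError("unit ids must lie in [0, n_units)")

    def __len__(self) -> int:
        return len(self.events)

    @classmethod
    def from_arrays(
        cls, times: Sequence[float], units: Sequence[int], n_units: int, duration: float
    ) -> "SpikeTrainSet":
        ev = np.empty(len(times), dtype=EVENT_DTYPE)
        ev["time"] = times
        ev["unit"] = units
        return cls(ev, n_units, duration)

    def unit_times(self, unit: int) -> np.ndarray:
        """Spike times of one unit (sorted)."""
        return self.events["time"][self.events["unit"] == unit]

    def counts_per_unit(self) -> np.ndarray:
        return np.bincount(self.events["unit"], minlength=self.n_units)

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Events with time in ``[t0, t1)`` (view into the sorted array)."""
        lo = np.searchsorted(self.events["time"], t0, side="left")
        hi = np.searchsorted(self.events["time"], t1, side="left")
        return self.events[lo:hi]


@dataclass(frozen=True)
class EmbeddedPattern:
    """Ground truth for a planted repeating spatiotemporal pattern."""

    member_units: np.ndarray  # unit ids carrying the pattern
    offsets: np.ndarray  # (n_spikes,) relative times in [0, length]
    offset_units: np.ndarray  # (n_spikes,) unit id of each pattern spike
    length: float  # pattern duration, ms
    onsets: np.ndarray  # sorted occurrence times, ms
    jitter_sd: float = 0.0  # per-spike Gaussian jitter, ms

    def __post_init__(self) -> None:
        if len(self.offsets) and (
            self.offsets.min() < 0 or self.offsets.max() > self.length
        ):
            raise ValueError("pattern offsets must lie in [0, length]")
        if len(self.member_units) and not set(self.offset_units) <= set(
            self.member_units.tolist()
        ):
            raise ValueError("every pattern spike must belong to a member unit")
        members_with_spike = set(self.offset_units.tolist())
        if not set(self.member_units.tolist()) <= members_with_spike:
            raise ValueError("every member unit needs at least one pattern spike")
        if len(self.onsets) > 1 and np.any(np.diff(self.onsets) < 0):
            raise ValueError("onsets must be sorted")

    @property
    def n_members(self) -> int:
        return len(self.member_units)


class GapProcess(str, Enum):
    """How successive pattern occurrences are spaced."""

    UNIFORM_GAPS = "uniform_gaps"
    POISSON_GAPS = "poisson_gaps"


class EmbedMode(str, Enum):
    """Whether pattern spikes add to or replace the background."""

    SUPERIMPOSE = "superimpose"
    REPLACE_WINDOW = "replace_window"


@dataclass(frozen=True)
class AfferentPopulationSpec:
    """Parameters of the afferent population and its embedded pattern.

    Defaults reproduce the headline regime: 100 afferents at 20 Hz for
    200 s, half carrying a frozen 50 ms pattern recurring at uniform gaps
    on [150, 500] ms with 1 ms per-spike jitter.
    """

    n_units: int = 100
    background_rate: float = 20.0  # Hz per unit
    duration: float = 200_000.0  # ms
    pattern_fraction: float = 0.5
    pattern_length: float = 50.0  # ms
    gap_process: GapProcess = GapProcess.UNIFORM_GAPS
    min_gap: float = 150.0  # ms between consecutive onsets
    max_gap: float = 500.0
    jitter_sd: float = 1.0  # ms
    spikes_per_member: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pattern_fraction <= 1:
            raise ValueError("pattern_fraction must lie in [0, 1]")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.min_gap <= 0 or self.max_gap < self.min_gap:
            raise ValueError("require 0 < min_gap <= max_gap")
        if self.spikes_per_member < 1:
            raise ValueError("spikes_per_member must be >= 1")


def generate_background(
    spec: AfferentPopulationSpec, seed: Optional[int] = None
) -> SpikeTrainSet:
    """Independent homogeneous Poisson trains at ``background_rate`` per unit."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rate_per_ms = spec.background_rate / 1000.0
    times_all = []
    units_all = []
    for u in range(spec.n_units):
        n = rng.poisson(rate_per_ms * spec.duration)
        if n:
            t = rng.uniform(0.0, spec.duration, size=n)
            times_all.append(t)
            units_all.append(np.full(n, u, dtype=np.int64))
    if times_all:
        times = np.concatenate(times_all)
        units = np.concatenate(units_all)
    else:
        times = np.empty(0)
        units = np.empty(0, dtype=np.int64)
    return SpikeTrainSet.from_arrays(times, units, spec.n_units, spec.duration)


def _draw_onsets(spec: AfferentPopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Occurrence onsets over [0, duration - length] with gaps >= min_gap."""
    horizon = spec.duration - spec.pattern_length
    if horizon < 0:
        raise ValueError("duration is shorter than the pattern length")
    onsets = []
    t = float(rng.uniform(0.0, spec.min_gap))
    while t <= horizon:
        onsets.append(t)
        if spec.gap_process is GapProcess.UNIFORM_GAPS:
            gap = rng.uniform(spec.min_gap, spec.max_gap)
        else:
            # shifted exponential: hard floor min_gap, mean (min_gap+max_gap)/2
            gap = spec.min_gap + rng.exponential(
                (spec.max_gap - spec.min_gap) / 2.0
            )
        t += gap
    return np.asarray(onsets)


def make_pattern(
    spec: AfferentPopulationSpec, seed: Optional[int] = None
) -> EmbeddedPattern:
    """Draw the frozen pattern: members, relative spike times, occurrences.

    Members are the first ``ceil(fraction * n)`` units of a seeded
    permutation; each member receives ``spikes_per_member`` offsets drawn
    uniformly on ``[0, length]``.
    """
    n_members = math.ceil(spec.pattern_fraction * spec.n_units)
    if n_members < 1:
        raise ValueError("pattern must have at least one member unit")
    if spec.duration < spec.pattern_length:
        raise ValueError("duration is shorter than the pattern length")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    members = rng.permutation(spec.n_units)[:n_members]
    offset_units = np.repeat(members, spec.spikes_per_member)
    offsets = rng.uniform(0.0, spec.pattern_length, size=len(offset_units))
    onsets = _draw_onsets(spec, rng)
    return EmbeddedPattern(
        member_units=np.sort(members),
        offsets=offsets,
        offset_units=offset_units,
        length=spec.pattern_length,
        onsets=onsets,
        jitter_sd=spec.jitter_sd,
    )


def embed_pattern(
    background: SpikeTrainSet,
    pattern: EmbeddedPattern,
    mode: EmbedMode = EmbedMode.SUPERIMPOSE,
    seed: int = 0,
) -> SpikeTrainSet:
    """Insert the pattern's spikes at every occurrence.

    In ``superimpose`` mode pattern spikes are added on top of the
    background; in ``replace_window`` mode each member's background spikes
    inside ``[onset, onset + length]`` are first removed, keeping the
    in-window rate comparable to baseline.  Per-spike Gaussian jitter of
    ``pattern.jitter_sd`` ms is applied; jittered times falling outside the
    recording are clipped to the boundary (logged).
    """
    if len(pattern.member_units) and (
        pattern.member_units.max() >= background.n_units
    ):
        raise ValueError("pattern units must be a subset of background units")
    rng = np.random.default_rng(seed)
    ev = background.events

    if mode is EmbedMode.REPLACE_WINDOW and len(pattern.onsets):
        member_mask = np.isin(ev["unit"], pattern.member_units)
        in_window = np.zeros(len(ev), dtype=bool)
        for onset in pattern.onsets:
            in_window |= (ev["time"] >= onset) & (ev["time"] <= onset + pattern.length)
        ev = ev[~(member_mask & in_window)]

    n_new = len(pattern.onsets) * len(pattern.offsets)
    if n_new:
        t_new = (
            pattern.onsets[:, None] + pattern.offsets[None, :]
        ).ravel()
        u_new = np.tile(pattern.offset_units, len(pattern.onsets))
        if pattern.jitter_sd > 0:
            t_new = t_new + rng.normal(0.0, pattern.jitter_sd, size=n_new)
        out_of_range = (t_new < 0) | (t_new >= background.duration)
        if np.any(out_of_range):
            logger.info(
                "clipped %d jittered pattern spikes to the recording boundary",
                int(out_of_range.sum()),
            )
            eps = 1e-9
            t_new = np.clip(t_new, 0.0, background.duration - eps)
        add = np.empty(n_new, dtype=EVENT_DTYPE)
        add["time"] = t_new
        add["unit"] = u_new
        ev = np.concatenate([ev, add])

    return SpikeTrainSet(ev, background.n_units, background.duration)


def generate_afferents(
    spec: AfferentPopulationSpec,
    mode: EmbedMode = EmbedMode.SUPERIMPOSE,
    seed: Optional[int] = None,
) -> tuple[SpikeTrainSet, EmbeddedPattern]:
    """Background + pattern + embedding in one deterministic call."""
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    s_bg, s_pat, s_emb = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(3)]
    background = generate_background(spec, seed=s_bg)
    if spec.pattern_fraction * spec.n_units >= 1:
        pattern = make_pattern(spec, seed=s_pat)
        trains = embed_pattern(background, pattern, mode=mode, seed=s_emb)
    else:
        pattern = EmbeddedPattern(
            member_units=np.empty(0, dtype=np.int64),
            offsets=np.empty(0),
            offset_units=np.empty(0, dtype=np.int64),
            length=spec.pattern_length,
            onsets=np.empty(0),
            jitter_sd=spec.jitter_sd,
        )
        trains = background
    return trains, pattern


def make_coherent_input_set(
    spec: AfferentPopulationSpec,
    n_neurons: int,
    overlap: float = 0.5,
    onset_offsets: Optional[Sequence[float]] = None,
    mode: EmbedMode = EmbedMode.SUPERIMPOSE,
    seed: Optional[int] = None,
) -> list[tuple[SpikeTrainSet, EmbeddedPattern]]:
    """Coherent (not necessarily identical) input sets for a population.

    All neurons' patterns share the same occurrence onsets -- optionally
    shifted per neuron by ``onset_offsets`` -- while a fraction ``overlap``
    of the member units (with their relative spike times) is shared and the
    rest is drawn independently per neuron.  Backgrounds are independent.
    """
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must lie in [0, 1]")
    if onset_offsets is None:
        onset_offsets = [0.0] * n_neurons
    if len(onset_offsets) != n_neurons:
        raise ValueError("need one onset offset per neuron")

    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    master_ss, *per_neuron_ss = root.spawn(n_neurons + 1)
    master_seed = int(master_ss.generate_state(1)[0] % 2**31)
    master = make_pattern(spec, seed=master_seed)

    n_members = master.n_members
    n_shared = math.ceil(overlap * n_members)
    shared_units = master.member_units[:n_shared]
    shared_mask = np.isin(master.offset_units, shared_units)

    out = []
    for k in range(n_neurons):
        ss = per_neuron_ss[k]
        s_bg, s_draw, s_emb = [
            int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
        ]
        rng = np.random.default_rng(s_draw)
        # independent members drawn from the units not in the shared core
        pool = np.setdiff1d(np.arange(spec.n_units), shared_units)
        own = rng.permutation(pool)[: n_members - n_shared]
        own_units = np.repeat(own, spec.spikes_per_member)
        own_offsets = rng.uniform(0.0, spec.pattern_length, size=len(own_units))
        offset_units = np.concatenate(
            [master.offset_units[shared_mask], own_units]
        )
        offsets = np.concatenate([master.offsets[shared_mask], own_offsets])
        onsets = master.onsets + onset_offsets[k]
        onsets = onsets[
            (onsets >= 0) & (onsets <= spec.duration - spec.pattern_length)
        ]
        pat = EmbeddedPattern(
            member_units=np.sort(np.concatenate([shared_units, own])),
            offsets=offsets,
            offset_units=offset_units,
            length=spec.pattern_length,
            onsets=onsets,
            jitter_sd=spec.jitter_sd,
        )
        background = generate_background(spec, seed=s_bg)
        trains = embed_pattern(background, pat, mode=mode, seed=s_emb)
        out.append((trains, pat))
    return out
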