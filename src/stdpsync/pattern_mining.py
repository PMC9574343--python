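"""Sliding-window mining of recurring multineuronal spike patterns.

A candidate constellation is read out of every window of ``cfg.window`` ms
that starts at an event; candidates with at least ``min_units`` distinct
units are clustered by greedy tolerance matching: two constellations match
when they contain the same per-unit spike multiset and a single global time
shift brings every paired spike within ``match_tolerance`` ms.  Templates
supported by at least ``min_occurrences`` non-overlapping occurrences are
reported with dated, per-occurrence realizations (anchor time, matched
events, first-to-last duration, 1-based repeat index).

Significance is assessed against dither surrogates: every spike is
displaced independently by uniform noise on ``[-dither, +dither]``
(reflected at the recording boundaries, per-unit counts conserved), which
destroys millisecond coordination while preserving rates.  The chance level
per template-size class is an empirical ``(1 - alpha)`` quantile of the
surrogate counts; a class is retained only where the original count
strictly exceeds chance, and a template only where its occurrence count
strictly exceeds the class-wise surrogate occurrence quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .input_synth import EVENT_DTYPE, SpikeTrainSet

logger = logging.getLogger("stdpsync")

__all__ = [
    "MiningConfig",
    "PatternTemplate",
    "PatternOccurrence",
    "MinedPattern",
    "MiningResult",
    "mine_patterns",
    "generate_surrogate",
    "validate_significance",
    "mine_and_validate",
    "duration_distribution",
]


@dataclass(frozen=True)
class MiningConfig:
    """Sliding-window mining and surrogate-validation settings."""

    window: float = 50.0  # ms
    match_tolerance: float = 2.0  # ms per spike
    min_units: int = 3
    min_occurrences: int = 2
    surrogate_n: int = 100
    dither: float = 25.0  # surrogate dither half-width, ms
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.match_tolerance < self.window:
            raise ValueError("require 0 < match_tolerance < window")
        if self.dither <= self.match_tolerance:
            raise ValueError("dither must exceed match_tolerance")
        if self.min_units < 1 or self.min_occurrences < 1:
            raise ValueError("min_units and min_occurrences must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class PatternTemplate:
    """A recurring constellation, anchored at its earliest element.

    ``elements`` is a structured array (fields ``unit``, ``rel_time``)
    sorted by relative time then unit, with the first element at 0.
    """

    elements: np.ndarray

    def __post_init__(self) -> None:
        el = np.asarray(self.elements)
        if len(el) == 0:
            raise ValueError("template must have at least one element")
        if abs(el["rel_time"][0]) > 1e-12 or np.any(np.diff(el["rel_time"]) < 0):
            raise ValueError("elements must be sorted with first rel_time = 0")

    @property
    def span(self) -> float:
        return float(self.elements["rel_time"][-1])

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_units(self) -> int:
        return len(np.unique(self.elements["unit"]))

    @property
    def size_class(self) -> int:
        """Template-size class used for surrogate chance levels (= element count)."""
        return self.n_elements


@dataclass
class PatternOccurrence:
    """One dated realization of a template."""

    anchor: float  # time of the earliest matched spike, ms
    duration: float  # last - first matched spike time, ms
    event_indices: np.ndarray  # indices into the mined SpikeTrainSet
    residual: float  # max per-spike deviation after optimal shift, ms
    repeat_index: int = 0  # 1-based rank in anchor time, set after filtering


@dataclass
class MinedPattern:
    """A template together with its accepted (non-overlapping) occurrences."""

    template: PatternTemplate
    occurrences: list[PatternOccurrence]

    @property
    def n_occurrences(self) -> int:
        return len(self.occurrences)

    @property
    def durations(self) -> np.ndarray:
        return np.array([o.duration for o in self.occurrences])


# ---------------------------------------------------------------------------
# Constellation matching
# ---------------------------------------------------------------------------

def _match_shift(times_a: np.ndarray, times_b: np.ndarray, tol: float):
    """Optimal-shift match of two unit-aligned time vectors.

    Returns the max per-spike residual after the optimal global shift, or
    None when no shift brings every pair within ``tol``.
    """
    d = times_a - times_b
    lo, hi = d.min(), d.max()
    resid = (hi - lo) / 2.0
    return resid if resid <= tol else None


def mine_patterns(
    data: SpikeTrainSet, cfg: MiningConfig = MiningConfig()
) -> list[MinedPattern]:
    """Collect recurring constellations with a sliding window.

    Every event anchors one candidate window ``[t, t + window)``; windows
    with at least ``min_units`` distinct units are clustered greedily in
    time order: a candidate joins the best-matching existing template
    (smallest max-residual after the optimal shift, ties to the
    earlier-founded template) or founds a new one.  Comparison is
    restricted to templates with the same unit multiset, paired per unit in
    time order -- the only pairing a tolerance below the window width can
    realize.  Occurrences of one template may not overlap in time (greedy
    earliest-first acceptance).  Templates with at least
    ``min_occurrences`` accepted occurrences are returned, each occurrence
    dated and ranked by its 1-based repeat index.
    """
    ev = data.events
    n = len(ev)
    templates: list[PatternTemplate] = []
    raw_occ: list[list[PatternOccurrence]] = []
    by_sig: dict[bytes, list[int]] = {}
    rel_by_tid: list[np.ndarray] = []

    t_arr = ev["time"]
    for i in range(n):
        hi = np.searchsorted(t_arr, t_arr[i] + cfg.window, side="left")
        win = ev[i:hi]
        if len(np.unique(win["unit"])) < cfg.min_units:
            continue
        # canonical per-unit time-ordered form
        order = np.lexsort((win["time"], win["unit"]))
        sig = win["unit"][order].tobytes()
        rel = (win["time"][order] - t_arr[i]).astype(float)
        best_tid = -1
        best_res = np.inf
        for tid in by_sig.get(sig, ()):  # same unit multiset only
            res = _match_shift(rel, rel_by_tid[tid], cfg.match_tolerance)
            if res is not None and res < best_res:
                best_res = res
                best_tid = tid
        occ = PatternOccurrence(
            anchor=float(t_arr[i]),
            duration=float(win["time"].max() - t_arr[i]),
            event_indices=np.arange(i, hi),
            residual=0.0,
        )
        if best_tid < 0:
            el = np.empty(len(win), dtype=[("unit", "i8"), ("rel_time", "f8")])
            el_order = np.lexsort((win["unit"], win["time"]))
            el["unit"] = win["unit"][el_order]
            el["rel_time"] = (win["time"] - t_arr[i])[el_order]
            templates.append(PatternTemplate(el))
            rel_by_tid.append(rel)
            raw_occ.append([occ])
            by_sig.setdefault(sig, []).append(len(templates) - 1)
        else:
            occ.residual = float(best_res)
            raw_occ[best_tid].append(occ)

    out: list[MinedPattern] = []
    for tid, tmpl in enumerate(templates):
        occs = sorted(raw_occ[tid], key=lambda o: (o.anchor, o.residual))
        accepted: list[PatternOccurrence] = []
        last_end = -np.inf
        for o in occs:
            if o.anchor > last_end:
                accepted.append(o)
                last_end = o.anchor + max(o.duration, 0.0)
        if len(accepted) >= cfg.min_occurrences:
            for r, o in enumerate(accepted, start=1):
                o.repeat_index = r
            out.append(MinedPattern(tmpl, accepted))
    return out


# ---------------------------------------------------------------------------
# Surrogates and validation
# ---------------------------------------------------------------------------

def generate_surrogate(
    data: SpikeTrainSet, cfg: MiningConfig, seed: Optional[int] = None
) -> SpikeTrainSet:
    """Dither surrogate: each spike displaced by U[-dither, +dither].

    Displaced times are reflected at the recording boundaries, so per-unit
    spike counts are exactly conserved while millisecond coordination is
    destroyed.
    """
    if cfg.dither <= 0:
        raise ValueError("dither must be positive")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ev = data.events
    t = ev["time"] + rng.uniform(-cfg.dither, cfg.dither, size=len(ev))
    d = data.duration
    t = np.abs(t)  # reflect at 0
    t = np.where(t >= d, 2 * d - t, t)  # reflect at duration
    t = np.clip(t, 0.0, np.nextafter(d, 0.0))
    return SpikeTrainSet.from_arrays(t, ev["unit"], data.n_units, data.duration)


def _quantile_index(n: int, alpha: float) -> int:
    """0-based order-statistic index of the empirical (1 - alpha) quantile.

    Defined as floor((1 - alpha) * n) capped at n - 1; with alpha = 0.01
    and 100 surrogates this selects the maximum surrogate value.
    """
    return min(int((1.0 - alpha) * n), n - 1)


@dataclass
class MiningResult:
    """Mining output plus surrogate-based validation."""

    patterns: list[MinedPattern]
    validated: list[MinedPattern]
    chance_levels: dict[int, float]  # size class -> chance template count
    occurrence_levels: dict[int, float]  # size class -> chance occurrence count
    original_counts: dict[int, int]
    surrogate_n: int


def _counts_by_class(patterns: Sequence[MinedPattern]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for p in patterns:
        k = p.template.size_class
        counts[k] = counts.get(k, 0) + 1
    return counts


def _max_occ_by_class(patterns: Sequence[MinedPattern]) -> dict[int, int]:
    occ: dict[int, int] = {}
    for p in patterns:
        k = p.template.size_class
        occ[k] = max(occ.get(k, 0), p.n_occurrences)
    return occ


def validate_significance(
    patterns: Sequence[MinedPattern],
    surrogate_patterns: Sequence[Sequence[MinedPattern]],
    alpha: float = 0.01,
) -> MiningResult:
    """Retain templates exceeding the surrogate chance level.

    For each template-size class the chance level is the empirical
    ``(1 - alpha)`` quantile over surrogates of (a) the per-surrogate
    template count and (b) the per-surrogate maximum per-template
    occurrence count.  A template is validated when its class's original
    count strictly exceeds (a) and its own occurrence count strictly
    exceeds (b); ties fail.
    """
    n_sur = len(surrogate_patterns)
    if n_sur < 20:
        raise ValueError(
            f"need at least 20 surrogates for a stable quantile, got {n_sur}"
        )
    orig_counts = _counts_by_class(patterns)
    classes = set(orig_counts)
    sur_counts = {k: np.zeros(n_sur) for k in classes}
    sur_occ = {k: np.zeros(n_sur) for k in classes}
    for j, sur in enumerate(surrogate_patterns):
        cb = _counts_by_class(sur)
        ob = _max_occ_by_class(sur)
        for k in classes:
            sur_counts[k][j] = cb.get(k, 0)
            sur_occ[k][j] = ob.get(k, 0)
    qi = _quantile_index(n_sur, alpha)
    chance = {k: float(np.sort(sur_counts[k])[qi]) for k in classes}
    occ_level = {k: float(np.sort(sur_occ[k])[qi]) for k in classes}
    validated = [
        p
        for p in patterns
        if orig_counts[p.template.size_class] > chance[p.template.size_class]
        and p.n_occurrences > occ_level[p.template.size_class]
    ]
    return MiningResult(
        patterns=list(patterns),
        validated=validated,
        chance_levels=chance,
        occurrence_levels=occ_level,
        original_counts=orig_counts,
        surrogate_n=n_sur,
    )


def mine_and_validate(
    data: SpikeTrainSet, cfg: MiningConfig = MiningConfig()
) -> MiningResult:
    """Mine the data, mine ``surrogate_n`` dither surrogates, validate."""
    patterns = mine_patterns(data, cfg)
    root = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(cfg.surrogate_n)]
    sur_patterns = []
    for s in seeds:
        sur = generate_surrogate(data, cfg, seed=s)
        sur_patterns.append(mine_patterns(sur, cfg))
    return validate_significance(patterns, sur_patterns, cfg.alpha)


# ---------------------------------------------------------------------------
# Duration distribution
# ---------------------------------------------------------------------------

def duration_distribution(
    patterns: Sequence[MinedPattern],
    bin_width: float = 5.0,
    window: float = 50.0,
) -> tuple[np.ndarray, np.ndarray, Optional[int]]:
    """Histogram of validated per-occurrence durations over ``[0, window]``.

    Returns ``(bin_edges, counts, modal_bin_index)``; the modal bin index
    is None for empty input.  Ties go to the lowest bin (argmax
    convention).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(0.0, window + bin_width, bin_width)
    durations = (
        np.concatenate([p.durations for p in patterns])
        if patterns
        else np.empty(0)
    )
    counts, _ = np.histogram(durations, bins=edges)
    modal = int(np.argmax(counts)) if counts.sum() else None
    return edges, counts, modal
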