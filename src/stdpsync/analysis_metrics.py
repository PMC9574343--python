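"""Statistics operationalizing the three predictions of the hypothesis.

Latency trajectories quantify the single-neuron effect (responses migrate
toward pattern onset); compression regression quantifies the progressive
shortening of recurring multineuronal patterns across repeats; synchrony
concentration and sparseness trends quantify the population-level endpoint
(short-latency volleys, fewer spikes per neuron per event); vector strength
with a Rayleigh test quantifies phase locking to a subthreshold oscillation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .input_synth import SpikeTrainSet

logger = logging.getLogger("stdpsync")

__all__ = [
    "LatencyTrajectory",
    "CompressionFit",
    "SynchronyStats",
    "SparsenessStats",
    "PhaseLocking",
    "mann_kendall",
    "compression_regression",
    "synchrony_concentration",
    "sparseness_trend",
    "phase_locking",
]


# ---------------------------------------------------------------------------
# Latency
# ---------------------------------------------------------------------------

@dataclass
class LatencyTrajectory:
    """First-spike latency after each ground-truth pattern onset.

    ``latencies[i]`` is NaN for a miss (no spike inside the analysis
    window); misses are excluded from the medians but counted in
    ``hit_rate``.  ``false_alarm_rate`` counts spikes outside every window,
    per second.
    """

    onsets: np.ndarray
    latencies: np.ndarray  # NaN = miss
    window: float
    hit_rate: float
    false_alarm_rate: float

    @property
    def n_presentations(self) -> int:
        return len(self.onsets)

    def median_over(self, sl: slice) -> float:
        """Median latency over a slice of presentations, ignoring misses."""
        chunk = self.latencies[sl]
        hits = chunk[~np.isnan(chunk)]
        return float(np.median(hits)) if len(hits) else float("nan")

    def early_median(self, n: int = 100) -> float:
        return self.median_over(slice(0, n))

    def late_median(self, n: int = 100) -> float:
        return self.median_over(slice(max(len(self.latencies) - n, 0), None))


# ---------------------------------------------------------------------------
# Mann-Kendall trend
# ---------------------------------------------------------------------------

def mann_kendall(
    values: Sequence[float], alternative: str = "two-sided"
) -> tuple[int, float]:
    """Mann-Kendall sign statistic S and trend p-value.

    S = sum over i < j of sign(x_j - x_i); a negative S indicates a
    decreasing trend.  The p-value comes from Kendall's tau against the
    index sequence (exact for small n without ties, normal approximation
    otherwise).  ``alternative`` is one of ``two-sided``, ``decreasing``,
    ``increasing``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    s = 0
    for i in range(n - 1):
        s += int(np.sum(np.sign(x[i + 1:] - x[i])))
    if n < 2 or np.all(x == x[0]):
        return s, 1.0
    alt = {"two-sided": "two-sided", "decreasing": "less", "increasing": "greater"}[
        alternative
    ]
    _, p = stats.kendalltau(np.arange(n), x, alternative=alt)
    return s, float(p)


# ---------------------------------------------------------------------------
# Temporal compression
# ---------------------------------------------------------------------------

@dataclass
class CompressionFit:
    """Per-repeat medians of normalized pattern duration and their trend.

    Durations are normalized by each template's mean duration, pooled by
    repeat index, summarized as median +/- median absolute deviation, and
    fit by ordinary least squares (median vs repeat index).
    """

    repeat_indices: np.ndarray
    medians: np.ndarray
    mads: np.ndarray
    counts: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    n_patterns: int
    n_occurrences: int
    mk_statistic: int
    mk_p_decreasing: float


def compression_regression(
    groups: Mapping[int, Sequence[tuple[int, float]]],
    min_count_per_repeat: int = 3,
    max_repeat: Optional[int] = None,
) -> CompressionFit:
    """Fit the temporal-compression trend over pattern repeats.

    Parameters
    ----------
    groups
        Mapping from template id to its occurrences as ``(repeat_index,
        duration_ms)`` pairs; repeat indices are 1-based ranks in time.
    min_count_per_repeat
        Repeat indices supported by fewer occurrences (pooled over
        templates) are dropped before the fit.
    max_repeat
        Optional cap on the repeat index entering the fit.

    Notes
    -----
    If all pooled medians are identical the slope is 0 and R^2 is defined
    as 0 (the SS_tot = 0 convention; logged).
    """
    per_repeat: dict[int, list[float]] = {}
    n_occ = 0
    n_pat = 0
    for _tid, occ in groups.items():
        occ = list(occ)
        if not occ:
            continue
        n_pat += 1
        durations = np.asarray([d for _r, d in occ], dtype=float)
        mean_dur = durations.mean()
        for (r, d) in occ:
            n_occ += 1
            if max_repeat is not None and r > max_repeat:
                continue
            norm = d / mean_dur if mean_dur > 0 else 1.0
            per_repeat.setdefault(int(r), []).append(norm)

    reps = np.array(
        sorted(r for r, v in per_repeat.items() if len(v) >= min_count_per_repeat),
        dtype=int,
    )
    if len(reps) < 2:
        raise ValueError(
            "need at least 2 repeat indices with sufficient occurrence counts"
        )
    medians = np.array([np.median(per_repeat[r]) for r in reps])
    mads = np.array(
        [np.median(np.abs(per_repeat[r] - np.median(per_repeat[r]))) for r in reps]
    )
    counts = np.array([len(per_repeat[r]) for r in reps])

    x = reps.astype(float)
    slope, intercept = np.polyfit(x, medians, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((medians - pred) ** 2))
    ss_tot = float(np.sum((medians - medians.mean()) ** 2))
    if ss_tot == 0.0:
        logger.info("all per-repeat medians identical; defining R^2 = 0")
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    mk_s, mk_p = mann_kendall(medians, alternative="decreasing")
    return CompressionFit(
        repeat_indices=reps,
        medians=medians,
        mads=mads,
        counts=counts,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_patterns=n_pat,
        n_occurrences=n_occ,
        mk_statistic=mk_s,
        mk_p_decreasing=mk_p,
    )


# ---------------------------------------------------------------------------
# Synchrony concentration
# ---------------------------------------------------------------------------

@dataclass
class SynchronyStats:
    """Cross-neuron first-spike dispersion at each pattern presentation."""

    dispersions: np.ndarray  # NaN where < 2 neurons responded
    n_excluded: int  # presentations with < 2 responders
    threshold: float
    fraction_synchronous: float  # dispersion <= threshold, all presentations
    fraction_early: float  # ... over the first half
    fraction_late: float  # ... over the second half


def synchrony_concentration(
    output: SpikeTrainSet,
    onsets: Sequence[float],
    window: float,
    threshold: float = 5.0,
) -> SynchronyStats:
    """Dispersion (max - min) of per-neuron first spikes after each onset.

    Presentations where fewer than two neurons respond are excluded from
    the dispersion fractions but counted in ``n_excluded``.
    """
    if output.n_units < 2:
        raise ValueError("synchrony requires at least 2 neurons")
    onsets = np.asarray(onsets, dtype=float)
    disp = np.full(len(onsets), np.nan)
    for i, onset in enumerate(onsets):
        ev = output.window(onset, onset + window)
        if len(ev) == 0:
            continue
        firsts = []
        for u in np.unique(ev["unit"]):
            firsts.append(ev["time"][ev["unit"] == u][0])
        if len(firsts) >= 2:
            disp[i] = max(firsts) - min(firsts)
    valid = ~np.isnan(disp)
    half = len(onsets) // 2

    def frac(mask: np.ndarray) -> float:
        m = valid & mask
        return float(np.mean(disp[m] <= threshold)) if m.any() else float("nan")

    all_mask = np.ones(len(onsets), dtype=bool)
    early_mask = np.zeros(len(onsets), dtype=bool)
    early_mask[:half] = True
    return SynchronyStats(
        dispersions=disp,
        n_excluded=int((~valid).sum()),
        threshold=threshold,
        fraction_synchronous=frac(all_mask),
        fraction_early=frac(early_mask),
        fraction_late=frac(~early_mask),
    )


# ---------------------------------------------------------------------------
# Sparsening
# ---------------------------------------------------------------------------

@dataclass
class SparsenessStats:
    """Spikes per neuron per presentation across learning quintiles."""

    quantile_means: np.ndarray
    n_quantiles: int
    mk_statistic: int
    mk_p_decreasing: float
    per_presentation: np.ndarray


def sparseness_trend(
    output: SpikeTrainSet,
    onsets: Sequence[float],
    window: float,
    n_quantiles: int = 5,
) -> SparsenessStats:
    """Mean output spikes per neuron per presentation, per learning quintile."""
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) < n_quantiles:
        raise ValueError("need at least one presentation per quantile")
    n_neurons = max(output.n_units, 1)
    counts = np.array(
        [len(output.window(o, o + window)) / n_neurons for o in onsets]
    )
    chunks = np.array_split(counts, n_quantiles)
    qmeans = np.array([c.mean() for c in chunks])
    mk_s, mk_p = mann_kendall(qmeans, alternative="decreasing")
    return SparsenessStats(
        quantile_means=qmeans,
        n_quantiles=n_quantiles,
        mk_statistic=mk_s,
        mk_p_decreasing=mk_p,
        per_presentation=counts,
    )


# ---------------------------------------------------------------------------
# Phase locking
# ---------------------------------------------------------------------------

@dataclass
class PhaseLocking:
    """Vector strength of spike phases on a reference oscillation cycle."""

    vector_strength: float
    rayleigh_p: float
    n_spikes: int
    reliable: bool  # False when n < 10 (Rayleigh approximation unstable)


def phase_locking(spike_times: Sequence[float], osc_period: float) -> PhaseLocking:
    """Vector strength and Rayleigh test of spike phases.

    Phases are ``2 pi (t mod period) / period``; vector strength is the
    resultant length ``|sum exp(i theta)| / n`` (1 = perfect locking, 0 =
    uniform).  The Rayleigh p-value uses the large-n approximation
    ``p = exp(-n VS^2)``; with fewer than 10 spikes the VS is still
    returned but the p-value is flagged unreliable.
    """
    t = np.asarray(spike_times, dtype=float)
    n = len(t)
    if osc_period <= 0:
        raise ValueError("osc_period must be positive")
    if n == 0:
        return PhaseLocking(float("nan"), 1.0, 0, False)
    theta = 2.0 * np.pi * np.mod(t, osc_period) / osc_period
    vs = float(np.abs(np.exp(1j * theta).mean()))
    p = float(math.exp(-n * vs * vs))
    reliable = n >= 10
    if not reliable:
        logger.info("phase_locking: only %d spikes; Rayleigh p unreliable", n)
    return PhaseLocking(vs, p, n, reliable)
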