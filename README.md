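# stdpsync

**Synchrony through synaptic plasticity, simulated and tested.**

How do groups of neurons come to fire together within a few milliseconds
without being wired to each other?  One candidate mechanism is learning:
under spike-timing-dependent plasticity (STDP), synapses whose input
consistently precedes the postsynaptic spike are strengthened and the
others weakened, so a neuron driven by a recurring spatiotemporal input
pattern responds ever earlier, until it fires at the pattern's onset.
Several neurons receiving *coherent* (not identical) input that shares the
same temporal origin will each track back to that origin — and end up
firing in near-synchrony, with no connection between them.

`stdpsync` is a desk-scale toolkit for exercising this mechanism and its
three testable consequences:

1. **Latency reduction** — a single STDP neuron learns to respond to the
   onset of a repeating ~50 ms pattern embedded in Poisson afferent trains,
   with first-spike latency falling to a few milliseconds.
2. **Temporal compression** — recurring multineuronal spike patterns,
   recovered by sliding-window mining, shorten progressively across their
   repeats while the population is learning.
3. **Sparsening and synchrony** — responses concentrate into brief,
   near-synchronous volleys (pattern durations peaking below 5 ms) with
   fewer spikes per neuron per event.

An optional subthreshold oscillation mode demonstrates phase gating:
a slow sinusoidal drive confines spiking of a tonically excited neuron to
the depolarizing phase of the cycle.

## The model

The readout neuron is a current-based leaky integrate-and-fire unit.  Each
presynaptic spike of afferent *i* with efficacy *w<sub>i</sub>* ∈
[*w*<sub>min</sub>, *w*<sub>max</sub>] contributes a peak-normalized
double-exponential EPSP

&nbsp;&nbsp;&nbsp;&nbsp;*K*(*t*) = *c* (e<sup>−t/τ<sub>m</sub></sup> − e<sup>−t/τ<sub>s</sub></sup>),&nbsp;&nbsp; max<sub>t</sub> *K* = 1,

with τ<sub>m</sub> = 10 ms, τ<sub>s</sub> = 2.5 ms, so postsynaptic
potentials are effectively integrated over a 20–30 ms window.  A spike is
emitted when Σ<sub>i</sub> *w<sub>i</sub>* Σ<sub>k</sub> *K*(*t* −
*t<sub>i,k</sub>*) + tonic + oscillation reaches threshold outside the
refractory period.  Weights follow the classical additive STDP window

&nbsp;&nbsp;&nbsp;&nbsp;Δ*w* = +*A*₊ e<sup>−Δt/τ₊</sup> (pre before post, Δt ≥ 0),&nbsp;&nbsp;
Δ*w* = −*A*₋ e<sup>Δt/τ₋</sup> (post before pre),

applied in the all-pairs (trace) scheme with integral depression dominance
(*A*₋τ₋ > *A*₊τ₊), which drives uncorrelated afferents down and lets the
pattern-locked ones win.

Recurring multineuronal patterns are mined with a 50 ms sliding window:
every window anchored at a spike yields a candidate constellation, and
candidates match when the same per-unit spike multiset aligns within a
per-spike tolerance after one global time shift.  Chance levels come from
dither surrogates (each spike displaced uniformly within ±25 ms, counts
conserved): a template-size class is kept only where the original template
count strictly exceeds the (1 − α) surrogate quantile.

## Worked example

```bash
stdpsync demo-latency --seed 1 --out runs/latency
```

prints (and writes to `runs/latency/summary.tsv`):

```
n_presentations         608
early_median_latency_ms 7.8661
late_median_latency_ms  4.9545
hit_rate                0.8421
false_alarm_rate_per_s  1.965
n_output_spikes         973
```

Over 608 presentations of the embedded pattern the median first-spike
latency falls from ~8 ms (median over the first 100 presentations — single
presentations start near 30–40 ms before the unselective early phase ends)
to just under 5 ms, while the neuron responds to 84% of late presentations
and fires less than 2 spikes/s elsewhere: it has become a fast, reliable,
selective onset detector.

The population experiment with all three prediction statistics:

```bash
stdpsync demo-population --seed 1 --out runs/population
```

```
n_neurons                    6
n_presentations              1232
median_late_latency_ms       4.1206
n_validated_patterns         61
modal_duration_bin_start_ms  0.0
modal_duration_bin_end_ms    5.0
sync_fraction_early          0.7727
sync_fraction_late           0.9205
sparseness_first_quintile    1.1113
sparseness_last_quintile     1.0407
compression_slope            -0.016577
compression_mk_p             0.001497
compression_r_squared        0.3253
compression_n_repeats        20
```

Six unconnected STDP neurons driven by coherent inputs (half their pattern
units shared) converge to ~4 ms onset latency; mining the converged output
validates 61 recurring patterns whose duration histogram peaks in the
lowest (0–5 ms) bin; the fraction of presentations with cross-neuron
dispersion ≤ 5 ms rises from 0.77 to 0.92; spikes per neuron per
presentation decline; and during learning the per-repeat median normalized
pattern duration falls (slope −0.017 per repeat, one-sided Mann–Kendall
p = 0.0015).

Other subcommands: `generate` (afferent trains + ground truth to TSV),
`simulate`, `mine`, `analyze`; all accept `--config <yaml>` overriding any
default (unknown keys are rejected) and a single `--seed` that fans out to
per-module substreams.

## Layout

- `src/stdpsync/input_synth.py` — Poisson afferents + embedded frozen
  patterns (ground truth retained)
- `src/stdpsync/stdp_core.py` — LIF membrane + additive STDP (numba core)
- `src/stdpsync/population_sim.py` — independent-readout population driver,
  latency trajectories, oscillation gating experiment
- `src/stdpsync/pattern_mining.py` — sliding-window miner + dither
  surrogate validation
- `src/stdpsync/analysis_metrics.py` — compression regression, synchrony,
  sparseness, phase locking
- `src/stdpsync/cli_io.py` — TSV formats, config tree, pipelines, CLI
- `docs/methods.md` — model details, parameter rationale, limitations
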