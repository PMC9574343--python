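# Methods

## Model

### Membrane and synapse

The readout neuron is a current-based leaky integrate-and-fire unit with a
peak-normalized double-exponential EPSP kernel,

    K(t) = c (exp(-t/tau_m) - exp(-t/tau_s)),  t >= 0,  max K = 1,

and membrane potential

    V(t) = sum_i w_i sum_k K(t - t_ik) + I_tonic + A_osc sin(2 pi t / T_osc).

A spike is recorded at the integration step where `V >= threshold` outside
the absolute refractory period; the synaptic traces are then cleared
(spike reset) and afferent spikes arriving during the refractory period do
not contribute to the potential (they still update the plasticity
bookkeeping).  Potentials are dimensionless: resting level 0, unit-weight
EPSP peak 1.  The kernel sum is maintained by two exponential traces (one
per time constant), so integration cost is O(steps + input spikes); the
inner loop is compiled with numba.

Assumptions worth stating: synapses are current sources (no conductance or
reversal potentials, no dendrites); the subthreshold oscillation is an
additive current, i.e. pure excitability modulation; there is no
short-term plasticity, no inhibition, and readout neurons are mutually
unconnected.  The last point is deliberate — it tests the strongest form
of the population claim, synchrony without any coupling.

### Plasticity

Additive STDP with exponential windows:

    dw = +a_plus  * exp(-dt/tau_plus),  dt = t_post - t_pre >= 0
    dw = -a_minus * exp(+dt/tau_minus), dt < 0

`dt = 0` is assigned to the potentiation branch (convention).  Weights are
hard-clipped to `[w_min, w_max]` after every update.  The default pairing
scheme is *all-pairs*, implemented with the standard pre/post traces
(potentiation collects `a_plus * x_i` at each postsynaptic spike,
depression collects `a_minus * y` at each presynaptic spike).  Trace decay
is applied per integration step, so pairing lags are resolved at `dt_sim`
granularity; nearest-neighbor pairing (exact lags) is selectable.

All-pairs rather than nearest-neighbor is the default for a measured
reason: with 100 afferents at 20 Hz, the reduced nearest-neighbor scheme
(each postsynaptic spike pairs with every afferent's most recent spike)
becomes bistable — above roughly 100 Hz output the potentiation flux
outruns depression and every weight saturates, which the uniform initial
weights trigger.  Under all-pairs the uncorrelated drift is
`r_pre * r_post * (a_plus tau_plus - a_minus tau_minus)`, negative at any
rate when depression dominates integrally, which is the stability
condition the competitive-STDP literature relies on.

### Default parameters

| parameter | value | units | why |
|---|---|---|---|
| tau_m | 10 | ms | effective EPSP integration confined to ~20-30 ms |
| tau_s | 2.5 | ms | fast synaptic rise; dt_sim = 0.1 ms resolves it 25x |
| threshold | 5 | EPSP peaks | ~5 near-coincident potentiated afferents needed; see below |
| refractory | 5 | ms | one response per pattern occurrence after convergence |
| reset | 0 | — | return to rest |
| tau_plus / tau_minus | 16 / 32 | ms | potentiation window inside the EPSP integration span; wider depression |
| a_plus | 0.05 | — | learning converges in ~300-600 pattern presentations |
| a_minus | 0.04 | — | a_minus tau_minus = 1.6 a_plus tau_plus, depression-dominant |
| w bounds | [0, 1] | — | hard additive-STDP bounds |
| weight init | U[w_min, w_max] | — | unbiased, reproducible from the run seed |

The threshold sets the operating regime at both ends of learning.  With
uniform initial weights the mean background drive is ~16 EPSP peaks, far
above threshold: the neuron starts in an unselective high-rate phase and
depression prunes it.  After convergence only afferents whose pattern
spikes fall in the first few milliseconds keep `w ~ w_max`, and threshold 5
then requires ~5 near-coincident potentiated spikes — satisfied at pattern
onset (pattern spike density ~1/ms) but rarely by Poisson background, so
the converged neuron is selective (~1-2 false alarms/s).  A much lower
threshold (e.g. 1) pins the neuron at the refractory limit and makes every
statistic trivial; a much higher one prevents the converged state from
firing at all.

The depression/potentiation integral ratio 1.6 was chosen on the fixed
study conditions from a coarse grid: at 1.1 background weights equilibrate
near 0.33 with ~30 Hz output and no selectivity; at 2.0 learning is
selective but convergence is slow and occasionally incomplete; at 1.6 all
probed seeds converge and the latency trajectory reproduces the
~35 ms → ~5 ms reduction.  `a_plus = 0.05` (with `a_minus` scaled) makes
population runs converge reliably within 400 s; the single-neuron result
is insensitive to this choice between 0.03 and 0.05.

## Synthetic afferents

The generator emulates the experimental input regime: `n_units = 100`
independent homogeneous Poisson trains at 20 Hz for 200 s (single-neuron
experiment) or 400 s (population experiment, which must reach convergence
*and* leave a converged tail to mine).  Half of the units additionally
carry a frozen pattern: one spike per member at a fixed offset drawn
uniformly on the 50 ms pattern length, recurring at onsets spaced by
uniform gaps on [150, 500] ms (~2.7 occurrences/s, non-overlapping), with
1 ms Gaussian per-spike jitter.  Pattern spikes superimpose on the
background by default; a `replace_window` mode removes the members'
background spikes inside each occurrence to keep in-window rates at
baseline (superimposition raises them by ~50%, a confound worth
controlling for).  Every dataset carries its ground truth (members,
offsets, onsets) so latency and recall are scored against truth, never
against a re-detection.

For populations, `make_coherent_input_set` draws per-neuron patterns that
share occurrence onsets (optionally shifted per neuron) and a configurable
fraction of member units with their offsets (default overlap 0.5); the
rest of the members, all offsets of non-shared members, and all
backgrounds are independent.

What the generator does *not* emulate: rate-modulated or bursty
background, multi-spike per-member patterns by default, correlated noise
across afferents, and any feedback from the readout to the afferents.
Passing tests therefore show that the mechanism works under clean
stationary-Poisson conditions, not that it is robust to natural input
statistics.

## Pattern mining

Candidates are read from every window `[t_i, t_i + 50 ms)` anchored at an
event; those with >= 3 distinct units enter greedy clustering in time
order.  Two constellations match when they have the same per-unit spike
multiset and one global shift brings every paired spike within the
tolerance; pairing within a unit is order-preserving, and the optimal
shift has max residual `(max d - min d)/2` for the pairwise differences
`d`.  A candidate joins the best-matching template (smallest residual,
ties to the earlier-founded template) or founds a new one.  Occurrences of
a template may not overlap (greedy earliest-first acceptance); templates
with >= 2 accepted occurrences are reported, occurrences ranked 1-based by
anchor time.  Matching is exact-constellation (`max_missing = 0`): a
background spike inside a window makes that window a different candidate.
This keeps the procedure deterministic and checkable against brute-force
enumeration, at the cost of recall in dense backgrounds — acceptable here
because the mined data are the readouts' sparse output trains, not the
afferents.

Significance: 100 dither surrogates displace every spike independently by
U[-25, +25] ms with reflection at the recording boundaries (per-unit
counts conserved), destroying millisecond coordination while preserving
rates.  Per template-size class (element count), the chance level is the
empirical (1 - alpha) quantile — order statistic `floor((1-alpha) n)`,
i.e. the surrogate maximum at alpha = 0.01 with n = 100 — of the
per-surrogate template count, and likewise of the per-surrogate maximum
occurrence count.  A template is validated only if its class count
strictly exceeds the former and its own occurrence count strictly exceeds
the latter; ties fail.  On pure Poisson data this keeps the fraction of
runs with any validated template at or below 2 alpha.

## Statistics

*Latency*: first output spike in `[onset, onset + pattern length + 25 ms]`
per ground-truth onset; misses recorded but excluded from medians (the
margin accommodates pre-learning latencies near the pattern's end plus one
EPSP width).  *Synchrony concentration*: per presentation, the span
(max - min) of per-neuron first spikes; fractions with span <= 5 ms
compared between run halves.  *Sparseness*: spikes per neuron per
presentation, averaged within quintiles of the learning segment;
monotonic trend by the Mann-Kendall sign statistic.  *Phase locking*:
vector strength of spike phases on the oscillation cycle with the large-n
Rayleigh approximation `p = exp(-n VS^2)` (flagged unreliable below 10
spikes).  *Compression*: every occurrence's duration (first-to-last
matched spike) is divided by its template's mean duration; per-repeat
medians and median absolute deviations are computed over repeat indices
with >= 3 pooled occurrences, and an ordinary least-squares line is fit to
median vs repeat index (R^2 = 1 - SS_res/SS_tot, defined as 0 when all
medians coincide).  "Median deviation" is read as the median absolute
deviation from the median.

### Where compression is measured

Compression is a learning-phase phenomenon: once every neuron responds at
its converged latency, pattern durations are stationary by definition, so
pooling converged-phase occurrences dilutes any trend toward zero.  The
compression pipeline therefore (a) mines the first 150 s of the population
run with a wider 10 ms tolerance — a deforming pattern must stay matchable
to its template while it compresses, and matching tolerates span changes
up to twice the tolerance; (b) keeps only templates first seen within the
first 60 s (founded while latencies are still moving); and (c) caps the
fitted repeat range at 20, past which surviving templates are converged
and flat.  These are fixed pipeline constants, not per-run choices.  The
regression is fit to per-repeat medians; a raw-occurrence fit would need
cluster-robust errors because occurrences of one template are serially
dependent.

The trend is asserted as a negative slope with a one-sided (decreasing)
Mann-Kendall p < 0.05.  Elementwise non-increase of ~20 stochastic medians
is not a meaningful requirement (any noise breaks one pair); the
Mann-Kendall test is the standard operationalization of a monotone
decreasing trend.  R^2 of the simulated compression (typically 0.2-0.5 at
this scale) is reported, never asserted: near-perfect linearity of the
per-repeat medians requires orders of magnitude more patterns than a
desk-scale run yields.

### Oscillation gating experiment

20 fixed-weight (0.5) Poisson afferents at 10 Hz plus a tonic drive of 3.8
put the mean potential just above threshold 5; a 200 ms-period sinusoid of
amplitude 1 (period 20x the membrane time constant) is switched on or off.
Vector strength under modulation (~0.4) is compared with the control
(~0.01, Rayleigh non-significant) across seeds by a paired one-sided
Wilcoxon test.

## Numerical choices

Fixed-step clock-driven integration at `dt_sim = 0.1 ms` (25x finer than
tau_s); spike time = the step of threshold crossing, no sub-step
interpolation, so all outputs are bit-reproducible for a given seed and
configuration.  Non-finite potentials abort with a diagnostic.  Weight
snapshots default to 1 s intervals.  All randomness flows from one
integer seed through named `SeedSequence` substreams (CRC-32 of the stream
name), so the generator, weight init, population, mining surrogates and
compression surrogates can be re-run independently yet reproducibly;
derived seeds stay below 2^31.  Duration-histogram ties go to the lowest
bin; surrogate quantile ties fail validation (strict inequality).

Problem sizes used by the shipped experiments: 200 s single-neuron runs
(~530-630 pattern presentations), 400 s six-neuron population runs
(~1100-1300 presentations), 80 s converged tails for validated mining, 10
seeds for all seed-count claims.  The reproduction script pools the
validated-duration histograms of 3 replicate populations before taking
the modal bin, as the original distribution pools multiple recordings.

## Known limitations

- Exact-constellation matching bounds mining recall in dense backgrounds;
  mining is intended for the sparse readout trains.
- The compression trend at desk scale is noisy; roughly one seed in ten
  misses p < 0.05 despite a negative slope.
- The latency floor (~3-5 ms) is set by threshold and pattern spike
  density, not by the 0.1 ms integration step; pushing below it requires
  denser patterns or lower thresholds (at the cost of false alarms).
- Nearest-neighbor pairing is provided but not stable under the default
  input statistics (see above); use it only with parameter regimes whose
  equilibrium you have checked.
- The all-pairs trace implementation resolves pairing lags at integration-
  step granularity (0.1 ms), a negligible bias at the default window
  constants but one that grows with `dt_sim`.
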