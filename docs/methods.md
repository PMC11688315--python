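# Methods

This note documents the definitions, models and numerical conventions the
package implements, the design choices made where the design was genuinely
open, and the limits of what the synthetic-data studies demonstrate.

## Copied-visit detection

A drinking corner is *demonstrated* immediately after any animal's visit
there. A visit by animal B at corner c is a **copied visit** when the most
recent earlier visit at c inside the analysis window was by a different
animal A and B's entry follows with latency below the threshold
(default 4 s, strict `<`; a latency of exactly 4.0 s is not a copy, 0 s
is). Every visit re-demonstrates the corner: chains A→B→C produce two
events, a visit copies at most one leader (the immediately preceding
occupant), and self-succession is never a copy.

**Latency reference.** The latency is measured from the previous
occupant's *exit* to the follower's *entry*. The corner admits one animal
at a time, so an entry-to-entry reference would conflate long leader
visits with slow following; entry-to-entry remains available
(`latency_reference="entry"`) for sensitivity analysis. This choice is an
assumption of this implementation and is recorded in every report's
provenance block.

Both the leader's and the follower's entries must fall inside the
half-open analysis window. Detection is deterministic in the input row
order (an internal sort fixes the order) and, by construction, equivalent
to an exhaustive scan of all ordered visit pairs — an equivalence the test
suite checks against a brute-force oracle on over a thousand random logs.

## Graphs and engagement metrics

Per cage, nodes are animals with an activation state: the demonstrator;
*activated* observers (≥ 1 visit, un-normalized, with entry inside the
contagion window); *passive* observers (none). Each copied visit
increments the weight of the unordered {leader, follower} pair — the
**association index**. Followers are counted among observers only (the
demonstrator may lead but its follows are not follower events), while
nodes and possible edges (N²−N)/2 include the demonstrator. Pooled strain
metrics are plain sums over cages; pooling across strains is an error.

## Window summaries and normalization

Four parameters per animal and window: total visits, drinking visits,
inspection visits, total licking time (s). A visit is *drinking* iff it
registered ≥ 1 lick (`drinking_key="lick_duration"` switches to positive
lick contact time; the two coincide on data satisfying the licking-signal
invariant, so the choice only matters for logs from hardware with one
sensor absent). Window membership is by *entry time* in a half-open
`[start, end)` interval: attribution follows the moment the approach
decision was made, and half-open windows partition time without double
counting. Attribution by overlap fraction was considered and rejected as
an undocumented convention; entry attribution is flagged as an assumption.

The 3 h baseline is divided by 6 to match the 30-min contagion window; the
divisor applies to all four parameters, licking time included, and
defaults to the baseline/contagion length ratio. Summaries are additive
over a partition of time and linear in the divisor — both are property-
tested — and for a homogeneous Poisson visit process the normalized
baseline count is an unbiased estimate of the 30-min count.

## Statistical battery

* **Pooled 2×2 chi-square** — uncorrected Pearson,
  `N(ad−bc)²/(r₁r₂c₁c₂)`, df 1, two-sided. The continuity correction is
  available but off by default: pooled cohort comparisons in this paradigm
  are conventionally reported uncorrected, and the uncorrected form is
  what the reference statistics of this literature correspond to. A zero
  column marginal is reported as undefined, never silently patched.
* **Nested ANOVA** — strain, with cage nested in strain, by the explicit
  hierarchical sums-of-squares decomposition. The strain effect is tested
  against the residual mean square by default (`error_term="cage"` tests
  it against cage(strain) instead). Cages with a single animal are an
  error (no within-cage variance).
* **Mixed repeated-measures ANOVA** — one within factor (baseline vs
  contagion, or morning vs midday) and one between factor (cage or
  strain), computed by `pingouin.mixed_anova`. A subject missing a
  condition is an error; nothing is imputed. Zero-variance degenerate
  inputs resolve explicitly: a zero effect SS gives F = 0, a positive
  effect SS over a zero error SS gives unbounded evidence (p = 0).
* **Degrees-of-freedom reporting.** F statistics are always formed from
  the standard mean squares. Two reporting conventions exist for the
  denominator df: `"residual"` — the textbook error df — and `"reported"`
  (default) — the number of subjects minus one, the convention used in the
  behavioral-contagion literature this tool targets (31 observers in 8
  cages report strain as F(1, 30) and cage(strain) as F(6, 30); 15
  subjects in 4 cages report the within effect as F(1, 14)). p-values are
  computed from the df pair actually reported, so the F→p mapping is
  internally consistent under either convention; calibration studies use
  the residual convention.
* **Spearman screen** — tie-corrected rank correlations of baseline vs
  contagion parameters across animals; zeros are valid ranks, constant
  vectors are reported as undefined.
* No multiplicity correction is applied (none is conventional for this
  battery); every report carries the number of tests run so readers can
  apply their own.

## The colony simulator

One cage holds N animals (default 5: one demonstrator, N−1 observers) and
2 corners. The default time axis puts the circadian habituation block on
day 0 (09:00–15:00) and the test day on day 1: baseline 08:50–11:50,
reintroduction 12:01, contagion window the following 30 min.

Generative components:

| parameter | default | meaning / rationale |
|---|---|---|
| `lambda0` | 1.2 /h (control-like), 0.8 /h (model-like) | observer baseline visit rate; anchored to printed light-phase activity of roughly 0.6 visits per 30 min, with the model-like cohort scaled down in proportion to its lower baseline activation |
| `p_copy` | 0.6 / 0.05 | per-witnessed-visit copy probability per observer; presets encode a responsive vs attenuated cohort |
| `f_fast`, `fast_latency_max` | 0.7 / 0.5, 3 s | fraction and range of short uniform copy latencies (inside the 4-s detection window) |
| `slow_latency_mean` | 60 s | exponential tail of delayed following, truncated at the simulated span's end; no quantitative observer-latency distribution is available, so the mixture is a documented placeholder |
| `demo_rate0`, `demo_decay_tau` | 60 /h, 1200 s | demonstrator bout train: inhomogeneous Poisson with exponentially decaying rate from reintroduction — dense serial drinking concentrated in the first hour, ≈ 15 visits in the 30-min window |
| `visit_duration_mean/jitter/min` | 8 / 3 / 1 s | truncated-normal visit duration |
| `door_open_time` | 15 s | caps a single visit's drinking time |
| `refractory_period` | 300 s | a just-visited animal cannot be re-triggered (see below) |
| `p_drink_observer/demonstrator` | 0.5 / 0.9 | probability a visit includes licking |

**Triggering.** After every completed visit, each other present,
triggerable animal independently schedules a follow-up visit to the same
corner with probability `p_copy` and a latency drawn from the mixture.
Copy visits are ordinary visits and can themselves be copied, so cascades
emerge from a one-step mechanism. Two constraints keep the process
physical:

1. *Refractoriness* — an animal whose last exit is less than
   `refractory_period` ago cannot be re-triggered. Without it, any
   `p_copy ≥ 1/(N−1)` makes the triggered process supercritical and
   observer-observer cascades saturate the cage around the clock,
   contradicting the low baseline rates the method assumes; with it,
   spontaneous baseline visits ignite short self-limiting bursts while the
   demonstrator's sustained bout train drives contagion-window activity.
   The default (5 min, a short-term disengagement scale) caps triggered
   revisits at 12/h per animal.
2. *Single intent* — an animal holds at most one pending scheduled visit;
   being re-triggered while already intending does not create a second
   visit.

**Occupancy.** One animal per corner and one corner per animal at a time.
A scheduled entry during occupancy is delayed until both are free, which
realistically converts simultaneous intents into rapid chains and can push
a copy's measured latency past the detection threshold. The event queue is
a deterministic heap keyed by (time, sequence number); a configurable
event cap turns a non-draining queue (infeasible rates) into a diagnostic
error. `(config, profile, seed)` fixes the event stream bit for bit.

## Parameter recovery

The recovery study estimates `lambda0` from the mean observer baseline-
window count per hour, and `p_copy` from detected copied visits over
*triggerable copy opportunities*, corrected by the detectable-latency
fraction q of the mixture (the mass below the 4-s threshold). Three
design decisions matter:

* **Dyads.** The study runs in 2-animal cages: with larger groups and
  high `p_copy` the branching factor `p_copy·(N−1)` exceeds one, occupancy
  throttles the cascade, and the copied-visit fraction saturates — the
  proxy loses monotone identifiability. In a dyad the branching factor is
  `p_copy` itself. The demonstrator's absence during baseline also makes
  the baseline-rate estimator clean (nothing can trigger a lone animal).
* **Observer followers only.** Numerator and denominator are restricted
  to observers as followers, mirroring the follower metric; the
  demonstrator's dense bout train otherwise contributes queued re-entries
  that land within the threshold of an observer's exit by co-timing alone
  and inflate the proxy.
* **Pooled ratio.** The estimate is `Σ copied / (Σ opportunities · q)`
  across seeds, not the mean of per-seed ratios: a successful trigger
  makes the follower refractory and truncates that seed's opportunity
  count, so per-seed ratios are upward-biased under this adaptive stopping
  while the pooled ratio is not (≈ 15% inflation at `p_copy` = 0.2 was
  measured for the per-seed version during development). The standard
  ratio-estimator SE accompanies the estimate.

Residual bias sources, accepted and documented: chance co-timing adds a
small positive offset (the proxy reads ≈ 0.01 when the kernel is off);
pending-intent blocking, invisible in the log, slightly inflates the
opportunity count at high `p_copy` (the proxy reads ≈ 0.76 at a true 0.8).
The proxy is strictly monotone over {0, 0.2, 0.5, 0.8} and unbiased within
Monte-Carlo error in the moderate regime the acceptance study asserts.

## Calibration studies

The null colony has two pseudo-strains with identical profiles and the
copying kernel off, 4 cages × 5 animals each. Type-I error is measured
for the pooled activation chi-square (between pseudo-strains) and for the
within effect of the RM ANOVA (baseline vs contagion total visits, one
pseudo-strain, residual df convention). Both sit near the nominal 5%
(measured 0.050 and 0.051 over 2000 colonies). Note the tests run on
discrete, skewed counts at modest n: exact enumeration of the binomial
activation table puts the chi-square's true level between 0.04 and 0.06
across the plausible rate range, so the nominal level is an approximation
inherent to the method, not to this implementation. The control-like vs
model-like contrast (activation proportions ≈ 1.00 vs ≈ 0.74) is detected
by the pooled chi-square in ≈ 60% of colonies at these group sizes.

## What the simulator does and does not emulate

It reproduces the *structure* the method assumes — sparse baseline
activity, a dense decaying demonstrator bout train, short-latency copying
with occupancy interference — and therefore validates the detection,
graph, pooling and testing machinery end to end. It does not model
between-animal rate heterogeneity (real cohorts are overdispersed:
roughly half the observers never visit during a 3 h baseline while the
printed mean rate implies most would), circadian rhythm beyond the two
habituation windows, corner-preference or spatial movement, satiation
dynamics beyond the fixed refractory period, or sensory channels of
contagion other than the visit event itself. Passing calibration on
synthetic colonies therefore demonstrates correctness of the pipeline
under the stated generative assumptions, not that real cohorts meet those
assumptions.

## Numerical conventions

Timestamps are float seconds from a per-experiment epoch; ISO wall-clock
input is converted once at the I/O boundary (epoch key, or midnight of the
earliest date). Visit identity is (cage, corner, entry); duplicates are
an error, not deduplicated — hardware does not emit true duplicates, a
parse bug does. Validation is total: every malformed row is reported with
its position, never silently dropped. A follower entry exactly at the
leader's exit is latency 0 and counts; simultaneous same-corner entries
are impossible by the occupancy invariant. Reports serialize with sorted
keys and fixed float formatting, so reruns on identical inputs are
byte-identical. Study sizes used by the test suite and the reproduction
script (2000 null colonies, 200 contrast colonies, 100 recovery seeds,
1000+ oracle logs) were chosen to keep Monte-Carlo standard errors well
inside the asserted tolerance bands.
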