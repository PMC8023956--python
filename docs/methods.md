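# Methods

## The LC-CUSUM test

The learning-curve CUSUM monitors a sequence of pass/fail procedure
outcomes and signals competency. It is a sequential likelihood-ratio
test with the burden of proof on the learner: under the null hypothesis
the per-procedure failure rate is at an unacceptable level p₀, and the
chart accumulates log-likelihood-ratio evidence for the alternative of
an adequate rate p₁ = p₀ − δ. The score

S_t = max(0, S_{t−1} + W_t)

takes W_t = ln[(1−p₁)/(1−p₀)] after a success and W_t = ln(p₁/p₀) after
a failure, is clamped at 0 (holding barrier — early failures are not
punished indefinitely), and signals when S_t ≥ h. The signal comparison
is `≥`, chosen so that the continuous design (13 × 0.05716 = 0.7431 ≥
0.74) and the integer design (13 unit steps vs h = 13) signal at the
same consecutive-success count. Increments are stored at full floating
precision; the familiar +0.057/−0.405 are presentation roundings.

Assumptions: outcomes are independent Bernoulli trials at a given skill
level; the binary verdict carries all the information (no partial
credit); monitoring stops at the signal (the state is absorbing).

### Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| p₁ | adequate (acceptable) failure rate | 0.10 | clinical design choice for DHS wire placement |
| δ | equivalence zone, p₀ = p₁ + δ | 0.05 | separation the test must resolve |
| h | signal limit | 0.74 | gives ≈ 0.90 signal probability at p₁ over 50 procedures (see below) |
| horizon | procedures monitored | 50 | one level's procedure budget |

The integer program variant uses steps +1/−7, level width 13, three
levels and a 50-procedure cap per level. Each level's score lives in its
own band (0–13, 13–26, 26–39) and a failure clamps at the band floor —
the published band bounds imply clamp-at-floor, although no such event
is shown explicitly, so the floor clamp is this package's reading. The
program minimum is therefore 39 procedures and the program target score
is 39.

## Operating characteristics

`signal_probability_exact` computes the first-signal distribution by a
forward dynamic program. Because the two increments are incommensurable,
a rounded score grid would bias the result; instead each reachable state
is keyed by (number of successes, number of failures) since the chart
last touched the floor, which identifies the exact score. For the
default design this lattice stays below a thousand states over a
50-procedure horizon, so the DP is exact to floating precision and runs
in milliseconds. The Monte-Carlo route (`signal_probability_mc`) is a
vectorized simulation with a mandatory seed and a binomial standard
error; the two routes are validated against each other (3 SE at 10⁵
replicates across failure rates 0–1) and against brute-force enumeration
of all 2⁸ outcome sequences on a small design.

`calibrate_limit` searches a grid of limits (default step 0.01) because
the OC is a step function of h — it only changes when h crosses a
reachable score — and returns the largest grid limit meeting the power
target, with the achieved probabilities at both design rates.

Computed OC at the default design (all values produced by the exact DP
and cross-checked by the MC oracle in the test suite):

- single continuous chart, h = 0.74, horizon 50: signal probability
  0.9012 at true rate 0.10 and 0.6848 at 0.15;
- single integer level (+1/−7, h = 13, cap 50): 0.9117 and 0.7018;
- full three-level program at a constant rate: 0.7577 at 0.10 and
  0.3456 at 0.15.

A design goal of roughly 91% competency-declaration probability at the
adequate rate is met by the single chart under either variant. A
companion false-positive figure of 12% at the *unacceptable* rate is not
reproducible under any of these readings — the single-chart value at
rate 0.15 is 0.68, and even the stricter whole-program reading gives
0.35. Within this model, a 12% signal probability corresponds to a true
failure rate of about 0.30 (the DP gives 0.1182 there), i.e. to an
"inadequate performer" defined well above p₀. Published operating
characteristics derived from unstated computations should therefore be
checked with the DP rather than quoted; the package deliberately treats
them as properties to recompute, not constants.

## The rule engine

A procedure passes iff every configured criterion holds; the verdict
lists all violated criteria. Defaults (levels 0/1): tip–apex distance
≤ 20 mm, placement zone ∈ {center–center, center–inferior}, no cortical
breach, ≤ 3 K-wire attempts. Level 2 adds: no reamer breach, appropriate
plate angle, bicortical shaft screw. Thresholds are inclusive pass
bounds (failure strictly beyond), matching the "more than 20 mm / more
than 3 attempts" reading. Fluoroscopy time, radiograph count and total
time are carried in the data model but never affect the verdict under
the defaults; a property test enforces this. The complete operational
level-2 criterion list for the original simulator is not public, so the
level-2 defaults beyond the quoted criteria are a reasonable
reconstruction and the whole rule set is overridable from YAML.

## The synthetic cohort generator

The generator exists so that every downstream stage is testable without
real data; it targets structural, not numerical, fidelity.

- **Learning curve.** Failure probability decays exponentially in
  cumulative experience t: p_fail(t) = a + (i₀ − a)·exp(−t/τ). This is
  the simplest monotone model consistent with a learning curve; i₀, a, τ
  are configuration, not code.
- **Default mixture** (32 learners): a *persistent* archetype
  (i₀ = 0.55, a = 0.04, τ = 12, budget 160 procedures — converges below
  the adequate rate, attends all training days) and a *transient*
  archetype (i₀ = 0.70, a = 0.16, τ = 25, budget 60 — plateaus just
  above the unacceptable rate and stops after roughly one day), mixed
  50/50. The persistence budget is a hard cap on total procedures,
  modelling learners who do not return for further training days.
- **Metrics.** Given the verdict, metrics are drawn constructively:
  a passing draw (TAD ~ N(13 mm, 2 mm) truncated to [5, 20], passing
  zone, no breach, ≤ 3 attempts, level-scaled times and radiograph
  counts) is corrupted in one or more randomly chosen criteria for a
  failing draw, then re-assessed by the rule engine until the verdict
  matches (bounded retries; exhaustion signals an inconsistent rule
  set). Every generated row therefore re-assesses to its logged flag
  exactly.
- **Career outcome.** Bernoulli given the program verdict only
  (stay probability 13/14 if passed, 9/18 if failed by default) — the
  minimal structure able to produce a pass/fail × career 2×2 table.
  Richer confounding (e.g. persistence influencing both the verdict and
  the career) can be expressed through profile mixtures but is off by
  default.
- **Determinism.** Each learner receives a child generator spawned from
  the cohort seed; identical config + seed reproduces procedure logs
  byte-identically.

What the generator does *not* emulate: within-day fatigue or session
structure, correlation between consecutive outcomes beyond the smooth
curve, metric distributions conditional on anything but level and
verdict, and informative dropout beyond the hard budget. Passing tests
on synthetic cohorts therefore demonstrates the correctness of the
machinery (charts, rules, statistics), not the realism of any particular
cohort.

## Cohort diagnostics

Point estimates of PPV, NPV, sensitivity and specificity use exact
rational arithmetic before floating. The default 95% interval is the
Wilson score interval, which reproduces the intervals conventionally
reported for such cohorts where the simpler Wald interval does not
(Clopper–Pearson and Wald are available; the method label travels with
the output). For the reference counts (13, 1, 9, 9) the Wilson upper
bounds for PPV and specificity are 0.987 and 0.982 — reported elsewhere
as 100 and 99 after a different convention; the point estimates are
unambiguous. Fisher's exact test uses the two-sided probability-mass
ordering (the total probability of all tables with the observed margins
no more likely than the observed one), verified in tests against
brute-force enumeration; the chi-square test is Pearson's without
continuity correction by default (Yates togglable). Group summaries
report mean with a t-based 95% CI (undefined for a group of one) or
median with range.

## Numerical choices and problem sizes

- Signal comparison uses an absolute tolerance of 1e−12 to guard exact
  integer hits expressed in floating point.
- DP mass bookkeeping conserves probability to 1e−9 per query
  (asserted).
- The test suite exercises Monte-Carlo agreement at 10⁵ replicates and
  parameter recovery with cohorts of 2,000 learners per rate — sizes at
  which the 3-SE acceptance bands are a few tenths of a percentage
  point wide while the whole suite stays fast.
- Sequences longer than the horizon/cap are truncated with a warning
  rather than rejected; `allow_overrun` records extended traces (a
  learner may keep training past the cap) while the pass/fail verdict
  still applies the cap.

## Known limitations

- No risk-adjusted CUSUM, non-binary outcome charts, or Bayesian
  variants; no steady-state average-run-length theory (the finite
  horizon makes the DP exact and sufficient).
- The DP assumes a constant true failure rate; learning curves are
  handled by simulation, not by the DP.
- Program-level probability assumes independent, identically
  distributed procedures within a level and independence across levels.
- Tip–apex distance arrives as a measured value; no 3-D geometry is
  computed.
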