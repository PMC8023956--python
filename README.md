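# lccusum

Sequential competency monitoring for procedural skills training, built
around the learning-curve CUSUM (LC-CUSUM) test, with exact operating
characteristics, a configurable procedure pass/fail rule engine, a
synthetic learner-cohort generator, and cohort-level diagnostic-accuracy
analysis.

It is written for biostatisticians and medical-education researchers who
design or evaluate mastery-learning programs — for example virtual-reality
simulation of dynamic hip screw (DHS) fixation of trochanteric hip
fractures — where each procedure is scored pass/fail and a statistical
rule must decide when a trainee has demonstrated competency.

## The model

The LC-CUSUM inverts the usual control-chart logic: the null hypothesis
is that the learner is **not yet competent** (per-procedure failure rate
at an unacceptable level p₀), and competency is signalled when the
accumulated evidence for an adequate rate p₁ < p₀ crosses a limit h.
The score follows the CUSUM recursion with a holding barrier,

S_t = max(0, S_{t−1} + W_t),  W_t = ln[(1−p₁)/(1−p₀)] on success,
W_t = ln(p₁/p₀) on failure,  signal when S_t ≥ h.

With the clinical defaults — adequate failure rate p₁ = 10%, equivalence
zone δ = 5% (so p₀ = 15%), h = 0.74 over a 50-procedure horizon — the
increments are **+0.057** per success and **−0.405** per failure, and 13
consecutive successes are needed to signal.

A didactically simplified integer variant (+1 per success, −7 per
failure, limit 13) scores a three-level curriculum: repeated K-wire
placement in one patient (CL0), K-wire placement across varying patients
(CL1), and the full DHS procedure (CL2). Each level occupies a 13-point
band (0–13, 13–26, 26–39) with the score clamped at the band floor;
passing the program means signalling all three levels within 50
procedures each, so the fastest possible pass takes exactly **39**
procedures.

The package provides:

- `lccusum.charts` — design construction and chart execution (both
  variants, multi-level program logic, overrun mode);
- `lccusum.oc` — exact first-signal distributions by dynamic programming
  over the lattice of reachable clamped scores, a seeded Monte-Carlo
  oracle, program-level pass probability, and calibration of h;
- `lccusum.assessment` — the conjunctive pass/fail rule engine
  (tip–apex distance ≤ 20 mm, center–center/center–inferior placement,
  no cortical breach, ≤ 3 wire attempts; level 2 adds reamer, plate and
  shaft-screw criteria), configurable via YAML;
- `lccusum.synth` — synthetic learners with exponential-decay learning
  curves, verdict-consistent procedure metrics, and career outcomes;
- `lccusum.diagnostics` — 2×2 predictive values, sensitivity/specificity
  with Wilson intervals, Fisher's exact and chi-square tests, group
  summaries;
- `lccusum.io` / `lccusum.cli` — delimited-text formats, trajectory
  export, the end-to-end pipeline, and the `lccusum` command.

## Worked example

Diagnostic accuracy of a program verdict for a downstream binary outcome
(here: still in the specialty at ≥ 2-year follow-up), from the four cell
counts passed/stayed, passed/left, failed/stayed, failed/left:

```text
$ lccusum diagnostics --counts 13 1 9 9
table: passed_stayed=13 passed_left=1 failed_stayed=9 failed_left=9
ppv=93% (69-99)  npv=50% (29-71)
sensitivity=59% (39-77)  specificity=90% (60-98)  [wilson CI]
fisher_exact_p=0.0189  chi_square=6.7325 (p=0.0095)
```

Passing the program predicts staying (PPV 93%), while failing is an even
coin flip (NPV 50%); the association is significant by Fisher's exact
test (p ≈ 0.02).

Exact operating characteristics of the continuous design (h = 0.74,
horizon 50) over a grid of true failure rates:

```text
$ lccusum oc --rates 0,0.05,0.10,0.15,0.30,1
rate,horizon,signal_probability,expected_run_length,no_signal_probability
0.0,50,1.000000,13.0000,0.000000
0.05,50,0.993031,18.0043,0.006969
0.1,50,0.901244,23.1757,0.098756
0.15,50,0.684815,26.6220,0.315185
0.3,50,0.118183,30.2726,0.881817
1.0,50,0.000000,nan,1.000000
```

A learner whose true failure rate equals the adequate 10% is declared
competent with probability 0.90 within 50 procedures, after 23
procedures on average. The full synthetic pipeline (simulate → assess →
chart → diagnostics) runs with one command:

```text
$ lccusum run-pipeline --seed 7 --out-dir demo
11/32 learners passed (min procedures to pass: 39) -> demo
```

and writes `procedure_log.csv`, `trajectories.csv` (score paths on the
0–39 program scale, ready for replotting), `cohort_summary.csv`,
`diagnostics.json` and a `manifest.json` recording the seed and
configuration hash.

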