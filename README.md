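# operant-iiv

Intra-individual variability (IIV) analysis of operant-chamber behavior.

Subjects with ADHD-like phenotypes are not just *more* active, impulsive or
inattentive on average — their behavior is also more *inconsistent* from
moment to moment. This package quantifies that inconsistency in operant
conditioning data: it turns time-stamped event streams from a two-group
(e.g. Spontaneously Hypertensive Rat vs Wistar-Kyoto control) visual
discrimination experiment into per-session **phenotypic dispersion** scores
for three traits, and tests whether dispersion differs between groups and
changes over time. A synthetic-data generator with the same study structure
makes the whole pipeline testable without animal data.

## The statistic

Each 90-min session is divided into five 18-min segments. For rat *i* with
per-segment trait counts *X<sub>ij</sub>* (*j* = 1..5), the phenotypic
dispersion of that session is the mean absolute deviation from the session
mean:

> PD<sub>i</sub> = (1/5) Σ<sub>j</sub> | X<sub>ij</sub> − X̄<sub>i</sub> |

one value per rat, session and trait. The three traits are:

| trait | definition |
|---|---|
| hyperactivity | all lever presses, minus the impulsive (short-IRT) ones |
| impulsiveness | correct-lever presses whose inter-response time (IRT) < 0.67 s |
| inattention | incorrect openings of the reinforcer-cubicle door |

Excluding short-IRT presses from hyperactivity decouples its dispersion from
impulsiveness, so per segment `impulsiveness + hyperactivity = total lever
presses`. Group inference uses a Kruskal–Wallis rank test on per-rat
session-averaged PD, a general linear model on log(PD + 1) giving F tests,
group means with 95% CIs and the variance proportion η², and
repeated-measures models for among-session (day-to-day) and within-session
(segment 1–5) dispersion trends with per-strain slopes.

## Worked example

```bash
operant-iiv simulate --seed 1 --out events.csv
operant-iiv extract --events events.csv --out traits.csv
operant-iiv dispersion --traits traits.csv --out pd.csv --out-segment-dev segdev.csv
operant-iiv analyze --pd pd.csv --segdev segdev.csv --out report.csv --out-json report.json
```

The first command simulates the default design — 16 "SHR-like" rats (high
rate, bursty, high dispersion, positive within-session dispersion trend)
versus 15 "WKY-like" controls, five sessions — and prints
`wrote 77235 events for 31 rats to events.csv`. The final report
(`report.csv`) for that seed reads, per trait:

| trait | KW χ² | KW p | F | η² | mean log PD ± CI (SHR) | (WKY) |
|---|---|---|---|---|---|---|
| hyperactivity | 22.50 | 2.1e-06 | 448.1 | 0.94 | 3.29 ± 0.10 | 1.87 ± 0.10 |
| impulsiveness | 22.50 | 2.1e-06 | 279.4 | 0.91 | 2.18 ± 0.10 | 0.98 ± 0.11 |
| inattention   | 22.50 | 2.1e-06 | 636.9 | 0.96 | 2.67 ± 0.09 | 1.15 ± 0.09 |

i.e. the SHR-like group is far more dispersed on every trait (χ² = 22.5 is
complete rank separation of 16 vs 15 rats), with strain explaining >90% of
the between-rat variance in log dispersion here. The JSON report adds the
trend fits: for this seed the within-session slope of the inattention
dispersion is +1.43 counts/segment in the SHR-like group and −0.12 in the
controls — the generator's injected "behavior grows more erratic as the
session wears on" signature, recovered by the analysis.

The same pipeline is available in Python:

```python
from operant_iiv import default_config, simulate_experiment, analyze_events

design, params = default_config(seed=1)
events = simulate_experiment(design, params)
report = analyze_events(events)
print(report["comparison_table"])
```

Real data enter through `read_events` / the `extract` subcommand: a UTF-8
CSV (or TSV) with header `rat_id,strain,session,time_s,event_type`, times in
seconds from session start, event types in `{correct_lever, incorrect_lever,
correct_door, incorrect_door, reinforcer}`.

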