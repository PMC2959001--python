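# Methods

## The dispersion statistic

Behavior is summarized per segment: each 90-min session is split into
`n_segments` equal half-open intervals (default five 18-min segments;
`[start, end)`, so an event exactly on a boundary belongs to the later
segment). For a rat's per-segment counts `x_1..x_K` of one trait in one
session, the phenotypic dispersion is the mean absolute deviation from the
session mean, `PD = (1/K) Σ|x_k − mean(x)|`, with the plain `1/K` divisor
and no small-sample correction — the definition is an average of absolute
deviations, not a variance estimator. PD is computed on raw counts; because
segments have equal duration, counts and rates differ only by a constant
factor, which cancels in all rank-based and log-scale comparisons.

The within-session trend analysis needs one dispersion value per segment
rather than per session. We use the absolute deviation of each segment's
count from **its own session's mean**, averaged over sessions. This is the
only per-segment quantity consistent with the session-level statistic:
averaging it over segments recovers exactly the rat's mean PD over sessions
(verified numerically in the test suite). This interpretive choice is echoed
in every JSON report under `segment_deviation_definition`.

## Trait definitions

* **Impulsiveness**: correct-lever presses whose inter-response time (IRT)
  is defined and `< 0.67 s`. IRTs exist only between consecutive *correct*
  presses within a session: incorrect presses neither carry IRTs nor reset
  the clock; the first press of a session has no IRT, is never impulsive,
  and always counts toward hyperactivity. An IRT spanning a segment
  boundary is attributed to the segment of the later press (events belong
  where they occur).
* **Hyperactivity**: total lever presses (both levers by default;
  `hyperactivity_levers="correct"` restricts to the reinforced lever) minus
  the impulsive presses. The exclusion removes exactly the impulsiveness
  events, so the two trait counts always sum to total lever presses —
  asserted as an invariant on all simulated data — and their dispersion
  estimates are not mechanically confounded.
* **Inattention**: incorrect door openings. Correct door openings and
  reinforcer deliveries are parsed and validated but used by no statistic.

## Inference

* **Kruskal–Wallis** on PD with midranks and tie correction; with two
  groups, H is χ²(1). The analysis unit is one session-averaged PD value
  per rat (`kw_unit="rat"`), avoiding pseudo-replication from repeated
  sessions of the same animal; `kw_unit="rat-session"` is available for
  comparison. An all-identical sample returns H = 0, p = 1.
* **GLM on log PD**: `y = log(PD + 1)` averaged per rat over sessions, then
  a one-way fixed-effect model `y ~ strain`, F on (1, N−2) df. The offset
  is needed because PD can be exactly 0 (a session with identical segment
  counts); it is configurable (`--log-offset`) and echoed in all output.
  Group means are reported on the log scale with t-based 95% CIs from the
  pooled residual variance, and back-transformed (`exp(mean) − offset`),
  labelled as such.
* **Variance proportion** η² = SS_between/SS_total from the same one-way
  decomposition (equivalently F/(F + N − 2) for two groups). Zero total
  variance returns 0 with a warning.
* **Temporal models**: univariate repeated-measures ANOVA with rat as
  subject, between-subject factor strain and within-subject factor session
  (among-sessions model, on log PD) or segment (within-sessions model, on
  log per-segment deviations). No sphericity correction by default;
  Greenhouse–Geisser is available by flag. For sign reporting, per-strain
  linear slopes on the temporal index are fitted with rat-clustered
  standard errors: on the log scale for the among-sessions model (the
  scale of the fitted ANOVA) and on the raw count scale by default for the
  within-sessions model, where count-scale slopes are the conventional
  report. An exactly collinear fit (zero residual variance) reports SE = 0,
  flags the strain as degenerate and leaves the slope p undefined rather
  than claiming p = 0.
* P-values are two-sided; no multiple-testing correction is applied across
  the three traits.

## The synthetic generator

The generator emulates the *design* of a two-strain operant study — 16 vs
15 rats, five daily 90-min sessions of five 18-min segments, correct-lever
reinforcement on a variable-interval 180-s schedule — and injects the three
statistical structures the pipeline is meant to detect:

* a per-rat lognormal rate effect (`rat_rate_sd_log`) for stable
  between-animal differences;
* multiplicative lognormal segment noise `exp(N(0, σ_k²))` applied to all
  rates of a (session, segment), with `σ_k = segment_dispersion_sd_log +
  dispersion_trend_per_segment·k` floored at 0. The first term is the IIV
  knob; the second injects a within-session dispersion trend. The
  multiplier is deliberately not mean-centred: all trend claims made (and
  tested) are sign-level, and the simpler mechanism keeps the knob
  interpretable;
* burst responding: lever-press IRTs from a two-component exponential
  mixture — with probability `burst_prob` a short burst IRT (mean below the
  0.67-s threshold), otherwise a long IRT. The long component's mean is set
  so the mixture mean equals `60/rate`; when the target rate is too high
  for the long component's floor (`nonburst_irt_mean_s`), both component
  means are rescaled by a common factor, keeping the mixture mean exact and
  the burst component short. A 1-ms refractory floor on IRTs keeps
  successive presses distinct after timestamps are rounded to 4 decimals
  for file output.

Reinforcement follows a VI schedule: availability after an exponential wait
(mean `vi_mean_s`, clipped to [1 s, 3·mean] to avoid degenerate near-zero
intervals); the first correct press at/after availability emits a reinforcer
and one correct door opening after a lognormal latency (median 1.5 s,
σ_log 0.4) — plumbing that no statistic consumes. Incorrect-lever presses
are a fixed fraction of presses with no scheduled consequence; incorrect
door openings are a Poisson process scaled by the same segment multiplier.

Determinism: one experiment seed; each rat draws from an independent
substream keyed by (strain index, rat index), so identical seeds give
bit-identical event files and enlarging the cohort never perturbs existing
rats.

### Presets

The shipped defaults (`data/default_config.toml`) encode an "SHR-like"
group — base rate 4 presses/min, burst probability 0.35, incorrect-door
rate 1.5/min, segment dispersion SD 0.5 (log scale), trend +0.05/segment —
versus a "WKY-like" control (2.5/min, 0.15, 0.5/min, 0.2, −0.03). These are
realistic orders of magnitude for water-reinforced VI responding and give
the high-dispersion group the qualitative signature the analysis targets
(higher dispersion on all traits; within-session dispersion rising in one
group, flat-to-falling in the other). They are modelling choices, not
estimates fitted to any dataset, and no claim is made of reproducing any
particular study's printed statistics.

### What the generator does not model

Acquisition/learning dynamics across sessions (dispersion is stationary
across days by default), motivational drift within a session beyond the
dispersion trend, extinction-schedule microstructure on the wrong lever,
and any neurobiological mechanism. Passing tests therefore demonstrate
statistical correctness and sensitivity of the *pipeline* under a plausible
generative model — not claims about real strains.

## Validation experiments (test suite)

Problem sizes were chosen to give stable Monte-Carlo estimates at
interactive runtimes: 1000-input oracle checks for the dispersion formula;
10,000 two-group (16/15) null draws for rank-test calibration (rejection
rate within [0.03, 0.07] at α = 0.05); 500 fully simulated null experiments
for pipeline-level type-I error (each trait within [3%, 7%]); 200
replicates each for the doubled-dispersion recovery experiment (direction
≥ 95%, rank-test power ≥ 80% per trait) and the within-session trend
sign-recovery experiment (≥ 90%). The doubled-dispersion experiment uses
the bursty high-rate preset as its common base: with the low-rate control
preset, impulsive-response counts (~6/segment) leave the renewal-process
sampling floor dominating segment-to-segment variation, which would test
count sparsity rather than dispersion recovery. The trend experiment
injects +0.05/segment (the SHR-like preset's value) into one strain of a
control-preset pair; the zero-trend strain's slope is additionally checked
to be centred on zero. A true-zero slope has no well-defined sign, so
"sign recovery" is operationalized per replicate as: the trending strain's
slope is positive and exceeds the flat strain's.

## Numerical and degenerate-input policy

Event times are validated to `[0, session_duration)`; malformed rows are
rejected with the line number and field. Ties in time are broken by input
order (stable sorts throughout), which also fixes the press-before-
reinforcer order at shared timestamps. Missing segments raise errors naming
the rat and session rather than silently propagating NaNs. Dispersion of
fewer than two segments is undefined and rejected. All statistics are
invariant to row order and rat relabelling (tested).

## Known limitations

η² is reported from the per-rat one-way decomposition and, like the F test,
inherits the log(PD + 1) offset choice; very small PD values make both
offset-sensitive. The repeated-measures machinery is the univariate ANOVA —
no mixed-model REML, no Bayesian variants. The rank test's χ² approximation
is used at n = 31 (calibration verified by simulation at exactly this n).
With default presets the strain separation is large; users studying subtler
contrasts should run their own power simulations with
`simulate_experiment`.
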