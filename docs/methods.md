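# Methods

## Model

The package predicts top-down, task-driven visual attention allocation in
supervisory monitoring. The display is partitioned into `n` sections with
expert-elicited fuzzy importance degrees `V_i ∈ [0, 1)`; nothing else
enters the model. All entropies are in nats.

**Correct-evaluation probabilities.** The hybrid entropy
`S(P) = Σ −P_i ln P_i + Σ P_i h(V_i)`, with `h` the natural-log binary
entropy, is concave in `P` on the simplex; its unique maximizer is
`P_i = exp(h(V_i)) / Σ_j exp(h(V_j))`, implemented directly as this
closed form. The maximum `S_max = ln Σ_j exp(h(V_j))` is exposed as the
mental entropy. The test suite independently verifies the closed form by
constrained numerical maximization (SLSQP on the simplex, tolerance
1e-14, componentwise agreement within 1e-6 on 100 random profiles).

**Value priority and allocation.** The proposed cognitive evaluation is
`C_i = −P_i ln(1 − V_i)`; the fuzzy baseline it improves on uses
`C_i = P_i V_i`. Attention shares are `A_i = C_i / Σ_j C_j`. Note the
baseline's allocation formula is sometimes printed with `ln V_i` in the
denominator sum; that is a typographical error — the denominator is
`Σ P_i V_i` (with the four-section reference profile this sum is exactly
0.5, by the pairing of `V` with `1 − V` and the complement-invariance of
`P`), and only this form reproduces the published prediction table.

**Edge cases.** Profiles reject `V = 1` by default since
`−ln(1 − V)` diverges; a permissive mode (`allow_unit=True`) admits it
and `allocate` then assigns all attention to the unit-importance
sections, split equally — the model's limiting behavior as `V → 1`. An
all-zero profile has `Σ C = 0` under the proposed rule and raises rather
than silently falling back to uniform. Fractions are the internal
representation everywhere; percentages appear only in rendered tables.

**Anchored inversion.** Observed shares determine the per-section values
`g(V_i) = exp(h(V_i))·(−ln(1−V_i))` only up to a common factor, so the
inverse problem is a one-parameter family. One known `(index, V)` anchor
pins the scale; each remaining `V_i` then solves `g(V_i) = s·A_i`
uniquely because `g` is strictly increasing on `[0, 1)` (Brent's method
on `[0, 1−1e-15]`, xtol 1e-12). An anchor implying `g`-values beyond
that range is reported as infeasible.

## Continuum analysis

Letting the section count grow with `V` sweeping `[0, 1]` turns the
model into curves over `V`. The integral form of the evaluation
probability only yields finite printed values on a finite grid: on a
uniform `n`-point grid every `P` scales as `1/n`, while the 2:1 ratio of
the mid value to the endpoint values is grid-free
(`exp(h(0.5))/exp(h(0)) = 2`). The default is `n = 101` (step 0.01,
`V = 0.5` on-grid), which gives `P(0.5) = 0.012` and
`P(0) = P(1) = 0.006` at 3-decimal rounding; this holds for grids of
96–104 points and the docs treat the printed values as `n ≈ 100`
conventions, not grid-free limits.

At the `V = 1` endpoint `h(1) = 0` keeps `P` finite, but the proposed
evaluation and allocation diverge; they are stored as `inf` sentinels,
excluded from monotonicity scans, and rendered as `"inf"` in CSV
exports. The proposed allocation curve is therefore normalized over the
finite grid points.

The baseline's stationary point solves `d/dV [V·exp(h(V))] = 0`, reduced
analytically to `1 + V·ln((1−V)/V) = 0` (the `exp(h)` factor is
positive). The root is unique on `(0.5, 1)`: the factor is continuous,
equals 1 at `V = 0.5`, and tends to `−∞` as `V → 1`. Brent's method on
`(0.5, 1−1e-9)` with default xtol 1e-12 gives `V* = 0.7822` (4
decimals); a brute-force scan at 1e-6 resolution agrees within 1e-5.
Normalization does not move the stationary point, so the evaluation and
allocation curves share it.

## Experiment-side statistics

Two empirical attention estimates per participant, both normalized to
sum to one before any averaging:

* keypress: `A_k = O / Σ O` with `O_i` the correct-response ratio of
  AOI `i`'s overload events. A participant with a zero-overload AOI has
  an undefined ratio there and is excluded from the group mean rather
  than imputed (pooled-counts aggregation is available but non-default).
* fixation: `A_e = m / Σ m` with `m_i` the count of fixations inside
  AOI `i` (dwell-time weighting optional; counts are the default).
  Fixations outside every AOI are dropped from the normalization.

Group vectors are means of per-participant fractions. Averaging order
matters: the mean of normalized vectors is not the normalization of mean
ratios, which is why published group tables can disagree slightly with
naive renormalization of their own ratio rows.

AOIs are axis-aligned pixel rectangles, origin top-left, half-open on
the right and bottom edges, so boundary fixations belong to exactly one
AOI and overlapping AOIs are rejected.

Model-vs-behavior comparison uses Pearson r on group-mean vectors across
AOIs (two-tailed p from the t-transform with `df = n_AOI − 2`; with four
AOIs this df of 2 makes even r ≈ 0.94 non-significant) and one-sample
t-tests of per-participant fractions against a model's predicted
fraction (`df = n_participants − 1`, 95 % CI of the mean difference;
zero-variance samples are reported as undefined rather than infinite).
Both go through scipy.stats. The CI and p-value are mutually consistent:
the 95 % CI excludes zero iff p < 0.05, and a property test asserts it.

## Simulator

The generator emulates a four-section fan-monitoring task: per-AOI
Poisson overload events lasting one second, and a gaze process whose
stationary AOI shares equal the proposed model's allocation. Defaults
(the study conditions): 14 participants, 300-s sessions, overload rate
2/min per AOI, 1680×1050 screen tiled 2×2.

* **Gaze.** Attention-share data constrain only the stationary AOI
  shares, not the dynamics, so the default is the simplest process with
  the right shares: each fixation's AOI is drawn i.i.d. from `A`. A
  sticky variant (`stickiness` mixes in a self-transition weight) is
  available for scanpath realism; its stationary shares still equal `A`.
  Positions are uniform within the AOI rectangle.
* **Fixation timing.** Lognormal durations with mean 250 ms, sd 100 ms —
  conventional eye-movement values — plus an 80 ms saccade gap, giving
  about 3 fixations/s (~900 per 300-s session). These affect only
  realism and sampling noise, not any deterministic quantity.
* **Detection.** An overload is answered correctly iff some fixation in
  its AOI overlaps the 1-s window, minus a lapse probability
  (default 0.05) emulating misses while gazing. Misses produce no
  keypress row (`responded = correct` in the log); response latency is
  not modeled — the window-overlap rule is an explicit stand-in.
* **Scoring.** Each correct response earns that AOI's `V` in points,
  so attending high-importance sections more maximizes expected score at
  a fixed fixation budget; this is documented, not optimized for.
* **Determinism.** One seed sequence spawns per-participant generators,
  so identical configs give byte-identical CSVs and adding participants
  does not perturb earlier ones.

What the simulator does **not** emulate: bottom-up salience, fatigue or
vigilance decrement, saccade trajectories, calibration error, blinks, or
any fan-speed physics. Passing recovery tests therefore shows the
analysis pipeline is consistent with the model under ideal top-down
conditions — not that real supervisors behave this way; real validation
requires recorded gaze and keypress data.

Cohort-level checks run at 14 participants × 300 s (~12 000 fixations,
~600 overload events), where per-AOI binomial noise is comfortably under
the 3-percentage-point tolerance; single-run convergence checks use
~3000 fixations against a 4-sigma binomial envelope over 20 seeds.

## Known limitations

* The evaluation probabilities depend only on `h(V)`, so `V` and `1−V`
  are indistinguishable to the fuzziness channel; only the value channel
  separates them.
* The continuum `P` values are grid-size conventions (they scale as
  `1/n`); only ratios between them are model facts.
* Profile elicitation (how experts assign `V`) is out of scope, as are
  multi-factor extensions (salience, effort, fatigue, detection
  efficiency) that can multiply into the evaluation term.
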