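# Methods

This note documents the models, procedures, and numerical choices behind
the package: what is simulated, how movement measures are extracted, how
the statistics are computed, and what the synthetic data can and cannot
say about real recordings.

## Task model

The task is two coupled 1-D kinematic problems joined at a strike zone.
The target appears 213 cm from the strike-zone center and approaches it
at a piecewise-constant speed: 145 cm/s at baseline, switching at most
once per trial to 200 cm/s ("fast") or 90 cm/s ("slow") immediately after
movement onset (operationalized as the first 200-Hz sample after effector
speed exceeds 5 cm/s). The effector is driven along a 27.7-cm groove; its
center must meet the target center at the strike-zone center line.

Geometric quantities are closed-form:

- time window `= (w_t + w_e) / v`, with motion-axis widths 6 cm (target)
  and 4 cm (effector): 68.97 ms at 145 cm/s, 50 ms at 200 cm/s, 111.1 ms
  at 90 cm/s;
- the instructed movement time of 200–250 ms over 27.7 cm implies mean
  hand speeds between 110.8 and 138.5 cm/s (the upper value is the
  arithmetic consequence of the stated distance and MT floor; a commonly
  quoted 135 cm/s would correspond to a 27.0-cm path);
- constant error `CE = x_target_center(t_cross) − x_strike_center`,
  evaluated when the effector center first crosses the strike-zone center
  line. The sign convention is **positive = effector late** (target
  already past the center). The sources describing this paradigm annotate
  direction verbally rather than with a printed sign, so the convention
  is fixed here and used consistently; magnitudes are comparable either
  way. A hit is `|CE| ≤ 5` cm (boundary inclusive).

## Protocol

Stabilization is a run criterion on consecutive hits: one run of three
(SG, cap 200 attempts) or six non-overlapping runs of three (SSG, cap
320). Runs are counted with a reset — six straight hits credit exactly
two blocks — because overlapping windows would credit four blocks to six
hits, which contradicts the "blocks of three attempts" framing.
Participants exhausting the cap are excluded and reported, never silently
dropped.

The exposure phase is 129 trials: 111 controls and 18 perturbations
(9 fast, 9 slow, order randomized). Placement is uniform over all
position sets in trials 2–128 with at least `min_gap = 2` control trials
between consecutive perturbations, drawn constructively through the
gap-removal bijection (sample sorted positions in a compressed index
space, then re-expand), so generation is exact and needs no rejection
loop. First and last trials are controls; every perturbation therefore
has well-defined Pre and Post neighbors, which the block analysis
requires. MT feedback categories use half-open bins (<180, [180,200),
[200,250], (250,270], >270 ms) so every positive MT maps to exactly one
category despite the gaps in the printed integer anchors.

## Kinematic extraction

Position traces (200 Hz) are low-pass filtered with a zero-phase
2nd-order Butterworth (dual pass, effective 4th order); velocity and
acceleration come from central differences (one-sided at the ends).

**Cutoff.** The default cutoff is 14 Hz. The driving constraint is
amplitude preservation: a 200-ms minimum-jerk reach filtered at 10 Hz
loses 2.0% of its peak velocity, violating the <1% preservation the
measure chain is required to have; 14 Hz keeps the loss at 0.26–0.53%
across the instructed 200–250 ms MT range while still suppressing tablet
noise. The cutoff is exposed in `KinematicsConfig`.

**Movement bounds.** Onset is the last sample before the velocity peak
with `v < 0.05·PV` (backward scan); offset is the first sample after the
peak where velocity stays below that threshold for 50 ms. The hold
matters: corrective submovements are separated by brief velocity dips
that must not terminate the movement. The strike-zone crossing is located
on the *raw* position trace (linear interpolation between samples; the
zero-phase filter rounds the end-of-reach corner and would bias the
crossing ~9 ms early, i.e. ~1.3 cm of spurious CE). The crossing feeds CE
only; it does not truncate the analysis window, because speed-up
corrections follow through past the line and truncation would discard
their signature. MT, tPV% and the peak are refined to sub-sample
precision (linear threshold-crossing interpolation; parabolic peak fit) —
at 200 Hz one sample is ~2.5 percentage points of tPV%, larger than the
effects of interest.

**N-cor.** Corrective submovements are counted as qualifying valleys of
the acceleration trace between onset and offset: a local minimum
qualifies when its drop from the nearest preceding local acceleration
maximum reaches at least 2% of that maximum's magnitude (the alternative
reading — valley magnitude itself ≥ 2% of the peak — is selectable via
`depth_mode="abs"`). The terminal deceleration minimum that every reach
ends with is excluded, so a monophasic reach scores 0. A valley is
terminal when **no substantial re-acceleration peak follows it** in the
window (prominence ≥ 2% of the trace's maximum acceleration magnitude);
this formulation, rather than "the last minimum", is required because a
braking correction followed by a slow re-approach can end the detected
window before the re-approach's own terminal valley.

## Synthetic participants

The simulator generates the statistical structure the analysis assumes,
with full ground truth. It is a control model, not a biomechanical one.

**Planned reach.** A beta-family velocity profile
`v(τ) ∝ τ^a (1−τ)^b` with `a = 4p`, `b = 4(1−p)` — exactly minimum-jerk
for `p = 0.5` — gives each agent a planned relative time-to-peak-velocity
dial `p`. Launch time is set so the effector reaches the strike line at
the *base-velocity* target arrival (perturbations are unpredictable
before launch), plus Gaussian aim noise specified as a spatial SD and
converted through the base target speed (SD 0.5 cm ⇒ CE variance
0.25 cm²).

**tPV strategy.** A lower planned tPV% is implemented by *stretching* the
reach: the profile's duration grows by `p_base/p` so the velocity peak
keeps its absolute time while the deceleration tail lengthens. This is
the motor-control meaning of an early peak — time bought for
feedback-based corrections — and it is what makes late slow-perturbation
corrections kinematically possible for the early-peaking group. The shift
applies on perturbed trials, as a statistical stand-in for an
anticipatory strategy; the simulator makes no claim about how a
participant could condition a pre-programmed profile on an unpredictable
event, and no trial-to-trial learning is modeled.

**Corrections.** On a perturbed trial, a Bernoulli draw (per-agent
correction probability) decides whether the agent corrects; corrections
start one latency (default 150 ms) after the perturbation and re-plan the
remaining reach as minimum-jerk (quintic) segments that match position,
velocity and acceleration at the correction time, removing a fraction
(gain, default 0.8) of the predicted timing error, repeated while the
predicted |CE| exceeds half the bandwidth up to `max_corrections`
(default 2):

- *speed-up* (fast target): a 40-ms drive release (acceleration dips
  0.3·scale below its current value — the burst follows a partial
  let-off) and then a boost segment that crosses the line at the
  re-planned time at roughly the mean remaining speed, with an 80-ms
  follow-through to rest past the line;
- *delay* (slow target): braking over 40% of the remaining distance to a
  stop, then a fresh rest-to-rest approach timed to the re-planned
  crossing. The approach must be a discrete submovement (peak velocity
  ≥ 20 cm/s, duration ≥ 60 ms); its peak-velocity floor caps the
  achievable delay, so slow-perturbation errors are only partially
  corrected — a long hang cannot be produced by an undetectably slow
  creep. When no such submovement fits (movement nearly over), the agent
  cannot correct, and no correction is injected: ground truth counts only
  discrete corrective events, which is also exactly what the
  acceleration-valley rule can see.

A superimposed pulse with negative net displacement cannot delay the
crossing without leaving the effector short of the line altogether, which
is why corrections re-plan instead of superimposing. The classic
superimposed-pulse composite is retained as a separate generator
(`composite_trajectory`) used as the ground-truth harness for
detector-recovery tests; its pulse amplitudes (6–9 cm) and durations
(110–140 ms) are drawn so that each pulse's initial jerk exceeds the main
reach's steepest deceleration slope — a pulse that cannot bend the
acceleration trace leaves no valley to find, by construction rather than
by detector failure.

**Population defaults.** Correction probability SG 0.3 / SSG 0.8 (jitter
SD 0.08), latency N(150, 20) ms clipped to [80, 300], gain N(0.8, 0.05),
planned MT U(200, 250) ms, tPV% 50 baseline with a −10 perturbed-trial
shift for SSG, aim noise N(3.0, 0.8) cm clipped to [0.5, 8] (≈20 ms of
timing SD at the base speed, a typical interceptive-timing variability,
and enough to make learning-phase hit runs non-trivial), positional
(tablet) noise SD 0.05 cm. These are calibration choices that reproduce
the qualitative group structure — more corrections and earlier peaks in
the superstabilization group, error pulled late by fast and early by slow
perturbations — and are explicitly **not** estimates of any real
participant group.

**What the simulator does not emulate.** No trial-to-trial adaptation or
learning dynamics; no muscle or limb dynamics (accelerations during
forced late corrections can exceed what a limb would produce); no
reaction-time modeling of the foreperiod; measured CE carries a small
early bias (≈1 cm at the default noise) from noise-driven first passage
of the strike line near zero velocity, affecting all blocks and groups
alike. Passing tests therefore certify the measurement and analysis
chain and the qualitative group fingerprint, not quantitative agreement
with any particular human dataset.

## Statistics

Per-trial measures are organized per perturbation kind into three moments
(perturbation ordinals 1–3, 4–6, 7–9) × three blocks: Pre (the controls
immediately preceding those perturbations), P, and Post (immediately
following); every cell is the mean of exactly three trials, and cells
with missing flanking controls are flagged incomplete and excluded from
inference.

The mixed-design ANOVA (group between, block within) uses the classical
balanced sum-of-squares partition — identical to Type-III in a balanced
design — with **no sphericity correction**, giving the uncorrected
(1, N−2) and (2, 2(N−2)) degrees of freedom; N = 40 yields (1, 38) and
(2, 76). The implementation is verified to 1e-9 against an independent
mixed-ANOVA implementation (pingouin) and against a hand-computable 2×3
toy table, and its group-effect Type-I rate over 2000 null replicates is
0.0535 at α = 0.05. A constant dependent variable yields zero sums of
squares and is reported as F = 0, p = 1 with a degenerate flag rather
than crashing.

Effect size is partial eta squared with the conventional bands
(trivial < 0.01 ≤ small < 0.06 ≤ medium ≤ 0.14 < large). Tukey HSD uses
the studentized-range distribution over the ANOVA's within-subject error
term; interaction cell means are decomposed when the interaction is
significant at 0.05, marginal block means otherwise (the pooled error
term is used in both cases; a per-simple-effect error term is a
documented alternative, not implemented). N-cor is compared between
groups by independent-samples pooled-variance t tests per perturbation
kind (and per moment), with the t = 0 / p = 1 convention when both groups
are constant and equal. The Shapiro–Wilk screen reports per-cell p values
and a proceed flag at α = 0.05; it never switches the analysis to a
nonparametric alternative. On synthetic data the tPV% cells are often
non-normal (a mixture of corrected and uncorrected trials), which the
screen duly reports.

No multiplicity adjustment is applied across the six kind × moment
ANOVAs; all p values are reported raw at α = 0.05.

## Problem sizes and determinism

Every random stage descends from a single integer seed through
`numpy.random.SeedSequence` spawning (one child stream per participant),
so identical configurations produce byte-identical artifacts. The
package's own verification runs use: 250 trials for detector ground-truth
recovery (0–3 injected submovements, noise-free and at 0.05-cm noise),
100 replicate studies of 20 participants per group for the group
fingerprint, and 2000 null replicates for Type-I control — about six
minutes single-core in total.
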