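# Methods

## The cascade model

The package models the occupancy of three firing-rate modes (beta, sigma,
delta) in a closed, fixed-size generating population of brainstem
activating neurons. Within a *towards* (sleep-deepening) phase the
population cascades beta → sigma → delta; within an *away* phase the
cascade reverses. Each individual transition is treated as instantaneous
relative to the episode, so mode occupancies obey linear serial-decay
(Bateman-type) kinetics with rates equal to the transition probabilities
per unit time. Time is measured in percent of the NREM episode duration
everywhere in the core; conversion to seconds or minutes happens only at
I/O. The four rates default to P = [0.13, 0.131, 0.2, 0.6] per 1 % of
episode duration and are shared by all phases, episodes and subjects.

The closed-form solution is generalized to arbitrary phase-start values,
because each phase starts from the end values of the previous one. Two
numerical points matter:

- The towards rates 0.13 and 0.131 sit next to the singular denominator
  p₂ − p₁ of the two-exponential term. The difference of exponentials is
  therefore always evaluated as −e^(−p₁t)·expm1(−(p₂−p₁)t), which is
  accurate for any rate separation, and the analytic equal-rate limit
  N₂(t) = (N₂(0) + N₁(0)p₁t)e^(−pt) is used only when
  |p₂ − p₁| < 10⁻⁹ p₁.
- The interior sigma maximum is found in closed form
  (ln(p₂/p₁)/(p₂−p₁)) when the middle mode starts empty, and by root
  finding on the inflow–outflow balance p₁N₁(t) = p₂N₂(t) otherwise.
  When the initial outflow already exceeds the inflow the middle mode
  declines from the start and no interior maximum is reported.

The Monte Carlo variant thins an integer population with per-step
Bernoulli transitions (probability p·dt per neuron per step, default
dt = 0.01 time units). It conserves counts exactly and its survival
probability is (1 − p·dt)^(t/dt) rather than e^(−pt); at the default dt
the discrepancy is below one percent and the tests budget for it
explicitly. A continuous-time event scheme was deliberately not used:
at the stated dt, discrete thinning is indistinguishable from it at the
resolution of any downstream analysis.

## Fitting an episode

The episode is normalized to 100 % duration and each band averaged into
fifty 2 % bins; missing bins (artefacts) stay missing and are excluded
from every residual sum. Delta is fitted first: the delta series is
normalized to its maximum, the switchover plan is initialized by
peak/trough detection on the three-point-smoothed delta curve, and the
switchover times are refined by coordinate search on the bin grid
(one time moves at a time, up to three bins per move, times kept strictly
increasing and at least one bin apart to prevent phase collapse), with
the vertical scale at its closed-form least-squares optimum for every
candidate plan. With the plan frozen, the sigma and beta scales are then
fitted in closed form; beta after subtracting a constant background
component (default 2 µV², configurable per subject). The probability
vector is fixed by default; freeing it wraps a Nelder–Mead search over
log-rates around the same machinery, and on synthetic cohorts it does not
materially improve the fit — consistent with treating P as a constant.

Fit quality is the coefficient of determination R² (%) per band, which
may be negative for fits worse than the mean. The three bands are
combined on the Fisher-z scale: each R² is converted to r = √(R²/100),
z = atanh(r) averaged, and the mean back-transformed and squared. The
same transform underlies the cohort mean R². This choice (z of r, not of
R² expressed as a fraction) is the standard Fisher transform and is the
variant that reproduces the package's reference-cohort Mean row at
printed precision; the two variants are numerically close for single
combinations but diverge in cohort averages. Overall R² is classified
VG (≥ 60 %), G (40–60 %), F (19–40 %); values below 19 — never observed
in the reference cohort — are labelled BF (below fair).

A runs test on the signs of the delta residuals is reported (not
enforced) as a randomness check. On data with realistic spectral noise
the fit may insert short spurious cycles beyond the generating ones:
peak/trough initialization has no model-selection penalty, and extra
switchovers can only increase R². The pipeline tests therefore require
every generating switchover to be recovered within ±2 bins rather than
an exact cycle count; on directly generated (binned) power curves with
10 % multiplicative noise, the full plan is recovered within ±2 bins in
≥ 90 % of replicates.

## Spectral preprocessing

Raw single-channel EEG (256 Hz default) is analysed in consecutive 4-s
epochs by Hanning-windowed periodogram (0.25 Hz resolution), summing the
one-sided density over the band edges: delta 1–4 Hz, sigma 12–15 Hz,
beta 18–25 Hz. The beta lower edge is subject-dependent in practice and
exposed as a parameter; 18 Hz is the default. Artefacts are flagged at
1-s resolution when the RMS amplitude exceeds 4× a centered 3-min rolling
median RMS; the original routine's constants are unpublished, so these
are documented stand-ins. Flagged seconds make the containing 4-s epoch
missing, preserving time continuity.

NREM episodes are delimited on the 20-s hypnogram: sleep onset is the
first stage-2 epoch; REM bouts separated by less than 15 min without REM
form one REM episode (no minimum REM duration); each NREM episode runs
from the epoch after the previous REM episode's last REM epoch to the
epoch before the next REM episode. Sleep latency is lights-off to first
stage 2; the efficiency index is total sleep over the onset-to-last-sleep
period.

## Flip-flop alignment

The threshold analysis is generic: a binned activity trace is compared
against a threshold curve; crossing instants are linearly interpolated
between bin centers at each sign change and alternate in direction by
construction. State transitions of the paired slow-wave-activity trace
are its smoothed peaks (away-start) and troughs (towards-start); extrema
with prominence below 10 % of the trace range are treated as noise.
Matching is greedy nearest-first with a one-to-one constraint — the
minimal formalization of visual alignment; the tie-break between two
transitions equidistant from one crossing is by order of ascending time
difference. Because both event series are quantized to bins, each carries
about half-a-bin timing precision, and alignment is scored at a one-bin
tolerance. The binning artefact is reproduced as a demonstrable property:
a sharp sub-bin peak straddling a bin edge is attenuated to roughly half
its amplitude on both sides and can fail to produce a crossing that the
unbinned signal produces.

## Cohort statistics

The one-way within-subject ANOVA uses explicit sums of squares,
F = MS_episode / MS_(subject × episode), with the Huynh–Feldt epsilon
computed from the double-centered within-subject covariance matrix and
applied to the p value only (never to F). Trends across the four episodes
use the orthogonal polynomial contrasts (−3,−1,1,3), (1,−1,−1,1),
(−1,3,−3,1); each contrast's per-subject scores are analysed as a
one-sample problem, giving F(1, n−1) against its own error term, and the
three contrast sums of squares decompose the episode effect exactly, so
their percentage shares sum to 100. Fit-quality inference is run on the
Fisher-z scale (z of r), which is the scale on which the package's
reference statistics are exact; TA-cycle counts are analysed untransformed.
An independent implementation (pingouin) cross-checks F and epsilon in
the test suite.

The packaged reference cohort (30 subjects × 4 NREM episodes of overall
R² and TA counts, fitted with the common probability set) ships as a CSV
fixture. One published percentage in its quality breakdown (the
second-episode "fairly good" cell) recomputes to 6.7 (2/30) rather than
the printed 6.6; the recomputed value is reported and the discrepancy is
treated as a rounding slip in the source, not forced.

## Synthetic data

The generators are pure functions of (parameters, seed) and emulate the
statistical structure the analysis assumes, not real EEG. Noise on band
power is multiplicative lognormal (power is positive with roughly
scale-proportional variability; no noise model is prescribed by the
method itself, so this is a documented stand-in), with optional random
missing bins (default 2 %). Cohorts draw TA counts as shifted Poisson
variates centered on (5.2, 6.7, 6.8, 7.1) for episodes 1–4 and truncated
at 1, and draw switchover plans by stick-breaking over [0, 100] with a
two-bin minimum phase length — the largest floor compatible with the
observed TA range (a four-bin floor is arithmetically infeasible beyond
six cycles). Per-subject vertical scales vary lognormally around
delta 120, sigma 12, beta 5 µV² with a 2 µV² beta background.

Paired SCN/SWA traces alternate the SCN between two levels at a known
schedule with Gaussian noise, while SWA ramps up when the SCN is below
threshold and down when above (clipped), so its turning points fall
exactly on the switch times; a steeper, saturating ramp reproduces the
negative bin-wise SCN–SWA correlation. Synthetic EEG sums band-limited
Gaussian carriers whose amplitude envelopes are the square roots of the
model's band-power curves, framed by low-amplitude wake and REM sections
with a matching hypnogram. Per-4-s-epoch periodogram estimates carry few
degrees of freedom, so envelope-recovery checks operate on the 2 % bins
the pipeline consumes.

What passing these tests shows: the pipeline is internally consistent
and recovers known generating structure under its own noise assumptions.
What it does not show: performance on real recordings, whose artefacts,
arousals and non-stationarities the generators deliberately do not model.

## Problem sizes and determinism

Default study sizes were chosen to make every stochastic check stable
across seeds: 100 replicates for noisy switchover recovery, 10 seeds for
alignment rates, 10,000 neurons for the Monte Carlo cross-check, 30 × 4
synthetic cohorts. All randomness flows through explicit integer seeds;
rerunning any generator, fit or pipeline with the same inputs and seed
reproduces its output bit for bit.

## Known limitations

- Switchover times are estimated on the 2 % bin grid; sub-bin refinement
  is not attempted, matching the data resolution.
- No penalty discourages spurious short cycles on noisy data (see above).
- The threshold estimator (midpoint of the 10th/90th percentile
  envelopes) is a labelled heuristic; supplied thresholds are preferred.
- The artefact filter's background window (3 min) and threshold (k = 4)
  are package choices, not published constants.
- EDF ingestion is not built in; raw EEG enters as single-column text
  (or any array via the `EEGRecord` API).
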