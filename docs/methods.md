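# Methods

## Setting and conventions

The analysis operates on one recording session: a behavioral trajectory
sampled at 30 frames/s on an annular track (square 30 cm maze or circular
35 cm maze, concentric 20 cm cylinder, track ≈ 5 cm wide) and an aligned
cells × frames matrix of non-negative deconvolved activity in arbitrary
units. Positions are converted to polar coordinates about the maze center.
Angles are radians in [0, 2π), anticlockwise positive; frames are 0-based
and frame ranges half-open; the track is divided into 24 angular bins,
half-open, bin 0 starting at the reward site (at the track midline each
bin covers roughly 3 cm). A lap is a maximal span between successive
anticlockwise reward-site crossings; laps with clockwise regression beyond
π/12 are discarded, and reward-consumption frame ranges (supplied in the
session config) are unassigned. A behavioral bout is the window from π/4
before to π/4 after an object within one lap, labeled exploration or
non-exploration externally (blinded annotation in an experiment; ground
truth in simulation); unlabeled passes are treated as excluded.

## Statistics

**Spatial information.** SI = Σᵢ pᵢ (rᵢ/r̄) log₂(rᵢ/r̄) bits over occupied
bins, with occupancy pooled across laps (occupancy-weighted frame pooling
rather than averaging per-lap rates; the two differ only when occupancy is
uneven across laps). Bins with zero rate contribute the x·log x → 0 limit,
as does a ratio that underflows. The null circularly shifts the
concatenated in-lap activity trace by an offset uniform on [0.05 T,
0.95 T] frames — preserving the trace's autocorrelation while decoupling
it from position — and the observed SI is z-scored against 100 such
shuffles (normal approximation on the null mean/SD). Place cell ⇔ z ≥
1.65. Because the SI null is right-skewed (approximately a quadratic form
with ~23 degrees of freedom), the realized false-positive rate of this
z-rule on untuned cells is ≈ 6% rather than the nominal 5%; this is a
property of the z-score convention, not of the implementation, and is
measured by the calibration test.

**oePC test.** Per cell × object with at least three exploration and three
non-exploration bouts, the per-bout maximum of bin-averaged activity over
the bout's bins is computed; the difference of means is compared with 1000
label shuffles preserving group sizes. The pass rule is: the fraction of
null differences *strictly below* the observed must reach 0.99 ("exceeds
99.0% of the chance"). Ties count against the cell, so a degenerate null
fails automatically, and the rule has a resolution floor at small designs:
with all bout maxima separated, 3v3 (20 arrangements) and 4v4 (70) cannot
reach the criterion and 5v5 is the smallest passing design — exhaustive
enumeration over label arrangements is used as the oracle for this in the
tests. A cell qualifying at several objects is assigned the object with
the highest percentile. The oePC label further requires SI z ≥ 1.65
computed over that object's exploration laps and a session-maximum
activity ≥ 2 arb. units. The Difference Index uses the maxima of the
exploration and non-exploration lap-average vectors over the three
object-centered bins.

**Exclusion controls.** Off-track frames: per bin, mean ± 2 SD (sample SD)
of radial distance over pooled non-exploration bout frames; exploration
frames outside their bin's band are flagged. Head-direction outliers use
the same rule with the circular mean and circular SD √(−2 ln R), making it
invariant to the 0/2π wrap. Bins with fewer than two non-exploration
frames give indeterminate (not off-track) flags. After exclusion, a
two-sided Mann-Whitney U test on frame-level activity must keep p ≤ 0.05
for the cell to be retained. Under an i.i.d. Gaussian radial null the
flagging rate is the two-tailed 2 SD mass, ≈ 4.55%; when the radial noise
is strongly autocorrelated the per-bin SD estimates become noisy and the
realized rate rises (Jensen's inequality on the band width), which the
synthetic sessions exhibit by design of their smooth radial noise.

**Reward-associated cells.** RA ⇔ the maximum of the tuning curve over the
three reward-centered bins exceeds the mean + 2 SD (sample SD) of the full
24-bin vector. The "activity in the bins proximal to the reward" is read
as the peak over that window: a 3-bin mean would fail the natural
single-peaked example, while the peak rule preserves locality (a remote
peak inflates the SD and cannot qualify). RA cells that are also oePCs are
excluded from RA analyses.

**Speed-drop periods.** Sub-threshold-speed runs inside laps, detected
with hysteresis (enter < 2 cm/s, exit > 4 cm/s, ≥ 3 frames) to avoid
chatter, are classified exploration / reward / other by location; the
remaining in-lap frames are the baseline, so the four sets partition the
in-lap frames. Speed-activity coupling is the Pearson correlation within a
period, tested against 100 within-window circular shifts; negative
coupling is significant below the 5th percentile of the null.

**Decoding.** Bouts are labeled ±1; features at a bin are the oePC
activities (or mean radial distance) averaged over the bout's frames in
that bin, optionally after off-track exclusion (bouts whose bin empties
are dropped). A linear-kernel SVM (C = 1; features standardized on each
training fold so no cell dominates by scale) is scored by leave-one-out
accuracy (1/k) Σ I(yᵢ = ŷᵢ); a fold left with one training class predicts
that class. Significance: observed accuracy strictly above the 95th
percentile of 100 accuracies under label permutations that preserve class
counts. Profiles span the bout window, bins −3 … +2 relative to the
object (the window's half-open end leaves no frames at +3).

## Synthetic sessions

The generator produces the statistical structure the analysis assumes,
not raw imaging. Kinematics: anticlockwise laps at 12 cm/s along the
track midline with small angular jitter; on exploration passes the speed
ramps down multiplicatively (floor 0.25 across a ±π/8 window) and the
animal dwells ~1 s at the object; each lap ends with a 0.5 s hesitation at
the reward port (in-lap) and a 1.5 s consumption pause (excluded);
occasional pauses elsewhere provide "other" speed-drop events. Radial
position is the track midline plus smoothed Gaussian noise (SD 0.4 cm);
half of exploration bouts (configurable) add an outward radial bump of 3
noise-SD at the object, emulating off-track excursions toward the object.
Head direction is the velocity heading plus noise, overridden toward the
object during excursions. Exploration labels are Bernoulli(p_explore =
0.4) per pass, drawn before kinematics so label statistics are exact.

Activity is sparse events: per frame a Poisson count with lognormal
amplitudes (mean 4 arb. units, CV 0.5), with the expected trace value
equal to the cell's rate curve — Gaussian angular tuning (SD 0.35 rad)
peaking at 6 arb. units over a 0.1 arb. unit background. Classical place
cells and reward-tuned cells fire every lap; oePCs carry the same tuning
centered 3.04 cm (track arc) before their object — at the simulated
approach speed this reproduces the observed ≈ 0.78 s activation lead —
and are gated to exploration bouts of that object; untuned cells emit
background only. All randomness flows from the two config seeds; identical
configs give bit-identical sessions.

What the generator does *not* emulate: fluorescence dynamics and
deconvolution artifacts, within-field firing variability beyond Poisson
events, theta-scale temporal structure, behavioral idiosyncrasies
(variable running speed across laps, partial passes), or cross-day cell
identity. Passing recovery tests therefore demonstrates that the
statistical machinery detects the planted structure at realistic effect
sizes, not that it is robust to every failure mode of real data.

## Numerical choices and degenerate inputs

- Bin intervals half-open; a boundary angle belongs to the bin it
  lower-bounds. A frame exactly at the maze center propagates the previous
  angle with a warning.
- The tuning-curve center of mass is the angular coordinate of the
  shoelace centroid of the polar polygon (vertices at radius = bin
  activity, angle = bin center, ordered by angle); fewer than three
  positive vertices or near-zero area fall back to the activity-weighted
  circular mean with a warning. An independent geometric library serves as
  the test oracle.
- Place fields are maximal circularly contiguous runs of bins strictly
  above 20% of the cell maximum; fields may wrap; no merging or splitting
  beyond that rule.
- Zero-variance inputs return missing values rather than raising: SI with
  zero mean rate, z with zero null SD, Pearson r on constant series, DI
  with both windows silent.
- Speed is frame displacement × frame rate, boxcar-smoothed over 5 frames.

## Problem sizes

Defaults were chosen so a full session analyzes in seconds on one CPU: 20
laps (~6–7 thousand frames), 3 objects, 100 cells (30 cPC / 10 oePC /
10 RA / 50 untuned), 100 SI shuffles, 1000 bout shuffles, 100 decoding
permutations. Calibration tests use 1000–2000 replicates, giving binomial
standard errors of ~0.2–0.7 percentage points on the 1% and 5% levels
they check.

## Known limitations

- The z-score convention for SI significance is anti-conservative by
  ~1 percentage point (see above); a rank-based rule would be exactly
  calibrated but would depart from the stated procedure.
- The 99% bout-shuffle criterion is unreachable below 5v5 bouts when the
  null support is small; sessions near the 3-bout eligibility floor can
  only fail.
- Off-track flagging assumes the non-exploration radial sample per bin is
  large enough to estimate the band; strongly autocorrelated radial noise
  inflates the realized flag rate above the nominal 4.55%.
- Decoding with few bouts has a coarse accuracy grid (multiples of 1/k),
  so permutation thresholds are conservative at small k.
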