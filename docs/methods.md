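# Methods

`pointkin` analyzes 3D index-finger trajectories from a referential
pointing task in which a communicator points at one of three signs for an
addressee seated to their left or right, either communicatively
("mind-oriented") or instrumentally ("object-oriented").  The package
implements the full analysis chain — preprocessing, phase segmentation,
kinematic parameters, trajectory profiles, variability ellipses, trial
exclusion, and within-subject inference — together with a synthetic
generator that emulates the 2 (action) × 2 (addressee) × 3 (sign) design
so every stage can be validated against known ground truth.

Coordinates: x lateral (positive rightward from the communicator), y depth
(toward the screen), z altitude; origin at the home-key; SI units
internally, with parameters reported in the field's customary units (ms,
cm, cm/s, mm).

## Preprocessing

Positions are low-pass filtered at 15 Hz with a sixth-order Butterworth
filter, applied forward and backward (zero phase) by default so that phase
boundaries are not displaced by filter lag; the effective amplitude
response is then the squared single-pass magnitude (gain 1/2 at the
corner).  The single-pass variant is available through
`FilterConfig(zero_phase=False)`.  Edges are handled by reflection padding
of 3 × order samples.  Velocities are central differences on the filtered
positions (one-sided at the ends); segmentation uses the speed component
in the sagittal (yz) plane, parameter extraction the full 3D speed.

## Phase segmentation

A trial decomposes into reaction (stimulus to home-key release), forward
transport, hold, and backward transport.  Transport phases are intervals
where the sagittal speed exceeds 0.1 m/s; "remained above" is
operationalized as a 50 ms debounce so sensor noise cannot spawn
micro-phases.  The hold is the longest sub-threshold interval that (a)
lies strictly between the forward and backward transports — the
post-return rest at the home-key is not a candidate — and (b) sits in
proximity of the signs.  Spatial gates (all inclusive): movements must
start no more than 10 cm above / 8 cm in front of the home-key and end no
more than 10 cm above, 15 cm below, or 15 cm lateral of the sign row; the
backward movement must return to within the same home gate.  Violations
set per-trial reason codes consumed by the exclusion stage; they never
raise.

Threshold crossings are refined to sub-sample precision by a local
quadratic fit of the speed within an 80 ms half-window around the
provisional crossing, re-centered once.  This matters: a first-sample
detector carries a uniform one-sample quantization error plus, at 1 mm
sensor noise, ~1.5 samples of crossing jitter; the refined estimator
recovers noise-free ground-truth bounds to < 0.5 samples and keeps ~98% of
1 mm-noise trials within 2 samples.  The literal first-sample rule remains
available (`refine_crossings=False`).

Note that threshold-detected transport durations are inherently shorter
than the underlying kinematic segment (the sub-threshold acceleration and
deceleration tails, ~7.5% of a minimum-jerk reach at each end, fall
outside the detected phase), so condition effects injected on kinematic
transport durations are recovered attenuated by roughly 0.77.  Holding
time is the complementary case: the detected hold includes those tails,
which is why the generator injects HT on the detected scale (below).

## Kinematic parameters and profiles

Per trial: RTc (stimulus to home-key release), MTf, HT, MTb (from the
detected bounds), MTa (addressee release to selection, from the event
channel), TL (summed Euclidean segment lengths of the forward phase, cm),
PV (maximum 3D speed in the forward phase, cm/s), rtPV (time of PV as a
percentage of MTf), and the end-point EPx/EPy/EPz — the position at
forward offset (a hold-average variant is config-selectable) expressed in
mm relative to a configurable reporting origin chosen so the three signs
land near 18 / 63 / 110 mm laterally.

The forward phase is resampled at 100 time-equidistant samples with a
cubic spline through the phase samples; signed per-axis instantaneous
velocities come from the spline's analytic derivative.  Lateral
(x-axis) displacement and velocity profiles are averaged per subject and
condition cell, and mind-minus-object difference profiles are formed per
sign or per addressee for the time-resolved inference.

## Trajectory variability

The spatially averaged trajectory is defined by a fixed point: initialize
as the pointwise mean of the time-normalized trajectories, then
iteratively (i) resample the mean at 300 points equidistant in arclength,
(ii) intersect every trajectory with the plane perpendicular to the mean's
tangent at each point (linear interpolation at sign changes of the plane
distance; with several crossings, the one whose sample fraction is nearest
the section's arclength fraction, config-exposed alternative: first), and
(iii) replace each point by its section centroid, until the largest
pointwise move is below 0.1 mm or 20 iterations (non-convergence returns
the best iterate, flagged).  Each section's 2D basis is the global x-axis
projected into the plane (y-axis fallback), so orientations are comparable
along the trajectory.  Per section, the 95% confidence ellipse comes from
the eigen-decomposition of the 2D covariance with semi-axes
`sqrt(lambda_i * q)`, `q` the chi-square(2 df) 95% quantile; the area
series (cm²) is the variability profile.  Fewer than 3 crossings yields a
flagged degenerate section.

## Trial exclusion

Sequential rules, each trial attributed to the first rule that removes
it: (1) the first two trials of the first block; (2) trials either player
answered incorrectly; (3) RTc > 8 s; (4) per-subject interquartile screen —
a trial is an outlier if any screened parameter (default RTc, MTf, HT,
MTb, TL, PV) falls more than 3 IQRs outside that subject's first or third
quartile (linear-interpolation quartile convention, recorded in the
report); (5) no valid detected movement (segmentation reason codes).  The
IQR screen is within-subject, matching the repeated-measures design.  The
report carries per-rule counts/percentages and per-condition retention,
and is exactly recomputable from the retained ids.

## Statistical inference

Cell means (12 per subject and parameter) enter a balanced fully
within-subject factorial ANOVA computed by the marginal-means (Möbius)
sums-of-squares decomposition; every effect is tested against its own
effect-by-subject interaction with uncorrected degrees of freedom (df1 ∈
{1, 2}, df2 = 12·df1 at n = 13); Greenhouse–Geisser adjustment of the
p-value is available behind a flag.  Partial eta-squared is
SS_eff/(SS_eff + SS_err), equivalently F·df1/(F·df1 + df2).  A one-sample
Kolmogorov–Smirnov screen against a normal with the sample moments is
reported per parameter (no gating).

Time-resolved profiles violate pointwise independence, so condition
contrasts use cluster-based permutation statistics: pointwise paired t
(or one-way repeated-measures F for multi-level contrasts) at each of the
100 samples, thresholded at the parametric critical value at alpha = 0.05
(two-sided with signed clusters for t); cluster mass is the summed
statistic over each contiguous supra-threshold run; the null distribution
is the maximum cluster mass under within-subject relabelings (sign flips
for t, within-subject level permutations for F) — the max-statistic
correction for multiple comparisons.  Labelings are fully enumerated when
2^n does not exceed the requested permutation count (p = count/2^n,
identity included), otherwise Monte-Carlo sampled with the
(b + 1)/(m + 1) estimate.  Default 10,000 permutations; the test-suite
calibration study uses 1,000 to keep its 500-simulation type-I-error check
tractable.

Design power uses the within-factors repeated-measures convention:
f² = η²p/(1 − η²p), noncentrality λ = f²·n·m/(1 − ρ) with repeated-measures
correlation ρ = 0.5 by default, df1 = m − 1, df2 = (n − 1)·df1, power =
noncentral-F upper tail beyond the central critical value.  Under these
conventions η²p = 0.2 at n = 13 gives power 0.911 and η²p = 0.43 at
n = 10 gives 0.998.

## Synthetic experiments

Each trial is a stationary reaction segment, a minimum-jerk reach
(p(τ) = start + (end − start)(10τ³ − 15τ⁴ + 6τ⁵), peak speed
1.875·d/T at mid-movement), a stationary hold, a minimum-jerk return, and
a 0.3 s tail, sampled at 250 Hz, with additive Gaussian sensor noise
(default 0.3 mm per axis) and quantization to the 0.1 mm tracker
resolution.  Minimum-jerk was chosen because its analytic velocity profile
provides closed-form oracles (rtPV = 50%, analytic threshold crossings);
condition effects ride on smooth quintic-smoothstep bias fields so the
kinematics stay differentiable and end with zero velocity.

Defaults are the study conditions: 13 subjects × 240 trials in 24 blocks
of ten; addressee side alternating every block, action condition every two
blocks (starting sides counterbalanced across subjects); signs balanced
20/20/20 within each action × addressee group.  Duration effects (ms):
RTc 1945 (+98 mind), MTf 870, MTb 704 (+45 mind), HT 227 for object trials
(+185 mind, +48 more at the middle sign — so the middle-sign pair means
460 vs 227 and the action main effect is 201).  Spatial effects: 2.4 mm
outward end-point shift at the outer signs (mind), a 2 mm early lateral
shift rising between 10% and 22% of movement (mind), and an
addressee-directed displacement ramping in over the final quarter
(0.25 mm on all trials + 0.6 mm on mind trials), whose derivative is the
late addressee-directed lateral-velocity effect.  Error flags are
injected at 1.9% (communicator), 2.7% (addressee), 3.0% (both).

Reaction and holding times are log-normal (positive, right-skewed),
parameterized by mean and sd so injected means are exact; transport times
truncated normal.  Between-subject offsets (drawn once per subject) have
sds 350/110/60/100 ms for RTc/MTf/HT/MTb; trial sds 380/60/80/50 ms; the
end-point varies by 2.5 mm per axis per trial.  Where the source design
gives no distributional information these are this package's assumptions,
visible and overridable in `EffectSpec`.

Holding time is special: the *detected* hold necessarily contains the
transports' sub-threshold tails, giving it a physical floor of
~140 ms under these kinematics.  The generator therefore treats the
injected HT as the detected hold and draws it from a shifted log-normal
above the per-trial floor, keeping its mean exactly at the injected value
(subject HT offsets are bounded below at −55 ms for the same reason).
Ground truth stores both the kinematic segment boundaries (as event marks)
and the analytic threshold-crossing bounds an ideal detector would report,
which is what the segmentation oracle compares against.

What the generator does not emulate: corrective submovements, movement
curvature beyond the injected lateral fields, drift or dropouts in the
tracker, biomechanical sign asymmetries (the real data's backward-time and
trajectory-length sign effects), or any addressee behavior beyond drawn
response times.  Passing tests therefore demonstrate correctness of the
pipeline's operations and calibration of its inference, not validity of
any scientific claim about real pointing data.

## Numerical choices and problem sizes

Tolerances: mean-trajectory convergence 0.1 mm / 20 iterations; hold
candidates need ≥ 12 ms below threshold; crossing refinement 80 ms
half-window, quadratic, two passes; ANOVA sums of squares below 1e-12 of
the total are treated as exact zeros.  Ties in hold selection go to the
earliest interval; gate comparisons are inclusive.  Text intermediates are
written at full precision (`%.17g`) and read with round-trip parsing so
re-running any stage from disk reproduces downstream outputs exactly.

The test suite exercises the pipeline at sizes chosen to keep a full run
in a few minutes on one core: 500-trial segmentation oracles, a
500-simulation × 1,000-permutation calibration of the cluster test, and a
20-experiment (13 subjects × 240 trials each) parameter-recovery study;
the acceptance script runs one full default experiment end to end.

## Known limitations

- The ANOVA requires a complete balanced subject × cell table; designs
  with empty cells raise rather than impute.
- The mean-trajectory fixed point is not guaranteed unique for strongly
  self-intersecting bundles; the nearest-fraction crossing rule handles
  mild multi-crossing cases only.
- Power follows one convention for repeated-measures effect-size
  inflation; calculators differ, so values should be compared only under
  matching conventions (m enters through λ = f²·n·m/(1 − ρ)).
- Detected transport durations are threshold-trimmed; comparisons with
  kinematic ground truth must use the stored threshold-crossing bounds.
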