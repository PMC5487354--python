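# pointkin

Kinematic analysis of referential pointing movements.

When people point at something *for* someone, the movement itself changes:
the finger lingers near the target, end-points shift toward the addressee,
and the whole trajectory bends from early in the reach.  `pointkin` is a
tested, reusable pipeline for quantifying such effects in 3D motion-tracker
recordings of a communicator pointing at one of three signs for an
addressee seated to the left or right, under communicative
("mind-oriented") versus instrumental ("object-oriented") task demands —
a 2 × 2 × 3 within-subject design.

It is written for motor-control and social-cognition researchers who have
per-trial 250 Hz index-finger position streams plus event marks, and for
methodologists who want a fully synthetic, ground-truthed replica of this
experiment class to validate analysis choices.

## What it computes

- **Preprocessing** — 15 Hz sixth-order zero-phase Butterworth filtering;
  central-difference velocities; sagittal (yz) speed.
- **Phase segmentation** — reaction, forward, hold, and backward phases
  from a 0.1 m/s sagittal-speed threshold with debouncing, sub-sample
  crossing refinement, and spatial gates around the home-key and signs
  (10 / 8 / 10 / 15 / 15 cm); invalid movements are flagged with reason
  codes.
- **Kinematic parameters** — RTc, MTf, HT, MTb, MTa, trajectory length TL,
  peak velocity PV, relative time-to-peak-velocity rtPV, and end-points
  EPx/EPy/EPz; 100-sample spline-interpolated trajectory profiles with
  signed per-axis velocities.
- **Trajectory variability** — iterative spatial averaging at 300
  equidistant-arclength samples, perpendicular-plane cross-sections of the
  trajectory bundle, and 95% confidence-ellipse areas
  (semi-axes √(λᵢ·q), q the χ²(2 df) 95% quantile).
- **Trial exclusion** — first-trials, error, reaction-time (> 8 s),
  within-subject 3-IQR outlier, and invalid-movement rules applied
  sequentially, with a recomputable retention report.
- **Inference** — balanced within-subject factorial ANOVA with partial
  eta-squared (η²p = SS_eff/(SS_eff + SS_err) = F·df1/(F·df1 + df2)),
  Kolmogorov–Smirnov normality screening, cluster-based permutation tests
  on time-resolved profiles (max-cluster-mass null over within-subject
  relabelings), and noncentral-F power for the repeated-measures design.
- **Synthetic experiments** — minimum-jerk forward–hold–backward trials
  with injectable condition effects (holding-time prolongation, end-point
  shifts, early and late lateral trajectory effects), sensor noise, and
  full ground truth for every trial.

## Worked example

```python
from pointkin import (DesignSpec, synthesize_experiment, rm_anova)
from pointkin.pipeline import analyze_experiment

exp = synthesize_experiment(DesignSpec(n_subjects=13), seed=1)
retained, report, profiles_x, profiles_vx = analyze_experiment(exp)
print(f"retained {report.retention_pct:.1f}% of {report.n_total} trials")

means = retained.groupby(["subject", "action"])["ht_ms"].mean().unstack()
print(f"holding time mind {means['mind'].mean():.0f} ms, "
      f"object {means['object'].mean():.0f} ms")

table = means.reset_index().melt("subject", var_name="action", value_name="ht_ms")
res = rm_anova(table, dv="ht_ms", within=("action",))
row = res["action"]
print(f"F(1,{row['df1']*12:.0f}) action effect: F={row['F']:.1f}, "
      f"p={row['p']:.2g}, eta_p2={row['eta_p2']:.3f}")
```

prints

```
retained 91.4% of 3120 trials
holding time mind 425 ms, object 224 ms
F(1,12) action effect: F=10777.1, p=4.3e-19, eta_p2=0.999
```

i.e. the pipeline recovers the injected ~201 ms communicative prolongation
of the holding time from the noisy synthetic recordings (the enormous F
reflects the generator's modest between-subject variability in this
contrast, not a claim about real data).

The same stages run from the shell as a configured pipeline:

```bash
pointkin run-all --seed 1 --out run1            # simulate ... permtest
pointkin simulate --config my.yaml --seed 2 --out run2
```

Each stage persists plain-text intermediates (trial tables, phase tables,
parameter tables, 100-sample profile matrices, JSON reports) under the run
directory, and any stage can be re-run from them exactly.

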