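# mealmodel

Mechanistic simulation of intermittent gastric emptying and postprandial
glucose–insulin dynamics after a milk-based meal, with

- a five-state delay model: stomach/plasma acetaminophen (the gastric-emptying
  marker), stomach hexose, plasma glucose and plasma insulin, driven by a
  piecewise-constant outflow schedule (codes 0/1/2 = none/slow/fast);
- fixed-step 4th-order Runge–Kutta integration (0.002-min step) with two fixed
  transport lags handled by history replay (`mealmodel.simulator`);
- marker-based gastric-emptying estimation: slope classification of the
  outflow schedule, closed-form piecewise solution of the marker subsystem,
  and bound-constrained least-squares fitting scored by rMSPE
  (`mealmodel.gastric_fit`);
- differential-evolution estimation of the eight free glucose–insulin
  parameters under basal steady-state constraints (`mealmodel.gi_fit`);
- 0.5×–1.5× AUC sensitivity analysis (`mealmodel.sensitivity`);
- a built-in reference animal, meal-to-dose arithmetic and seeded synthetic
  observation generation (`mealmodel.synthetic_data`).

Units are fixed package-wide: minutes, mg (acetaminophen), mmol (glucose),
μg (insulin), L, kg; plasma concentrations use fixed volumes of distribution
(0.9 L/kg for the marker, 0.251 L/kg for glucose/insulin).

## Command line

```sh
mealmodel simulate -o traj.csv                      # reference animal, 420 min
mealmodel simulate --set K_Gl_PIn=4.4 --steady-state -o traj.csv
mealmodel synth --meal 2L --bw 60 --noise-cv 0.05 --seed 7 -o obs/
mealmodel fit-ac --ac obs/ac.csv -o acfit.json
mealmodel fit-gi --glucose obs/glucose.csv --insulin obs/insulin.csv \
    --ac-fit acfit.json --seed 1 -o gifit.json
mealmodel sensitivity --auc-mode total -o table.csv
```

Timecourses are two-column CSV (`time_min,value`); a single negative-time
pre-meal baseline row is remapped to t = 0. Parameter files are flat YAML
(one key per model symbol); unknown keys are rejected with the list of valid
symbols. Every run logs version, seed, step size and the resolved parameter
set.

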