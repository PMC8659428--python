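# comtrack

Validation toolkit for pelvis-tracker approximations of whole-body centre
of mass (COM) during balance tasks.

## The problem

Clinical balance assessment increasingly uses consumer VR hardware: a
single 6-DOF tracker strapped to the pelvis is a cheap, portable stand-in
for the whole-body COM that a full optical motion-capture system would
measure. Before such a proxy can be trusted — for instrumented balance
batteries, falls-risk screening, or biofeedback — its trajectory must be
validated against the optically derived COM. `comtrack` implements that
validation end to end for researchers in movement biomechanics:

* **COM estimation from segment kinematics.** Each body segment carries a
  rigid cluster of ≥3 markers. Per frame, the segment pose `(R, t)` solves
  the orthogonal Procrustes problem
  `min Σᵢ ‖R·localᵢ + t − observedᵢ‖², det R = +1` (closed-form
  SVD/Kabsch solution), and the whole-body COM is the anthropometric
  composition `COM = Σₛ mₛ (Rₛ cₛ + tₛ)` with mass fractions `mₛ` summing
  to 1.
* **Registration and preprocessing.** The tracker stream is mapped from
  the game-engine frame to the lab frame (signed axis permutation, X
  forward / Y left / Z up), temporally aligned on a shared event onto a
  common 100 Hz grid, Savitzky–Golay smoothed (41-sample window ≈ 0.4 s,
  order 3) and mean-centred per axis.
* **Agreement metrics.** Per trial and axis, `RMS = √(mean (a−b)²)` in cm;
  for standing tasks, the displacement range `max − min` per horizontal
  axis for each method.
* **Agreement statistics.** Classical repeated-measures ANOVA for the
  method effect (subject-blocked, F on (1, n−1) df) and a Bayes factor
  BF₁₀ under a Jeffreys–Zellner–Siow Cauchy prior on the standardised
  effect (default scale 0.5), with Lee–Wagenmakers evidence labels;
  BF₁₀ < 1 is evidence for method equivalence.
* **A synthetic study generator** with full ground truth: 13 participants
  × 12 balance tasks at 100 Hz, physiological sway (2–4 sinusoids in
  0.1–1 Hz plus band-limited noise), minimum-jerk transitions, a circular
  360°-turn path, and a configurable tracker error model (lever-arm
  offset, per-axis sway gain, white noise, sleep-mode dropout) plus the
  emulated missing-data pattern (21 COM-missing + 8 tracker-missing trials
  over 10 participants).

## Worked example

```python
import comtrack as ct

spec = ct.default_task_specs()[1]          # standing unsupported, 120 s
rec = ct.generate_task_trial(spec, ct.SensorErrorModel.default(), seed=3)
row, disp = ct.analyze_trial(rec)
print(row.rms)       # per-axis RMS error in cm
```

Running the narrative scripts in `examples/` prints, e.g.:

```
$ python examples/03_trial_agreement.py
RMS error  X (AP): 0.070 cm   Y (ML): 0.064 cm   Z: 0.046 cm
range [com    ]  X: 2.55 cm   Y: 2.41 cm
range [tracker]  X: 2.83 cm   Y: 2.91 cm
```

The sub-millimetre RMS reflects waveform disagreement only (the 15% sway
magnification and 2 mm sensor noise of the default error model): DC
removal cancels the constant 8 cm lever-arm between pelvis fixture and
COM. The tracker's displacement ranges exceed the COM's by the injected
gain — exactly the magnification the statistics stage then detects:

```
$ python examples/04_method_agreement_stats.py
pooled RMS over analysed trials: 0.23 +/- 0.29 cm
X: F(1,12) = 1591.9, p = 3.97e-14, BF10 = 6.5e+10 (extreme evidence for H1)
Y: F(1,12) = 562.5, p = 1.89e-11, BF10 = 2.32e+08 (extreme evidence for H1)
```

With `SensorErrorModel.identity()` the same pipeline returns RMS ≈ 0 and
BF₁₀ < 1 (evidence for equivalence).

A thin CLI wraps the same stages:

```bash
comtrack simulate --seed 42 --duration-scale 0.1 --out study/
comtrack process --manifest study/manifest.csv --out results/
comtrack report --study study/manifest.csv --out results/plots/
```

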