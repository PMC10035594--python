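# emgh — hierarchical sEMG gesture and grasp-force classification

`emgh` implements a pattern-recognition control pipeline for multi-DoF
myoelectric prostheses: from six channels of **enveloped surface EMG**
(rectified, low-pass-filtered amplitudes, sampled at 1 kHz) it classifies
which of seven hand/wrist gestures the user intends — *rest, spherical,
platform, point, tip, supination, pronation* — and, when the gesture is one
of the two grasps (*spherical*, *tip*), simultaneously classifies the
intended grip-force level (*low, medium, high*). The package is aimed at
researchers in myoelectric control who want a tested, fully reproducible
reference implementation of this hierarchical strategy, including a
synthetic signal generator so the whole pipeline runs without subject
recordings.

## The method

**Features.** The signal is cut into 150 ms analysis windows with 50 ms
overlap (100 ms hop). Per window and channel five time-domain descriptors
are computed — enhanced mean absolute value (EMAV), enhanced wavelength
(EWL), slope-sign-change count (SSC), root mean square (RMS) and variance
(VAR) — giving x ∈ ℝ³⁰. EMAV and EWL use a position-dependent exponent
p(i) ∈ {0.5, 0.75} that emphasises the centre of the window:

    EMAV = (1/N) Σᵢ |xᵢ|^p(i)        EWL = Σᵢ₌₂ |xᵢ − xᵢ₋₁|^p(i)

**Classifiers.** Three one-vs-all algorithms are provided. Logistic
regression (LR) models the class-membership probability

    P(c | x) = 1 / (1 + e^{−(θᵀx̃ + θ₀)}),

trained per class by full-batch gradient descent on L2-regularised
cross-entropy; the non-linear variant (NLR) first expands x to all degree-2
monomials (30 → 495 terms). Per-class decision thresholds are chosen on a
held-out carve-out of the training part as the grid value maximising that
class's F1 score. Linear discriminant analysis (LDA) uses the closed-form
pooled-covariance discriminants and predicts by ĉ = argmax_c (β_cᵀx + β₀c).

**Hierarchy.** The gesture classifier runs on every window; if and only if
it outputs *spherical* or *tip*, the matching three-level force classifier
runs on the same feature vector. Predictions map to prosthesis commands:
grasps close the hand at a PWM duty cycle of 25/50/75 % for low/medium/high
(≈ 7.5/15/30 N grip force), the other active gestures drive the hand or
wrist at 50 % PWM, and rest issues no command. Per-grasp force levels are
calibrated from dynamometer traces: the mean plateau force of three 3-s
repetitions per perceived level, with ±10 % acceptance bands.

**Evaluation.** Offline: 70/30 stratified split, accuracy, per-class F1 and
confusion matrices; Mann–Whitney U tests with Bonferroni correction compare
conditions. Real time (simulated): 5-s streams per motion class, a new
decision from the most recent window every 90 ms, reporting per-class
online accuracy and the motion completion rate (MCR — a trial counts as
completed once the target class has been predicted for a cumulative 1 s).

## Worked example

```python
from emgh import HierarchicalEmgModel, SubjectProfile

model = HierarchicalEmgModel.from_synthetic_session(
    SubjectProfile(seed=7), algorithm="lr", feature_extraction=True
)
results = model.fit(seed=7)
print(results.summary())
report = results.simulate_realtime()
print(f"online accuracy {report.mean_online_accuracy():.1f}% | "
      f"MCR {report.mean_mcr():.1f}%")
```

Output:

```
Hierarchical sEMG classifier | algorithm=lr | features=on | seed=7
------------------------------------------------------------------------
classifier          accuracy  macro F1   per-class F1
gesture               1.0000    1.0000   1:1.000 2:1.000 3:1.000 4:1.000 5:1.000 6:1.000 7:1.000
spherical_force       1.0000    1.0000   1:1.000 2:1.000 3:1.000
tip_force             0.9762    0.9762   1:0.966 2:0.963 3:1.000
online accuracy 98.5% | MCR 100.0%
```

The first table is offline test-split performance of the three classifiers
(gesture codes 1–7 as above; force codes 1–3 = low/medium/high): the
synthetic subject's gestures are classified perfectly and the hardest task,
separating adjacent tip-grasp force levels, still reaches F1 ≈ 0.96. The
last line is the simulated online protocol (3 × 5-s trials for each of the
11 motion classes): 98.5 % of the ~54 decisions per trial match the target,
and every attempted motion is completed.

The same pipeline is scriptable from the shell:

```bash
emgh generate --seed 7 --out session/
emgh train    --seed 7 --data session/ --algorithm lr --out models/
emgh evaluate --seed 7 --data session/ --models models/ --out report/
emgh stream   --seed 7 --models models/ --out realtime/
emgh calibrate --seed 7 --out calibration/
```

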