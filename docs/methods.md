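# Methods

This note documents the models and procedures implemented in `emgh`, the
assumptions behind the synthetic data generator, and the numerical and
design choices that were genuinely open.

## Signal model and acquisition protocol

The unit of data is a **recording**: an `(n_samples × 6)` matrix of
nonnegative envelope amplitudes at 1 kHz, labeled with one of seven
gestures (codes 1–7: rest, spherical, platform, point, tip, supination,
pronation) and, for the two grasps, a force level (1–3: low, medium,
high). A training session holds each gesture for 3 s, six repetitions,
with the grasps repeated at all three perceived force levels — 66
recordings in total.

For classifier training, the central 800 samples of each repetition are
retained (the steady-state plateau; the 200 ms onset/offset ramps and the
surrounding transients are discarded) and stacked into the **DataSet
matrix**. With six repetitions per class this gives 4,800 samples per
class and 33,600 × 6 overall. The per-repetition keep length is a
parameter (`per_rep_keep`); 800 is the default because it reproduces those
protocol counts exactly. Since the grasps are recorded at 3 levels × 6
repetitions, the gesture DataSet takes two repetitions per level for each
grasp — every class then contributes six recordings and grasp training
still spans all force intensities. The force classifiers train on all 18
recordings of their grasp (14,400 rows each, labeled by level).

Splits are stratified per class: `round(0.7 · n_class)` rows to training
(ties toward training), seeded and deterministic.

## Synthetic generator

The generator emulates an *enveloped* sensor output, not raw EMG. Each
channel of a hold is

    x_c(t) = a[g, c] · gain(level) · r · η_c(t) · ramp(t),  clipped at 0

where `a` is a 7 × 6 activation template (each gesture dominated by 2–3
channels over a 0.8 floor; rest sits at 0.3 everywhere), `gain` is the
force-level multiplier (0.6 / 1.0 / 1.6 for low/medium/high), `r` is a
per-repetition amplitude factor (1 + jitter · z, jitter 0.05), and `η` is
multiplicative log-normal noise with unit mean and CV `noise_cv` (default
0.15), smoothed by a 50 ms moving average so it has the low-pass character
of an envelope. Ramps are linear over 200 ms at onset and offset.
Real-time streams use the same model without ramps (a hold already in
progress). Dynamometer traces use one noise channel around a plateau of
`force_newtons[grasp] · gain(level)` (18 N medium spherical, 9 N medium
tip — a power grasp is roughly twice as strong as a pinch).

Defaults were chosen once as plausible values for clean commercial
envelope sensors on distinguishable gestures: amplitude CV around 15 %,
rep-to-rep drift around 5 %, force levels separated by ~60 % steps. They
define well-separated classes — which is the point: the generator
validates the *pipeline* (shapes, routing, counting, learning dynamics),
not the difficulty of real amputee EMG. What passing tests show is that
the implementation is correct on data satisfying its assumptions; they say
nothing about electrode shift, fatigue, co-contraction variability or
limb-position effects, none of which are modelled. Every stream of
randomness is keyed on `(seed, kind, gesture, level, repetition)`, so any
subset of the protocol is reproducible independently of generation order.

## Features

Windows of 150 ms with 50 ms overlap; "overlap" is read as the span shared
by consecutive windows, so the hop is 100 ms and a 4,800-sample class block
yields 47 windows. Trailing partial windows are discarded.

Per channel: EMAV, EWL, SSC, RMS, VAR, in feature-major column order
(emav_ch1…emav_ch6, ewl_ch1…, …, var_ch6). The EMAV/EWL positional
exponent uses 1-based indices with p(i) = 0.75 strictly inside
(0.2 N, 0.8 N) and 0.5 otherwise; the strict-inequality convention is
fixed by the package's worked examples. SSC counts interior samples whose
neighbouring slopes change sign: product > dead_zone, with dead_zone = 0
meaning a strict sign change (constant runs never count). VAR is the
sample variance (mean-subtracted, N−1); RMS is not mean-subtracted. Both
conventions are deliberate and switchable at the call sites.

Z-score normalization is fitted on training data only (inside the
classifier's fit partition); zero-variance columns keep sd = 1 so
degenerate noise-free fixtures stay finite.

## Classifiers

**LR/NLR.** One binary logistic model per class (one-vs-all), trained by
full-batch gradient descent on L2-regularised mean cross-entropy (bias
unpenalised, zero initialisation, deterministic). Steps that would
increase the loss trigger step-halving (up to 40 times), making the loss
trajectory non-increasing; training stops at `max_iter` or when the
relative loss change drops below `tol`. Defaults: learning rate 0.1 on
z-scored inputs, max_iter 5000, tol 1e−7, l2 1e−4. NLR expands features to
all degree-2 monomials in the fixed order [linear | cross-products i<j |
squares]; degree 1 is plain LR by construction. Probabilities are
one-vs-all scores and are never renormalised across classes.

Decision thresholds are selected per class on a stratified 20 % carve-out
of the training part (the test split is never touched), over the grid
{0.05, …, 0.95} step 0.05, maximising that class's one-vs-rest F1; ties
break toward 0.5, then toward the lower threshold. At prediction time the
most probable class among those reaching their threshold wins; if none
does, the globally most probable class is used; exact ties go to the
lowest class code.

**LDA.** Closed-form: β_c = Σ⁻¹μ_c, β₀c = −½μ_cᵀΣ⁻¹μ_c + log π_c with the
pooled within-class covariance Σ and empirical priors. Σ is regularised by
max(1e−6 · trace(Σ)/d, 1e−12) on the diagonal; the absolute floor keeps
the noise-free degenerate case solvable, where LDA reduces to the
nearest-class-mean rule.

Models serialise to JSON (full precision, version-tagged envelope with a
`family` field distinguishing logistic from LDA).

## Hierarchy, calibration and commands

The gesture classifier gates the force classifiers: they run only when the
gesture output is spherical or tip, on the same window's feature vector
("simultaneously" is implemented as same-window sequential evaluation —
no concurrency is needed for correctness). Force classifiers are trained
exclusively on windows from their own grasp class, across all three
levels.

Force calibration takes the mean plateau force (central 80 % of each
trace, robust to ramps) over three repetitions per perceived level; bands
are ±10 % around the low and medium thresholds and [0.9·H, f_max] for
high. Non-monotone level means raise a calibration error; overlapping
low/medium bands warn. An alternative rule placing thresholds at 30/60/90 %
of maximum voluntary force is provided (`method1_thresholds`) but the
perceived-force method is the default, being the more repeatable protocol.
The bands label calibration data; they are not consulted at inference
time.

Command mapping: grasps → hand close at PWM 25/50/75 % (nominal
7.5/15/30 N); platform/point → hand at 50 %; supination/pronation → wrist
at 50 %; rest → the null command (`None`).

## Real-time simulation and metrics

A trial feeds a 5-s labeled stream to the cascade: at every 90 ms stride
tick the most recent 150 ms window is classified, starting when one full
window is available — 54 decisions per 5-s trial. Online accuracy counts
every tick from the first full window (no transient exclusion) and, for
grasp targets, requires both gesture and force level to match. A trial is
*completed* once the target has been predicted for a cumulative 1.0 s
(≥ 12 ticks at defaults); MCR is the completed fraction of attempted
trials. The cumulative-time completion rule is this package's
operationalisation of motion-completion testing; a consecutive-time
variant would be stricter and can be obtained by filtering the prediction
sequence. The full protocol is 3 trials × 11 motion classes = 33 streams.

The Mann–Whitney U test (two-sided; sidedness is a choice, two-sided being
the conservative default) uses exact enumeration when both samples have
≤ 8 observations and no ties, and the tie-corrected normal approximation
otherwise; the Bonferroni gate compares each p-value to α/m (0.05/3 ≈
0.0167 for the three-algorithm comparison).

## Problem sizes in the shipped tests

The default acceptance-scale run uses the full protocol (33,600-row
DataSet, 329 feature windows for the gesture classifier, 141 per force
classifier). Raw-mode (no feature extraction) comparisons and several
end-to-end unit tests use a reduced session (3 repetitions, 1.2-s holds,
400 samples kept per repetition), which preserves every structural
property while keeping gradient descent on tens of thousands of raw rows
out of the hot path.

## Known limitations

- The generator's stationarity and multiplicative-noise assumptions make
  classes more separable than real amputee sEMG; absolute performance
  numbers on synthetic data are upper bounds, not predictions.
- Only degree-2 polynomial expansion is implemented for NLR; higher
  degrees would need a different expansion strategy to stay tractable.
- The raw-signal (no-FE) hierarchical mode classifies window-mean
  amplitudes; per-sample streaming decisions without windows are not
  modelled.
- Channel count is fixed at six per arm; bilateral fusion is out of scope.
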