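# Methods

This note documents the models, numerical choices and limitations behind
`mrmprep`. It complements the README, which describes the overall flow.

## Problem setting and assumptions

A batch consists of *S* samples × *M* target metabolites. For every
(metabolite, sample) cell the instrument has recorded one quantifier and
up to two qualifier chromatograms — intensity versus retention time (RT,
minutes) for a fixed precursor→product transition. The method assumes:

* each chromatogram contains **zero or one** correct peak for its target,
  possibly accompanied by incorrect peaks of similar RT and even higher
  intensity (isobaric interferences, in-source fragments);
* retention times drift between runs approximately as a **quadratic
  function of RT**, as is typical for HILIC columns over an injection
  sequence, while individual metabolites may deviate from that trend by up
  to ~0.5 min;
* qualifier traces co-elute exactly with the quantifier when the signal is
  the target analyte, and do not when it is an interference — this is the
  main lever for telling correct from incorrect peaks;
* intensities are non-negative counts on an arbitrary scale: **no score
  may depend on the absolute scale**, only on ratios, correlations and
  times.

## Candidate detection and borders

Candidates are strict local maxima of a moving-average-smoothed quantifier
trace (window `smoothing_width`, default 5 points, shrinking at the
edges) inside `expected_rt ± initial_shift_window`, ranked by smoothed
apex height with ties broken by earlier RT; the top `n_candidates`
(default 5) are kept.

Borders are found by walking outward from the apex on the smoothed trace
until the first local minimum (the trace rises again — the shared valley
of merged peaks) or the first point below
`floor + border_frac · (apex − floor)`, where `floor` is the minimum of
the smoothed trace. Measuring the threshold above the floor makes it
robust to a constant background offset. `border_frac` defaults to 0.01:
with the linear between-border baseline used for integration, a border
threshold at 1% of apex loses ≈2.7% of a Gaussian's analytic area (0.2%
tail truncation plus the baseline rectangle), whereas a 5% threshold would
lose ≈11% — incompatible with the ±5–10% area-accuracy targets this
package sets for itself.

Integration is the trapezoidal integral of the signal above the straight
line joining the border intensities, clamped at zero; height is the
maximum excess over that line. This handles sloping, non-flat backgrounds
without modelling them.

## Quality scores

Twenty scores per candidate, all in [0, 1] with 1 ideal, in three
families (relative height / quantifier-qualifier agreement / shape & RT).
Raw ratios r are squashed by s = max(0, 1 − 1/r), which maps "twice as
high as the reference point" to 0.5 and grows saturatingly — chosen so
all scores are commensurable, because the no-model fallback classifier is
their plain mean. Correlation scores are max(0, Pearson r), zero for
degenerate windows (< 3 points or zero variance). Qualifier-dependent
scores are 0 when no qualifier trace exists. The Gaussian-shape score
fits A·exp(−(t−μ)²/2σ²) by Levenberg–Marquardt on the peak window
normalized to unit amplitude (so the fit path is scale-invariant) with
moment-based initial values, and reports the correlation between data and
fit. RT scores are 1 − |Δ|/drt_window clamped at 0, with
`drt_window = 0.5` min reflecting how far HILIC metabolites plausibly
stray from the batch trend.

The implementer-defined scores beyond the named eight are: expected-ratio
agreement min(r_obs/r_exp, r_exp/r_obs); width plausibility against a
[0.02, 0.6] min range (1 inside, proportional decay outside); apex height
over a noise floor estimated as the robust SD of successive differences
of the out-of-peak trace (trend-insensitive), squashed with a 3× margin;
left/right area symmetry; fraction of non-zero points in the window;
qualifier presence; and qualifier-trace analogues of the border-ratio,
Gaussian, symmetry, non-zero and noise scores. Each is frozen in
`quality.QS_NAMES` order and unit-tested; all satisfy the
scale-invariance property.

## RT alignment

Shifts are **sample RT − reference RT** (positive = sample elutes later);
aligning subtracts the shift. The reference is the sample with the highest
mean picking score over all metabolites (missing = 0, ties to batch
order).

Pass 1 measures each metabolite's shift by maximizing, over lags within
±`initial_shift_window` (0.5 min), the sum across available roles of the
Pearson correlation between the sample trace and the lag-shifted reference
trace, on a uniform grid at the reference's median sampling interval
(lag resolution = one grid step, ties prefer the smaller lag). A quadratic
shift-vs-RT model is then fit by ordinary least squares (exact at 3
points; constant median below 3; zero model with a warning at 0). Pass 2
repeats the measurement with the lag search centred on the fitted value
and halfwidth `refined_shift_window` (0.17 min ≈ 10 s), then refits.

The **refined per-metabolite raw shift** — not the fitted curve — aligns
the traces for prototype summation and carries prototype borders back
into each sample, with the quadratic prediction as fallback where no
shift could be measured. The narrow second pass exists precisely to
recover the individual deviations from the batch trend that the quadratic
model regularizes away; summing by the fitted curve alone leaves residual
per-metabolite jitter that smears the prototype and truncates its
borders. The quadratic model is the regularizer and safety net, not the
final coordinate map. An optional one-pass MAD-based reweighting
(`robust_fit`) is available for batches with gross outlier shifts,
default off.

The prototype grid is uniform at the first contributing sample's median
sampling interval over `expected_rt ± (initial_shift_window + 0.3)` min;
traces are linearly interpolated (zero outside their support) and summed
per role. Peak picking, scoring and border detection on the prototype use
the same code path as single samples.

## Classifiers

Both tasks are binary classification: picking uses the 20 QS; reporting
uses 26 features (QS + picking score `output_H` + its 0/25/50/75/100th
batch percentiles, linearly interpolated). Training always uses a
stratified 80/20 split (seeded), a small fixed hyperparameter grid scored
by 3-fold CV F1 on the training split — random forest: 200/500 trees ×
depth ∞/10; gradient-boosted trees: depth 3/6; RBF-SVM: C 0.1/1/10 with
internal Platt calibration so scores live on [0, 1]; one-hidden-layer
MLP: 8/32 units — and a single F1 evaluation on the held-out 20%, stored
with the model. Random forest is the default for its accuracy/training
speed balance on this feature set. Models persist as joblib artifacts
with their feature schema; loading validates the format tag.

Labels: a picking candidate is correct iff the expert solution gives a
positive area and the candidate apex lies between the solution's start
and end; reporting labels map review value 2→1, 0→0 and drop value 1.
The reporting gate passes peaks with score ≥ `report_threshold`
(default 0.5, configurable — the gate is a thresholded probability so
users can trade sensitivity against specificity).

## Synthetic batches

The generator emulates a DMRM-style HILIC batch, one acquisition segment
of ±1 min around each metabolite's expected RT at a 0.005 min (0.3 s)
cycle time. Defaults: 12 samples × 10 metabolites; expected RTs uniform
over 1–8 min; per-sample drift a_s·RT² with a_s ramping linearly over the
injection sequence from 0 to `drift_a` = 0.005 min⁻¹ (a column drifting
as the batch progresses; the first injection is drift-free); per-cell
normal RT jitter (SD 0.05 min, truncated at ±0.5 min); Gaussian peaks
with σ ∈ [0.03, 0.06] min and amplitudes log-uniform in [2·10³, 10⁵]
counts over a 50-count baseline with additive N(0, 20²) noise clipped at
zero; qualifier1 at 0.5× the quantifier; a ¹³C internal-standard
qualifier of constant amplitude spiked into every sample; peaks missing
with probability 0.1; an interfering decoy Gaussian 0.3–0.8 min away on
the quantifier only with probability 0.2 and 0.5–2× the analyte
amplitude. An exponentially-modified-Gaussian tail (`emg_tau`) is
available for asymmetric peaks, default off. All randomness flows from
one seed through spawned child generators, so batches are bit-identical
per seed.

The truth table stores the analytic area A·σ·√(2π) and borders at ±4σ
(99.99% of the mass) for integration and evaluation. The emitted *expert*
picking solution uses tighter borders at ±2.5σ: an operator marks the
visible extent of a peak, and near-baseline noise bumps on the outer
tails are not "the peak" to a reviewer — labeling them correct would
inject label noise no expert solution contains.

What the generator does **not** emulate: peak-shape drift within a batch,
correlated (pink) noise, detector saturation, co-eluting isomers with
shared qualifiers, gradient-dependent baselines, and carry-over. Passing
tests therefore demonstrate the machinery is correct under the stated
statistical structure, not that any given instrument dataset will reach
the same scores.

## Problem sizes and determinism

Tests and the acceptance script run batches between 2×2 and 24×20 cells —
the larger size matches a typical small study and keeps a full
train-and-validate cycle around a minute on one CPU. Everything is
deterministic given the seeds: tree/SVM backends are seeded, ties break
lexicographically, and reruns produce byte-identical output tables.

## Known limitations

* The mzML reader consumes only the chromatogram list (SRM traces with
  precursor/product isolation targets); spectrum-mode mzML and vendor
  formats are out of scope (convert upstream with msconvert).
* Lag resolution of the shift estimate is one sampling interval; no
  sub-sample interpolation is attempted.
* Prototype borders assume the refined shift is accurate to a few grid
  steps; metabolites whose true deviation exceeds `refined_shift_window`
  plus the fitted drift will be misaligned (bounded by design at ~0.17
  min).
* With no qualifier at all, half the evidence for the reporting decision
  disappears; the classifiers still run but specificity degrades — the
  package is intended for methods with at least one qualifier transition.
* `confusion_metrics` returns NaN specificity when TN+FP = 0 rather than
  guessing.
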