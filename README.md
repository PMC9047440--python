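# mrmprep

Fully automatic preprocessing of targeted LC-QQQ-MS data recorded in MRM
(multiple reaction monitoring) mode: from raw per-transition chromatograms
to a quality-gated table of peak areas, with no manual peak review.

`mrmprep` is aimed at targeted metabolomics labs running triple-quadrupole
instruments — in particular with HILIC separations, where retention times
drift from run to run and peak shapes vary from sample to sample. Manual
review of such batches takes hours and depends on the operator; this
package automates the two judgement calls that usually require an expert:
*which* candidate peak is the analyte (peak picking) and *whether* the
integrated peak is trustworthy enough to report (peak reporting). Both
decisions are made by machine-learning classifiers trained on
expert-labeled examples; without trained models the package falls back to
a transparent quality-score average.

## Method

For each metabolite, the instrument records a **quantifier** transition
and up to two **qualifier** transitions (one optionally a ¹³C-labeled
internal standard). Processing of a batch proceeds as:

1. **Candidate detection.** Local maxima of the smoothed quantifier trace
   inside a window around the expected RT are ranked by height; the top
   *n* (default 5) become peak candidates, with borders found by walking
   outward to the first local minimum or below 1% of apex.
2. **Quality scores.** Each candidate gets 20 scores in [0, 1] describing
   peak shape (Gaussian resemblance, symmetry, width), agreement between
   quantifier and qualifiers (trace correlation, observed vs expected
   intensity ratio), and RT deviation. Ratio-type raw values *r* are
   squashed as *s* = max(0, 1 − 1/*r*).
3. **Scoring and reference selection.** The peak-picking classifier maps
   each score vector to a probability; the sample with the highest mean
   score becomes the RT-alignment reference.
4. **Two-pass RT alignment.** Per-metabolite shifts against the reference
   are measured by simultaneous cross-correlation of quantifier and
   qualifier traces, regularized by a least-squares quadratic drift model
   shift(RT) = a·RT² + b·RT + c, then re-measured in a narrow window
   around the fitted value and refit.
5. **Prototype integration.** The aligned chromatograms of a metabolite
   are summed across all samples into a prototype chromatogram; peak
   picking runs once on this high-signal consensus trace, and the chosen
   borders are mapped back into each sample for trapezoidal integration
   above a linear baseline.
6. **Reporting gate.** The 20 scores plus the picking score and its batch
   percentiles (26 features) feed the peak-reporting classifier; only
   peaks above the reporting threshold reach the primary output table.
   Raw and ¹³C-normalized areas and heights are always written as
   alternative representations.

Training (`train_models`) derives labels from two expert tables — peak
area/start/end per cell for picking, and 0/1/2 report decisions for
reporting — and fits each classifier with a stratified 80/20 split and a
small cross-validated hyperparameter grid (random forest by default;
gradient-boosted trees, SVM and a small neural network are available).

A synthetic-batch generator (`mrmprep.simulate`) produces mzML-writable
batches with known ground truth — quadratic drift, per-metabolite RT
jitter, missing peaks, and interfering decoy peaks — so the entire system
is testable without instrument data.

## Worked example

```python
from mrmprep import ProcessingParams, process_batch, train_models
from mrmprep.simulate import SimConfig, generate_batch, emit_training_solutions

cfg = SimConfig(n_samples=24, n_metabolites=20, p_decoy=0.3, seed=7)
samples, metabolites, truth = generate_batch(cfg)
picking_sol, reporting_sol = emit_training_solutions(truth)

params = ProcessingParams(random_seed=7)
picking, reporting = train_models(
    samples, metabolites, params, picking_sol, reporting_sol, seed=7
)
print(f"picking F1 = {picking.validation_f1:.3f}")
print(f"reporting F1 = {reporting.validation_f1:.3f}")

result = process_batch(
    samples, metabolites, params,
    picking_model=picking, reporting_model=reporting,
)
print(f"reference sample: {result.reference_sample}")
print(f"reported peaks: {int(result.reported.to_numpy().sum())} / 480")
```

Output:

```
picking F1 = 1.000
reporting F1 = 1.000
reference sample: S13
reported peaks: 420 / 480
```

The held-out F1 of 1.000 means the picking classifier separates correct
peaks from decoys and noise maxima perfectly on this batch; 420 of 480
cells are reported because the generator omitted the remaining 60 peaks on
purpose (10% missingness) and the reporting gate correctly left those
cells empty.

The same pipeline is available from the shell:

```bash
mrmprep simulate --out demo --seed 7        # write a synthetic batch as mzML
mrmprep process demo/config.yaml --no-model # preprocess with fallback scoring
mrmprep train demo/config.yaml demo/picking_solution.csv demo/reporting_solution.csv
mrmprep evaluate reported.csv truth.csv     # confusion metrics vs ground truth
```

## Layout

| module | contents |
| --- | --- |
| `mrmprep.io` | mzML chromatogram reader, metabolite DB / sample info / parameter parsing, result tables |
| `mrmprep.chromatogram` | smoothing, candidate detection, borders, integration, resampling |
| `mrmprep.quality` | the 20 quality scores and the 26 reporting features |
| `mrmprep.alignment` | reference selection, cross-correlation shifts, quadratic drift model, prototype chromatograms |
| `mrmprep.models` | label derivation, classifier training/persistence, fallback scoring |
| `mrmprep.pipeline` | `process_batch` / `train_models` orchestration |
| `mrmprep.simulate` | synthetic batch generator with ground truth |
| `mrmprep.evaluate` | confusion metrics, replicate SD, reference correlation |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
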