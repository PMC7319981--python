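# maldiprofiler

Histology-directed MALDI imaging mass spectrometry (MALDI-IMS) profiling
pipeline for comparing two tissue classes across annotated tissue
compartments — built around the differential diagnosis of **low-grade
phyllodes tumor (LGP)** versus **fibroadenoma (FA)**, two biphasic
fibroepithelial breast lesions whose epithelial and stromal components are
profiled separately at pathologist-annotated spots.

The package implements, as tested and reusable code, the full analysis
chain such a study runs on its per-spot spectra, together with a synthetic
cohort generator that emulates the study design (two classes of ~30 cases,
20 epithelial + 20 stromal annotated spots per case, one spectrum per
spot, near-identical class profiles, heavy case-level heterogeneity) so
every stage is testable end to end without any data download.

## The analysis

Given per-spot spectra with provenance (case, spot, compartment, class):

1. **Preprocessing** (`preprocess`): baseline removal by the SNIP
   estimator (decreasing clipping window, 20 iterations, LLS-compressed),
   total-ion-current (TIC) normalization to the dataset median, and
   re-alignment of every spectrum to a reference (the spectrum closest to
   the 50th percentile of the TIC distribution) by a global linear warp
   `m/z' = a·m/z + b` fitted to matched landmark peaks.
2. **Peak picking** (`peaks`): local maxima on the overall mean spectrum
   with signal-to-noise above 3, where noise is the scaled median absolute
   deviation `1.4826 · median(|y − median(y)|)`; each spectrum is then
   reduced to one intensity per picked peak, giving the spectra × peaks
   matrix.
3. **Classification** (`classify`): linear-kernel SVM on standardized
   peak intensities, cost tuned by 5-fold cross-validation with folds
   grouped by case; whole cases are split into study/validation sets;
   validation cases get per-spot calls, a consistency fraction, and a
   majority final call.
4. **Differential peaks** (`diffpeaks`): per-peak AUROC via the
   Mann–Whitney identity `AUROC = U / (n_a·n_b)`, log2 fold change of
   class means with a Welch unpaired t-test (volcano coordinates),
   Benjamini–Hochberg adjustment, and mirrored ("butterfly") mean-spectra
   comparison.
5. **Clinical statistics** (`clinstats`): Wilcoxon–Mann–Whitney, Fisher
   exact, Kaplan–Meier product-limit curves with log-rank tests, and
   two-reader-averaged immunohistochemistry summaries, all two-sided.

`synthetic_data` generates cohorts from a transparent model — Gaussian
peaks on an exponential chemical baseline, log-normal per-case gain,
per-case peak-height perturbation, uniform per-spectrum mass shift,
truncated Gaussian noise — with a ground-truth sidecar recording
everything planted.

## Worked example

Run the whole pipeline on a synthetic null cohort (10 cases per class,
no planted class difference):

```python
from maldiprofiler.pipeline import RunConfig, run_all
from maldiprofiler.synthetic_data import SyntheticConfig

config = RunConfig(
    synthetic=SyntheticConfig(n_cases_per_class=10, n_peaks=40, seed=0),
    n_study_per_class=(6, 6),
    seed=17,
)
manifest = run_all(config, "results/demo")
print(manifest["classification"])
```

prints (stromal compartment shown):

```
"stromal": {"overall_accuracy": 0.375, "tuned_cost": 0.1, "n_fully_consistent": 8}
```

With nothing planted, 3 of the 8 held-out cases are called correctly —
chance-level, the expected negative result — while the volcano section of
the manifest reports 0 of 40 peaks past both the 2-fold and p < 0.05
guide lines. The run directory contains the peak matrix (delimited text),
preprocessing and classification reports, per-compartment volcano tables,
synthetic clinical/IHC tables with their summary, and a reproducibility
manifest; rerunning with the same config reproduces the outputs
byte-for-byte.

The same pipeline on a cohort with a planted 4-fold stromal effect
reaches 100% held-out case accuracy (see `experiments.signal_sanity`),
which is what makes the null result informative.

A `profiler` command mirrors the stages from the shell:

```bash
profiler simulate --seed 0 --out spectra.csv
profiler preprocess --in spectra.csv --out preprocessed.csv
profiler peaks --in preprocessed.csv --snr 3 --out matrix.csv
profiler run --out results/full_run
```

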