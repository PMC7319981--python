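# Methods

This note documents the models, numerical choices, and limitations behind
`maldiprofiler`. It is written for someone who wants to understand what the
pipeline computes and what the tests do and do not establish.

## Synthetic cohort model

`synthetic_data.generate_dataset` draws a two-class, two-compartment cohort
whose structure matches the emulated study design: `n_cases_per_class`
cases per class (FA, LGP), 20 annotated spots per compartment (epithelial,
stromal) per case, one spectrum per spot.

Each spectrum on a uniform m/z grid (default 800–3500 Da at 1 Da, the
tryptic-peptide MALDI range; the acquisition range is a package convention,
chosen because reflectron TOF peptide profiling typically covers it) is

    intensity = gain_case · [ Σ_j h_j · exp(−(mz − c_j − δ)² / 2σ²)
                              + A · exp(−λ·(mz − mz_min)) ] + ε,  clipped at 0

with

| parameter | default | meaning |
|---|---|---|
| `n_peaks` | 60 | shared peak panel, centers uniform with ≥ 8σ separation |
| `peak_height_median`, `peak_height_log_sd` | 100, 0.5 | log-normal peak heights (arbitrary units) |
| `peak_width_sigma` σ | 2 Da | Gaussian peak width; TOF reflectron peaks approximated as symmetric |
| `baseline_amplitude` A, `baseline_decay` λ | 30, 0.002 /Da | exponential chemical-noise baseline |
| `case_gain_sd` | 0.5 | log-normal per-case multiplicative gain — what TIC normalization removes |
| `case_peak_sd` | 0.3 | log-normal per-case, per-peak height perturbation — tumor heterogeneity, what makes case-level majority votes non-trivial |
| `mass_shift_max` δ | 0.5 Da | uniform per-spectrum linear mass shift — what re-alignment removes |
| `noise_sd` ε | 1.0 | additive Gaussian noise, truncated at zero |
| `effect_log2fc`, `n_discriminating_peaks` | 0, 0 | class effect: discriminating peaks × 2^fc in LGP stromal spectra |

The default is a **null** cohort — no planted class difference — because
that is the regime the emulated study found itself in. Noise is Gaussian
truncated at zero rather than Poisson (simpler variance bookkeeping,
adequate for the property tests). Isotope envelopes, detector physics, 2-D
rasters, and m/z-dependent peak width are deliberately not modeled, so
passing tests demonstrate correctness of the *analysis chain*, not realism
of instrument physics. The per-case heterogeneity model (gain × per-peak
perturbation) is the simplest structure that makes spots within a case
correlated, which is the feature of real profiling data that drives the
case-level analysis.

Clinical and IHC tables are drawn from clipped normal distributions whose
parameters match the emulated cohort summaries (e.g. LGP age mean 35.5 y,
range 14–63; FA tumor size range 1.2–5.1 cm; Ki-67 means 2.5 / 7.7 / 45.0%
across FA / LGP / HGP). Because clipping a normal shifts its mean, the
pre-clip location is solved numerically so the realized mean equals the
target. Two IHC readers see each case's true positivity with independent
noise (sd 15% of the true value, floor 0.5 points); the analysis value is
their average. The degenerate all-zero stromal E-cadherin marker is kept:
summaries must render it with p = 1 rather than fail.

## Preprocessing

**Order is fixed**: baseline → normalization → alignment. `RunConfig`
rejects any reordered stage list.

*SNIP baseline.* Decreasing clipping window: for half-window i =
`snip_iterations` … 1, every interior point is replaced by
min(v[m], (v[m−i]+v[m+i])/2) simultaneously; edges held. Default 20
iterations. The log-log-square-root compression
v = ln(ln(√(y+1)+1)+1) is applied first (standard for TOF dynamic range)
and inverted afterwards; the baseline is clipped into [0, y]. Spectra
shorter than 2·iterations+1 get a reduced window and a logged warning. A
literal two-loop implementation of the same recurrence serves as the test
oracle. Subtraction truncates at zero.

*TIC normalization.* Every spectrum is scaled so its total ion current
equals the dataset median TIC (keeping a physical intensity scale; a
unit-TIC mode exists). Zero-TIC spectra are excluded with a warning and
listed in the report.

*Reference selection.* The re-alignment reference is the spectrum whose
TIC is closest to the 50th percentile of the TIC distribution, ties to the
lowest index. Because normalization equalizes all TICs by construction,
the reference is chosen from the baseline-corrected, pre-scaling TICs —
the only reading under which the selection rule is meaningful.

*Re-alignment.* Landmarks are peaks at SNR ≥ 5 in the target, matched
one-to-one (nearest, greedy by distance) to the reference's landmarks
within 2000 ppm. With ≥ 2 matches, a least-squares line m/z' = a·m/z + b
is fitted and intensities are linearly re-interpolated onto the original
grid; otherwise — or if the slope leaves (0.9, 1.1) — the spectrum keeps an
identity warp and is flagged. A global linear warp captures TOF
calibration drift; piecewise/lowess warping is out of scope. On planted
shifts up to ±2 Da the median landmark residual is ~4% of the median
shift magnitude (the residual floor is grid quantization of detected
centers, ~dx/2).

No smoothing step is applied anywhere: the emulated workflow lists none.

## Peak picking and the peak matrix

Peaks are picked **once, on the overall mean spectrum of all spectra**
(study + validation pooled) — faithful to the emulated workflow; the mild
feature-selection leakage this implies is retained deliberately, with a
`peaks_from: study_only` option for the hygienic alternative. Candidates
are strict local maxima (plateaus take the leftmost index); retained peaks
need SNR > 3 and a minimum separation of two grid steps (higher peak
wins). Noise is the scaled MAD of the whole mean spectrum, and peak height
is measured **above the intensity median**: zero-truncation of noise
leaves a constant positive floor on the mean spectrum, and measuring
height from zero would let that floor masquerade as signal (hundreds of
spurious detections in early experiments; the floor-relative definition
reduced this to zero on the recovery study while leaving true-peak
sensitivity at 100%).

Matrix entries default to the windowed **maximum** within ±2000 ppm of
each peak center — robust to residual misalignment — with a trapezoidal
`area` alternative; whether the original "integration" meant height or
area is ambiguous, so both are supported and the default documented. No
spectrum is ever dropped; an empty peak list yields a 0-column matrix.

## Classification

Linear-kernel SVM (`C` from {0.1, 0.5, 1, 5, 10}) on features
standardized to zero mean/unit variance on the study set (linear SVMs on
raw intensities are scale-sensitive; the standardization is stored and
reused at prediction). Cost tuning: stratified 5-fold CV with folds
grouped by **case** (no case contributes spots to both sides of a fold;
a `spot` mode exists for fidelity experiments since the original fold
construction is unknown). Ties in CV accuracy go to the smaller cost
(more regularization). Folds are reduced with a warning when a study set
has fewer cases than folds. Epithelial and stromal compartments are
trained and evaluated separately by default (the compartments were
analyzed separately), with pooling available.

Case aggregation: the final call is the modal spot call; consistency is
the modal share; an exact tie is `indeterminate` and scored incorrect
(conservative). Evaluation reports overall accuracy, per-class
(correct, total), the number of fully consistent cases, and mean
consistency.

## Differential peaks

AUROC is computed through the rank-sum identity with midranks; the O(n²)
pairwise loop is the test oracle. The volcano uses the log2 ratio of class
means (means floored at machine epsilon with a flag), a **Welch**
unequal-variance t-test (the unpaired-t phrasing does not specify; a
pooled-variance switch exists), and Benjamini–Hochberg adjustment across
peaks. Guide lines default to |log2 FC| = 1 and p = 0.05; the "minimal
change" threshold in the emulated figure is never defined numerically, so
it is configurable.

The analysis unit defaults to the spot-level spectrum, matching the
emulated figure. Spot-level tests are **pseudo-replicated** whenever
per-case heterogeneity exists — under the null generator ~70–80% of
spot-level raw p-values fall below 0.05 — so a `unit="case"` mode first
averages spots within cases; only in that mode is the type-I rate
calibrated (fraction of raw p < 0.05 sits in the binomial band around
0.05), and that mode is what the calibration study checks.

## Clinical statistics

WMW: exact p when min(n) ≤ 8 with no ties, otherwise normal approximation
with tie and continuity corrections; fully degenerate input returns p = 1.
Fisher: two-sided p by the probability-at-most-observed rule (the common
software default; conventions differ, hence documented), sample odds ratio
with 0.5 added to every cell only when a cell is zero — the continuity
correction never touches the p-value; a zero margin gives p = 1 with the
OR flagged undefined. Kaplan–Meier/log-rank ride on lifelines; tied
event/censor times follow the events-first convention; no events in either
group makes the log-rank vacuous (χ² = 0, p = 1). All tests are two-sided.
Cox or any multivariable modeling is out of scope.

## Replication experiments and problem sizes

`experiments` wires everything together at a scaled-down problem size —
**10 cases per class, 20 spots per compartment, 40 peaks** (the spot count
is kept at the study design's value; the case count is scaled from ~30 per
class so a ≥ 20-replicate study runs in minutes on one CPU; statistical
bands in the tests are computed for the sizes actually run):

- *Null calibration*, 24 replicates: mean held-out case accuracy inside
  the 95% binomial band around 0.5 (192 case calls), and case-mean volcano
  raw p < 0.05 fraction inside the band around 0.05 (960 p-values). This
  is the qualitative reproduction of the emulated study's negative result.
- *Signal sanity*, 3 replicates with a 4-fold effect on 5 stromal peaks:
  held-out accuracy ≥ 0.95 (observed 1.0) — the null result is a property
  of the data, not a blind spot of the pipeline.
- *Mass-shift recovery*: 50 spectra, shifts uniform ±2 Da on a 0.1 Da
  grid; median landmark residual ≤ 10% of the median shift.
- *Peak recovery*: 15 weak planted peaks (mean-spectrum SNR ≥ 5),
  threshold 3, 10 replicates: sensitivity ≥ 93%, false discoveries ≤ 5%.
- *Fold-change recovery*: one 4-fold stromal peak among 50, small-noise
  regime (per-case heterogeneity nearly off, isolating the chain's
  systematic error): |log2 FC − 2| < 0.2 with BH-adjusted p < 0.05. The
  residual bias is the compression TIC normalization applies when a
  planted effect perturbs the total ion current (≈ log2(53/50) here).

## Known limitations

- The generator's spectra are far cleaner than real FFPE tryptic profiles
  (no isotopes, no m/z-dependent resolution, no spot-to-spot digestion
  variability); passing recovery tests bounds algorithmic error, not
  expected performance on real tissue.
- The linear warp cannot express higher-order TOF miscalibration.
- Windowed-maximum integration overestimates intensities when two picked
  peaks fall within one window; the generator's 8σ separation avoids this,
  real data may not.
- Spot-level volcano output is for figure fidelity; inference should use
  the case-mean mode.
- mzML support covers the common profile-spectrum core (little-endian
  32/64-bit floats, none/zlib compression), not the full standard; imzML
  is read through pyimzml. Bruker raw formats are not read.
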