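# Methods

This note records the statistical model behind `peptidiff`, the choices
made where the original analysis workflow left details open, and what the
synthetic-data generator does and does not emulate.

## Per-peak testing

Each row of the analysis matrix is compared between two groups with the
two-sided Wilcoxon–Mann–Whitney test. The implementation (a thin policy
layer over `scipy.stats.mannwhitneyu`) selects:

- the **exact** null distribution when the pooled sample size is ≤ 20 and
  the pooled values contain no ties;
- the **normal approximation with tie correction and continuity
  correction** otherwise (the study's comparisons have n = 20–21, so this
  is the path real-size data takes);
- **p = 1** when every pooled value is identical (the statistic's variance
  is zero and no evidence against the null exists).

Missing values ("absent" peaks) are governed by a *missing policy*:

- `zero` (default): absences enter the test as zeros. The rationale is
  physical — an undetected peak is below the detection limit, i.e. lower
  than every detected intensity — and empirical: with this policy the
  p-values of peaks whose significance is driven purely by detection
  patterns reproduce published CSF results exactly (detection 0/10 vs
  6/11 → p = 0.0092; 7/10 vs 0/11 → 0.0014; 6/10 vs 0/11 → 0.0041, each
  matching the printed value at all printed digits). These three values
  are frozen in the test suite.
- `detected-only`: only detected samples enter the test; a peak with no
  detections in either group gets an undefined p-value. Provided because
  the original matrix-processing software's behaviour is undocumented.

Fold changes always use detected samples only (larger group mean over
smaller, so ≥ 1 with a separate direction field) and are undefined when a
group has zero detections — this asymmetry (defined p, undefined fold)
mirrors how peptides absent from one whole group are reported. Incidences
are integer percentages; the default rounds half-up (3 of the 4
non-trivial printed incidences in the reference tables are consistent with
rounding, 1 with truncation; truncation is available as an option).

No multiple-testing correction is applied, deliberately: the study design
judges the *count* of p < α peaks against a permutation background
instead. Significance is strict (`p < α`, not ≤).

## Permutation background

For a comparison of groups A and B the matrix is restricted to their
samples, the A/B labels are permuted uniformly at random (group sizes
exactly preserved — permutation of the label multiset, not resampling),
the full per-peak test is re-run, and the count of p < α peaks recorded.
Default 50 iterations; duplicate permutations across iterations are
allowed (50 ≪ C(21,10)); the summary is mean and sample SD (n−1). All
randomness flows from one `numpy` Generator seeded explicitly, so a fixed
seed reproduces the estimate bit-for-bit.

## Calibration and matrix construction

Peak lists are recalibrated against reference ("omnipresent albumin")
peaks: each reference mass is paired with its nearest observed peak within
a ppm tolerance (default 20 ppm), an ordinary least-squares line maps
observed → reference m/z, and the whole axis is transformed. At least two
matched references are required; the model keeps slope, intercept and
post-fit residuals. The reference list defaults to the theoretical [M+H]⁺
monoisotopic masses of five abundant tryptic peptides of human serum
albumin (LVNEVTEFAK, YLYEIAR, AEFAEVSK, QTALVELVK, LVTDLTK), computed at
run time by the mass module; they contain no Cys or Met, so modification
conventions cannot shift them. The identity of the original five calibrant
peaks is not public; any reference list can be passed instead.

Alignment pools all samples' peaks, sorts by m/z and applies single-linkage
clustering with a relative gap threshold (default 5 ppm, an FT-ICR-scale
choice; the original value is unknown and the parameter is exposed): a new
matrix row starts wherever the gap to the previous pooled peak exceeds the
tolerance. On sorted one-dimensional data this equals full transitive
single linkage (verified in the tests against an exhaustive union-find
oracle). Consensus m/z is the intensity-weighted mean of the cluster; a
sample contributes at most one peak per cluster (most intense wins, with a
warning); cells without a contribution are *absent* (NaN), never zero. No
intensity normalization is applied — none is documented for the original
pipeline — so fold changes are ratios of raw group means.

Matrix files: tab-separated text (bit-exact round trip; cells parsed with
correctly-rounded `float()`, not pandas' fast parser) and XLSX via
openpyxl, which stores 15 significant digits (Excel's stored precision),
so XLSX round trips are exact to 1 part in 10¹⁴.

## Contamination QC

Two independent rules, a sample being excluded if either fires:

1. **Marker rule**: any peak within 10 ppm (configurable; the original
   window is unstated) of the hemoglobin-gamma peptide at m/z 1274.7255
   with S/N ≥ 4. If peaks sit in the window without S/N values the rule
   reports "not evaluable" and the sample fails conservatively rather
   than passing silently.
2. **Identification rule**: a peptide-spectrum match surviving the
   charge-dependent SEQUEST XC thresholds (1.8 / 2.2 / 3.75 for 1+ / 2+ /
   3+) whose accession is a blood protein (hemoglobin α/β/δ/γ1/γ2 or
   apolipoprotein B-100 by default; extendable). The same thresholds
   define "sufficiently confident" as define reliable identification —
   no separate cutoff is documented.

Both rules are monotone in their thresholds (raising a threshold never
flags a previously passing sample), which the tests check.

## Peptide masses and annotation

Monoisotopic masses are summed from the standard residue mass table plus
one water (18.0105647 u); [M+H]⁺ adds one proton (1.00727647 u), singly
protonated ions being the MALDI assumption. Modification deltas default to
the three-decimal values used in the original workflow (+57.021
carboxymethyl-Cys, fixed on every Cys; +15.996 Met oxidation, variable per
site) so that 2 ppm matching behaves identically; full-precision constants
are available. Digestion cleaves C-terminal to K/R except before proline
(Keil rule), emits all peptides with 0–2 internal missed cleavages
labelled with their count, and generates every combination of oxidized
methionines as a separate candidate. N-terminal Met removal and
semi-tryptic peptides are out of scope. Matching keeps *all* candidate
peptides within the ppm cutoff per observed mass, sorted by absolute
error; ambiguity is reported, not resolved.

## Validation statistics

Group summaries use the sample SD (n−1). Two-sample t-tests are provided
in both the pooled-variance and the Welch variant, plus a summary-level
version reconstructed from (mean, SD, n) triples with Welch–Satterthwaite
degrees of freedom — published tables print only summaries, and the
variant used originally is unstated, so reports carry both. Reconstructed
p-values for the four published assay summaries land at 0.014–0.018
(printed 0.017), 0.018 (0.019), 0.032 (0.032) and 0.040 (0.041): the
printed values are consistent with either variant at n = 10/11 and 10/10,
and all stay below 0.05 under at least one variant.

## Synthetic-data generator

The generator emulates the features the analysis depends on:

- **Intensities** are log-normal per peak: peak *i* has log-mean μ +
  δᵢ with δᵢ ~ N(0, spread) (defaults μ = 9, spread = 1) and
  within-peak log-SD 0.6. MS peak intensities are right-skewed and
  multiplicative; the original study documents no distribution, so
  log-normal is the field-standard choice.
- **Detection** is Bernoulli per peak per sample with a per-group
  probability (default 1.0, i.e. a continuous matrix — the cleanest null
  for calibration checks); undetected cells are absent, not zero.
- **Planted effects** add log(fold) to the affected group's log-mean or
  shift its detection probability; draws are made before effects are
  applied, so a no-op effect reproduces the null matrix exactly.
- **Group sizes** default to 10 (PP) / 11 (RR) / 10 (control), the study
  cohort.
- **Peak lists** derived from the matrix add the five albumin calibrants
  to every sample, a uniform ppm calibration drift, S/N values scaled to
  a noise floor two log-SDs below the base intensity, and optional
  blood-marker spikes at a requested S/N.
- **Streams**: every sample has its own random stream keyed by (master
  seed, group, within-group index), so enlarging the experiment never
  perturbs existing samples; equal config + seed gives byte-identical
  output.

Not emulated: profile-mode spectra, isotope envelopes, correlated peaks
from the same protein, intensity-dependent detection, batch effects, or
m/z-dependent calibration error. Passing tests on this generator therefore
demonstrate the statistical machinery (test calibration, power at stated
effect sizes, background estimation, QC logic), not robustness to every
artefact of real spectra.

## Problem sizes and numerical choices

The bundled checks run the null calibration at 1000 peaks × 21 samples
with 50 scramblings, and power estimates over 200 replicates of small
(5-peak) matrices containing the planted peak — sizes chosen so the whole
suite completes in seconds while keeping binomial uncertainty on estimated
rates near ±3 percentage points. Expected null behaviour at α = 0.01: the
continuity-corrected approximate test is slightly conservative at n =
10/11, so the per-peak rejection rate sits a little below α and observed
counts land in the lower half of the 3-SD binomial band around 10 per
1000 peaks — the same conservatism applies to observed and scrambled
counts alike, which is exactly what the background construction assumes.

## Known limitations

- The permutation background estimates the chance count, not per-peak
  permutation p-values; nothing corrects individual p-values.
- Incidence printing (round vs truncate) and the missing-value policy of
  the original matrix software are not documented; both are options here,
  with defaults chosen to match the published tables where checkable.
- The XLSX dialect is limited to 15 significant digits by the storage
  format.
- Fold changes on detected-only means are biased upward for peaks near
  the detection limit (censoring); the incidence columns carry the
  complementary information.
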