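# Methods

## Data model and coordinates

All genomic intervals are 0-based half-open, matching BED. A per-CpG track
stores strand-combined counts on the plus-strand C of each CpG: the
minus-strand C of a CpG lies one base 3' of the plus-strand C, so a
minus-strand call at position *p* is summed onto *p − 1*. CpGs observed on
only one strand are retained — discarding them would throw away roughly half
the information at ×1–2 coverage — and minus-only calls are remapped to
*p − 1* rather than dropped, with their number reported. The CpG-report file
dialect uses 1-based positions (the prevalent convention) and the reader
converts on input. Zero-coverage records are dropped at parse time; they
carry no information for any downstream statistic.

Clonal PCR duplicates are removed by keeping exactly one read per
(chromosome, start, strand) key; which duplicate survives is not
statistically meaningful, so the first in input order is kept for
determinism. Fold coverage is (number of mapped reads × read length) /
genome size, with the sum of lengths used for variable-length reads.

## Window methylation

The genome is tiled into non-overlapping windows (default 20 000 bp; the
final window of a chromosome may be shorter and is flagged partial). Window
methylation is **count-pooled**: Σmeth / Σtotal over the CpGs in the
window, not a mean of per-CpG fractions. At ×1–2 coverage per-CpG fractions
are mostly 0 or 1, so the pooled ratio is the maximum-likelihood estimate
of the window's methylation level while a mean of fractions would be
dominated by sampling noise. Windows with fewer than `min_support` total
calls (default 10 per 20 kb) are reported missing rather than noisy; the
threshold is exposed as a flag because no principled universal value
exists. "Fraction of windows below 60%" uses strict inequality; a window at
exactly 0.60 counts as not below.

Cross-sample distribution summaries bin each sample's observed window
fractions at 1% increments into 100 normalised bins and report min, mean,
max and population SD across samples per bin. Profile smoothing is a
first-order local polynomial (the LOESS building block): at each window
midpoint a weighted least-squares line is fitted over neighbours within the
bandwidth using tricube weights, and its intercept is the smoothed value.
Local linear fits reproduce constant and linear profiles exactly, which the
tests assert. A Gaussian-kernel density with Silverman bandwidth is
provided for plotting only and never feeds statistics.

## Two-state domain segmentation

The segmentation model is a two-state hidden Markov model over the pooled
consensus's window methylation fractions, with states PMD and HMD.

* **Pooling.** Individual samples are too shallow to segment; counts from
  all reference samples are summed per CpG first (17 samples at ×1.5 gives
  a ~×25 consensus).
* **Emissions.** Gaussian per state on the window fraction. The emission
  family is a modelling choice; a Gaussian on 20 kb pooled fractions is
  well justified by the central limit theorem (hundreds of calls per
  window) and keeps supervised training closed-form. Emission SDs are
  floored at 0.01 to guard degenerate (constant) training data.
* **Supervised training.** From hand-annotated example domains: state
  means/SDs are the sample mean/SD (ddof = 1) of window fractions inside
  that state's annotated intervals; each state's self-transition is
  1 − 1/(mean annotated run length in windows), the moment estimate for the
  geometric run-length law an HMM implies; the initial distribution is the
  stationary distribution of the transition matrix. Training requires at
  least two observed windows per state.
* **Decoding.** Hard Viterbi in log space — the deliverable is a single
  boundary map, not posterior marginals. Windows with missing fractions
  contribute no emission term; the path is bridged on transitions alone and
  missing windows are absorbed into the flanking decode. Exact ties resolve
  toward PMD (first-index argmax), a documented deterministic convention.
  A chromosome with no observed windows yields no domains and a warning.
* **Post-processing.** Off by default (`policy="keep"`): the decoded map is
  reported as-is. An opt-in merge pass absorbs domains shorter than a
  minimum length (default 100 kb, motivated by the typical scale of PMDs)
  into the longer flanking neighbour, ties to the preceding one, then
  re-merges same-state neighbours until stable.

Per-sample domain methylation is count-pooled per domain; per-sample global
PMD/HMD means are count-weighted pools over all of a sample's CpGs inside
that state's domains, which makes window-level and domain-level totals
conserve exactly (asserted in tests). The PMD–HMD relationship across
samples is summarised by the Pearson correlation of the two global means,
overall and per diagnostic group with least-squares lines.

## Contamination estimation

In female cells, X inactivation methylates CpG-island promoters on the
inactive X to roughly 50%; in male cells (one active X) the same islands
stay low. A male placental sample mixed with maternal blood therefore shows
elevated methylation over X CGIs in proportion to the female-cell fraction:

  f̂ = clip((m_CGI − m_male) / (m_female − m_male), 0, 1)

where m_CGI is the count-pooled methylation over all CpG islands **fully
contained** in X-chromosome HMDs (partial overlaps are excluded; "within"
is taken literally). The baselines default to m_male = 0.10 and
m_female = 0.50 — "low in pure male tissue, half-methylated in female
cells" — and are mandatory, reportable parameters: no empirical reference
values exist for them in general, and any absolute interpretation of f̂
must state them. The estimator is linear, hence monotone in m_CGI.
Correlations between f̂ (or m_CGI) and autosomal PMD methylation are
computed over male samples only, since the logic does not constrain
females; female samples are reported descriptively (their own inactive X
puts m_CGI near the female baseline regardless of contamination).

## Differential statistics

* **t-test.** Welch's unequal-variance statistic with Welch–Satterthwaite
  degrees of freedom, the conservative default when group variances are not
  known to be equal; a pooled-variance option exists. Degenerate inputs
  follow explicit conventions: both groups constant and equal → p = 1;
  both constant and different → p = 0 with t = ±∞.
* **FDR.** Benjamini–Hochberg step-up (via `statsmodels.multipletests`)
  with monotone q-values; rejection at q ≤ 0.05. Each feature class —
  PMDs, HMDs, chromosomes, promoters, CGIs, gene bodies, 20 kb windows,
  chromatin-state elements — is corrected as its own family, since each
  class is tested as a separate analysis.
* **Feature scan.** One Welch test per feature; features with fewer than
  two non-missing values in either group, or zero variance in both, are
  skipped and counted rather than given degenerate p-values.
* **Chromatin-state profiles.** Per element, the per-sample value is the
  unweighted mean of per-CpG fractions (each CpG counts once), then element
  values are averaged across each group's samples; state-level summaries
  use the standard box-plot convention (median, quartiles, whiskers at the
  furthest points within 1.5 × IQR).
* **Regressions.** Ordinary least squares with treatment-coded categorical
  predictors against declared reference levels. Responses are expressed in
  analysis units — 5 percentage points for PMD methylation, 2 for HMD
  (≈ 2 SD of each), 5% for the windows-below-60% metric — so coefficients
  read "units of response per unit of predictor". "Adjusted" models add the
  co-response (e.g. PMD mean adjusted for HMD mean) as a covariate that is
  not itself a tested term. BH-FDR runs across the family of reported
  terms. Rank-deficient designs raise an error naming the collinear
  columns.
* **Model selection.** AIC with the Gaussian log-likelihood, the constant
  counted among the parameters; all candidates must resolve to the same
  complete-case sample set or the comparison is refused. Ties go to fewer
  parameters, then declaration order. AICc is available behind a flag but
  is not the default. The selected model's coefficients are reported with
  HC1 sandwich-robust 95% confidence intervals ("sandwich estimator" is a
  family; HC1 is the declared member).

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated.

* **Architecture.** Each chromosome alternates PMD/HMD segments with
  lengths drawn in whole 20 kb windows from geometric laws (mean 300 kb for
  PMDs, 150 kb for HMDs) — the run-length family the HMM implies, keeping
  training and decoding self-consistent; a lognormal heavy-tailed option
  exists for robustness experiments. CpG positions follow an exponential
  spacing model (mean 100 bp; 20 bp inside CpG islands). State methylation
  means default to 0.55 (PMD) and 0.85 (HMD). Per-CpG locus noise (Gaussian
  on the logit, SD 0.1) is drawn once per architecture and shared by all
  samples, breaking up unrealistically uniform windows.
* **Counts.** Per CpG, depth ~ Poisson(fold coverage, default 1.5) and the
  methylated count ~ Binomial(depth, p); zero-depth CpGs are omitted.
* **Between-sample structure.** Offsets act on the logit scale, so mixtures
  and shifts stay inside [0, 1] without clipping: a shared component
  (SD 0.075) plus state-specific components (SD 0.07 PMD, 0.04 HMD). These
  defaults are calibrated so a ~47-sample cohort spreads its global PMD
  means over roughly 10 percentage points and its HMD means over roughly 4
  — PMDs more variable than HMDs — with a clearly positive PMD–HMD
  correlation through the shared component. Independent per-sample,
  per-domain noise of 2.5 percentage points (converted to logit scale at
  the local mean) sets the between-sample SD at domain scale, the scale on
  which differential tests operate; within-group domain variance has no
  published reference value, so this is a declared free parameter used
  consistently across all validation experiments.
* **Planted effects.** A designated autosomal HMD is shifted by a
  configured group difference (default 5 percentage points) in the ASD
  group. Maternal-blood admixture mixes probabilities linearly:
  p ← (1 − f)·p_placenta + f·p_blood, with blood at 0.85 everywhere
  (blood has no PMDs) except female X CGIs at 0.50. Placental X CGIs take
  0.10 in males and 0.50 in females; X CGI CpGs are governed by
  X-inactivation state alone and receive no global offsets or domain noise.
* **Annotations and truth.** The generator emits exactly the formats the IO
  layer reads (CpG reports, BED annotations, CSV sample sheet) plus a JSON
  truth ledger recording domains, offsets, the planted DMR, contamination
  fractions, sexes and seeds. "Visual annotation" for supervised training
  is simulated as a random ~30% subset of true autosomal domains. All
  randomness flows from explicit seeds; identical configuration gives
  byte-identical output.
* **What it does not emulate.** Read-level artefacts (bisulfite conversion
  errors, mapping bias, SNPs), real chromosome lengths and sequence
  composition, CpG clustering beyond the two-rate spacing model, and
  cell-type heterogeneity beyond a single blood admixture component.
  Passing tests therefore demonstrate the correctness and calibration of
  the algorithms under the stated generative model, not robustness to every
  artefact of real libraries.

For a statistics-scale experiment (FDR calibration, DMR power) the
feature-matrix generator draws domain-summary values directly —
baseline + Gaussian noise at the domain-scale SD — bypassing the count
layer, which is the appropriate resolution for hundreds of replicates.

## Validation experiments and problem sizes

The reproduction script and the acceptance tests run: exact agreement of
the Viterbi decoder with exhaustive path enumeration on 100 random
instances of up to 12 windows; domain recovery (window accuracy and median
boundary displacement) on a 10 Mb genome pooled from 17 samples at ×1.5;
contamination recovery at planted fractions 0/5/10/20% over 60 X CGIs, 20
replicates each; the empirical false-discovery proportion on 200 null
cohorts of 500 features at n = 24 vs 23; planted-DMR top-rank frequency
over 100 replicates at a 5-point shift and 2.5-point within-group SD; and
the landscape metrics of one default 47-sample cohort on two 5 Mb
autosomes. These sizes keep the whole validation suite to well under a
minute while leaving every Monte-Carlo bound comfortably tight.

## Known limitations

* Supervised training only; there is no Baum–Welch refinement and no
  support for more than two states.
* Single-sample segmentation at ×1 coverage is out of scope by design — the
  model is meant to run on a pooled consensus.
* The contamination estimator's absolute scale depends entirely on the two
  baseline constants; without matched reference data it should be read as a
  relative QC ranking.
* Decoded X-chromosome HMDs can fragment at windows containing CpG islands
  (the islands locally depress window methylation); for CGI selection a
  reference domain map for X is preferable to a fresh decode.
* BH-FDR assumes independent or positively dependent tests; domain
  methylation of neighbouring features is weakly correlated, which BH
  tolerates but does not exploit.
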