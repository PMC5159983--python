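# pmdkit

Segmentation and cohort statistics for partially methylated domains in
low-coverage whole-genome bisulfite (WGBS / MethylC-seq) methylomes.

Placental genomes — unlike most somatic tissues — alternate between large
**partially methylated domains** (PMDs, intermediate methylation, usually
over 100 kb) and **highly methylated domains** (HMDs). Because individual
samples are typically sequenced at only ×1–2 coverage, domain structure is
estimated from a pooled consensus and per-sample statistics are computed by
pooling counts within windows and domains. `pmdkit` implements that whole
path for epigenomics researchers comparing diagnostic groups (for example
ASD vs typically developing children in a birth cohort):

* **IO & bookkeeping** — per-CpG count tracks (CpG-report or count-bedGraph
  dialects), strand combining onto the plus-strand C, clonal read
  deduplication, fold-coverage estimation, BED interval IO, sample sheets.
* **Window profiles** — non-overlapping 20 kb windows with count-pooled
  methylation (Σmeth/Σtotal), the fraction of windows below 60%
  methylation, 1%-binned cross-sample distributions, and local-linear
  (LOESS-style) profile smoothing.
* **Domain segmentation** — a supervised two-state Gaussian hidden Markov
  model over window methylation. Emissions are N(μ_s, σ_s²) per state
  trained on annotated example domains; self-transitions are
  1 − 1/(mean annotated run length); decoding is hard Viterbi in log space,
  with transition-only bridging across low-coverage windows.
* **Contamination QC** — maternal-blood (female-cell) fraction of male
  placental samples from CpG-island methylation inside X-chromosome HMDs:
  X inactivation puts female CGIs near 50% methylation while male CGIs stay
  low, so f̂ = clip((m_CGI − m_male) / (m_female − m_male), 0, 1).
* **Differential statistics** — per-feature Welch t-tests with
  Benjamini–Hochberg FDR at 5% within each feature class (PMDs, HMDs,
  chromosomes, promoters, CGIs, gene bodies, windows, chromatin-state
  elements), unit-scaled univariate OLS, AIC model selection, and HC1
  sandwich-robust confidence intervals.
* **Synthetic cohorts** — a generator that emulates the full study design
  (alternating domain architecture, Poisson×binomial counts at ×1–2
  coverage, correlated per-sample offsets, a planted differential HMD,
  maternal-blood admixture) with a recorded ground-truth ledger, so every
  stage is testable without protected human data.

## Worked example

Simulate a 47-sample cohort (24 ASD vs 23 TD, ×1.5 coverage, two 5 Mb
autosomes plus an X), fit the segmentation model on the pooled autosomal
consensus, and scan HMDs for differential methylation:

```python
from pmdkit import (ArchitectureConfig, CohortConfig, generate_cohort,
                    DomainSegmentation, feature_scan)
from pmdkit.io import CpGTrack

cohort = generate_cohort(ArchitectureConfig(seed=7), CohortConfig(seed=7))
arch = cohort.architecture
autosomes = {c: L for c, L in arch.genome.items() if c != "chrX"}
tracks = [CpGTrack(t.sample_id, t.data[t.data["chrom"] != "chrX"], genome=autosomes)
          for t in cohort.tracks]

res = DomainSegmentation.from_tracks(tracks, arch.training).fit()
print(res.summary())
```

```
Two-state PMD/HMD segmentation
==================================
PMD: emission mean=0.5435 sd=0.0100 self-transition=0.9054 n_domains=23 mean_length=292,174 bp
HMD: emission mean=0.8453 sd=0.0100 self-transition=0.8571 n_domains=23 mean_length=142,609 bp
PMD genome share: 67.2%
```

The decoded PMDs sit near 54% methylation and HMDs near 85%, with domain
lengths of a few hundred kb. Testing every decoded HMD between groups:

```python
table = res.domain_methylation(cohort.tracks)
hmds = (res.domains.data["state"] == "HMD").to_numpy()
values = table.fractions[hmds]
values.index = [f"{r.chrom}:{r.start}-{r.end}"
                for r in res.domains.data[hmds].itertuples()]
print(feature_scan(values, cohort.groups(), "HMD").top(3))
```

```
          feature_id  mean_ASD  mean_TD         t        p        q  rejected
chr1:4660000-4780000  0.896761 0.849732  5.317598 0.000006 0.000131      True
        chr2:0-80000  0.851129 0.831675  2.312448 0.025832 0.297066     False
chr1:1040000-1440000  0.843236 0.859759 -1.911052 0.062463 0.478886     False
```

The only HMD surviving FDR correction (q ≈ 1.3 × 10⁻⁴, ASD ~4.7
percentage points above TD) is exactly the domain the generator planted
(`cohort.truth.dmr` → `chr1:4660000-4780000`, Δ = 5 pp).

A command-line front end mirrors the library
(`pmdkit simulate | windows | segment | contam | diffstats`).

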