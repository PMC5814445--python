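# lesionscope

Analytics for the multi-platform lesional landscape of T-cell
prolymphocytic leukemia (T-PLL) — a mature T-cell malignancy shaped by
TCL1 activation, biallelic ATM loss, chr.8q gains and JAK/STAT
mutations. The package re-implements, as a tested and reusable library,
the bespoke computational steps such a cohort study needs between the
standard callers and the figures:

- **Somatic filter cascade** (`lesionscope.filtering`) — population-MAF
  exclusion (MAF ≥ 0.01), damaging-prediction enrichment (PolyPhen2
  ≥ 0.957 or SIFT ≤ 0.05; PROVEAN for indels), COSMIC membership,
  second-caller confirmation for subclonal calls, targeted-amplicon
  quality gates (qual ≥ 100, depth ≥ 10), and the 8-oxoguanine
  orientation-bias filter: a call passes iff
  `TLOD ≥ 10 + (100/3)·FoxoG`, where FoxoG is the fraction of
  alternate read pairs in the oxidation-damage orientation.
- **Copy-number profiling** (`lesionscope.cna`) — length-weighted
  mapping of CBS segments (IGV SEG) onto genes; loss/gain calls at
  CN < 1.5 / CN > 2.5; minimal deleted/amplified regions as the
  maximal-frequency contiguous gene run; uniparental disomy as LOH
  genotype with CN ∈ [1.9, 2.1]; per-case complexity tiers and decade
  size-bin spectra.
- **Mutational spectra** (`lesionscope.spectrum`) — 12/6/96-class
  trinucleotide spectra, Mut/Mb rates, per-class odds ratios with
  Fisher tests, rank statistics, Spearman similarity to signature
  catalogs.
- **Expression statistics** (`lesionscope.expression`) — raw-scale
  signed fold-changes with t-tests on log2 values, Storey q-values,
  quantile-buffered two-tier stratification.
- **Lesion integration** (`lesionscope.integrate`) — allelic genotype
  classes (LOH / biallelic-mutated / UPD-mutated / ...), GOF/LOF calls
  (CN > 2.2 or CN < 1.7 with VAF > 0.5), deterministic cellular
  prevalence `CCF = VAF·(ρ·CN + 2(1−ρ))/ρ`, co-occurrence tests, the
  eight-category lesional matrix, gene-centric landscape summaries and
  cohort frequencies.
- **Prognostic index** (`lesionscope.prognostic`) — extreme-survivor
  selection (> 800 d vs < 300 d), SAM-style survival scoring
  `d = r/(s + s0)` with a permutation FDR, regression-guided training
  refinement, Tukey median-polish expression index, Kaplan–Meier /
  log-rank evaluation.
- **Drug synergy** (`lesionscope.synergy`) — plate normalization,
  four-parameter Hill fits, ZIP delta scores
  `δ = 100·(y_obs − (y_a + y_b − y_a·y_b))`, low-dose (1–300 nM)
  summaries, rank-sums, Friedman and Wilcoxon statistics.
- **Synthetic cohort** (`lesionscope.simulate`) — a fully synthetic,
  seed-deterministic multi-platform cohort (variants with clonal
  structure and orientation-biased artifacts, CN segments with planted
  common deletions, survival-linked expression probes, Hill-shaped
  dose-response plates) with a truth sidecar, so every stage is
  testable without any controlled-access download.

The numbered scripts under `analysis/` run the whole landscape study on
the synthetic cohort and write their tables under `results/`.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_filter_variants.py
python analysis/06_prognostic_index.py
```

prints (abridged):

```
  somatic calls: 3744 (558 injected oxo artifacts)
3744 calls -> 2529 after cascade
  removed by population: 318
  removed by second_caller: 535
  removed by oxog: 362
injected artifacts: 558, surviving: 0
probes after first SAM pass: 3; final probe set: ['P_surv1', 'P_surv2', 'P_surv3']
two-tier split (5% buffer): 32 high vs 31 low
log-rank chi-square 29.36, p = 6.02e-08
```

The cascade removes all 558 injected orientation-bias artifacts (none
survive), the SAM-survival pipeline recovers exactly the three planted
survival-associated probes out of 500, and the median-polish index
splits the cohort into prognostic tiers with a strongly significant
log-rank separation. `analysis/03`–`05` and `07` produce the
copy-number landscape (the planted ATM minimal deleted region at 39.8%
cohort frequency), the mutational spectrum (C>A odds ratio 5.44 against
an unbiased control), the integrated lesional matrix, and the ZIP
synergy ranking (rank-sums summing to 273 over 13 cases × 6
combinations, Friedman p ≈ 1e-10).

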