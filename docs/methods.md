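# Methods

This note documents the models, parameter choices and numerical
conventions behind `lesionscope`, and what the synthetic cohort does and
does not establish about real data.

## Variant filter cascade

Calls enter as annotated records (VAF, depth, Phred quality,
orientation-resolved alternate read counts, tumor-load log-odds,
population MAFs, damaging scores, COSMIC flag). Rules are pure
predicates; the cascade is their conjunction, so the surviving set is
independent of rule order — only the removal tally, which attributes
each removal to the first failing rule in the fixed order
population → damaging → COSMIC → second-caller → oxo → TAS-quality,
depends on it. All thresholds are inclusive exactly as printed
(≥ / ≤ / "at least").

*Damaging logic.* PolyPhen2 and SIFT are combined with OR by default
(either algorithm calling a variant damaging suffices; an AND switch is
provided). An SNV with neither score is "not evaluable" and passes
through by default, configurable.

*8-oxoG filter.* FoxoG is the fraction of alternate read pairs in the
orientation produced by oxidized guanine: F2R1 for C>A, F1R2 for G>T.
The filter applies only to C:G>A:T-class substitutions — the artifact
mechanism is specific to 8-oxoG — and exempts calls with no oriented
alternate reads. The pass rule is `TLOD ≥ 10 + (100/3)·FoxoG`.

*Second-caller rule.* Calls with VAF < 0.5 that are explicitly marked
unconfirmed by a second caller are dropped; the annotation is a
caller-agnostic boolean column, absent meaning "not subject".

## Copy-number profiling

Segments are 1-based inclusive with linear CN (diploid = 2); log2-ratio
SEG files are converted on read as `CN = 2·2^ratio`. Per gene and case
the CN is the overlap-length-weighted mean of overlapping segments;
genes with no overlap default to neutral CN 2 (array exports often omit
unaltered regions). Loss/gain calls use CN < 1.5 / CN > 2.5.

*Minimal regions.* The per-gene affected frequency is scanned along the
chromosome; the minimal deleted/amplified region is the contiguous run
of genes at the maximal frequency, ties broken by smallest genomic span
then leftmost start. This formalizes the "minimal common region"
intent; affected cases are those flagged on *every* gene of the run,
and the reported frequency is recomputed from that set (in planted or
unanimous scenarios it equals the per-gene maximum). Only raw cohort
frequencies are produced; no reference-panel recalibration is applied.

*UPD.* Copy-neutral LOH: an externally supplied LOH genotype flag
combined with CN ∈ [1.9, 2.1], both bounds inclusive.

*Complexity.* Per-case counts of loss/gain-flagged genes after removing
genes in caller-specified excluded regions; tiers moderate (< 2000),
intermediate ([2000, 5000]), high (> 5000).

*Size bins.* Non-neutral segments fall in decade bins [1, 1000],
[1001, 10^4], [10^4+1, 10^5], …, with size = end − start + 1; every
non-neutral segment lands in exactly one bin.

## Mutational spectra

The 12 directional substitution classes are kept alongside the
6 pyrimidine-collapsed classes (purine references are
reverse-complemented together with their flanking context) and the 96
trinucleotide classes. Contexts come from a FASTA; calls at contig
edges, indels and ambiguous bases are excluded with a tally. Mutation
rate is `n/(target_bp/10^6)`. Group comparison builds, per collapsed
class, the 2×2 class-vs-rest table across groups: sample odds ratio
with Haldane–Anscombe 0.5 on zero cells, two-sided Fisher exact p. The
12-class fractions are ranked descending with mid-ranks. When paired
per-sample fractions are available a Wilcoxon signed-rank test pairs
the class-wise mean fractions; pairing by sample or by context bin is a
documented ambiguity and both inputs are accepted. Catalog similarity
uses Spearman correlation on the normalized 96-vector; a constant
vector yields an undefined (NaN) correlation.

## Expression statistics

Fold-changes are computed on raw fluorescence (mean ratio), reported
with the signed convention (`fc = r` if r ≥ 1 else `−1/r`), so
`fc(A,B) = −fc(B,A)` away from 1. Tests are Welch t on log2 values by
default (pooled-variance switch provided). Storey q-values estimate π0
by a cubic smoother over `π0(λ) = #{p > λ}/(m(1−λ))`, λ = 0.05…0.95,
evaluated at the largest λ; estimates outside (0, 1], or small inputs
(m < 100), fall back to π0 = 1, where the procedure coincides with
Benjamini–Hochberg. Two-tier stratification is a median split with a
quantile buffer: cases whose mid-quantile rank lies within ± buffer of
0.5 are excluded (the buffer is taken around the split, not at the
extremes — a documented choice).

## Lesion integration

Genotype classes partition each fully observed gene/case pair:
mutated (any mutation with VAF strictly above 0.2) versus not, crossed
with monoallelic (CN below the canonical loss band) versus biallelic
(CN ∈ [1.9, 2.1]) and the UPD flag. CN values in the gaps (1.5–1.9,
above 2.1) are assigned to the nearest canonical band, split at 1.7.
GOF/LOF uses its own thresholds (CN > 2.2 / CN < 1.7 with VAF > 0.5);
the two VAF thresholds are deliberately kept independent. Cellular
prevalence assumes a single mutated copy:
`CCF = VAF·(ρ·CN + 2(1−ρ))/ρ`, clipped to [0, 1]; with CN = 2 and
ρ = 1 it reduces to 2·VAF. Co-occurrence reports the sample odds ratio
(0.5 correction on zero cells, NaN for constant flags) with the exact
hypergeometric two-sided p. The eight lesional categories follow fixed
gene rules; the epigenetic and DNA-damage-response sets are
user-supplied lists, and rearrangement evidence is consumed as a
per-case boolean, never inferred. All frequencies are mask-aware: a
case enters a denominator only where the platform was analyzed, and
percentages are rounded half-up at the requested precision.

## Prognostic index

Training extremes are OS > 800 days versus OS < 300 days, boundaries
exclusive; short survivors must have an observed event (an early
censoring time carries no outcome information). Each probe gets the
Cox partial-likelihood score statistic at β = 0 with Efron handling of
tied event times, vectorized over probes; the SAM-style regularized
score is `d = r/(s + s0)` with s0 the percentile of {s} minimizing the
coefficient of variation of the window-wise MAD of d across ten
s-quantile windows (median fallback). The null distribution permutes
survival records against expression columns. The FDR at a cutoff is
the expected null call count over permutations divided by the observed
count (the standard E[V]/R plug-in), monotonized along the cutoff
grid; the median-count variant is available but collapses to zero in
deep tails at these problem sizes and is therefore not the default.
Training refinement fits OLS of OS on the called probes over
event-observed training cases and removes the single worst-residual
case when its observed OS is below 200 days, then re-runs the scoring.
The final per-case index is the overall-plus-column effect of a Tukey
median polish over the selected probe submatrix (probes as rows;
missing values mean-imputed per probe beforehand). The polish
maintains `matrix = overall + row + col + residual` exactly at every
sweep. Evaluation uses lifelines' Kaplan–Meier fits and the two-group
log-rank test.

## ZIP synergy

Normalization offers the screen's stated formula
`100·(neg − well)/(pos + neg)` ("as-printed") and the conventional
span form `100·(neg − well)/(neg − pos)`; the printed sum-denominator
is likely a transcription slip, so the span form — under which percent
inhibition is a fraction of the control window and the ZIP algebra is
exact — is the default for delta computation, with the mode recorded
in every output. Monotherapy wells are fit with the four-parameter
logistic `y = emin + (emax−emin)/(1+(EC50/x)^slope)` (multi-start over
slope {0.5, 1, 2, 4}, EC50 at the geometric median dose, bounds
emin ∈ [−20, 50], emax ∈ [0, 120], slope ∈ (0, 10]). The
zero-interaction surface combines the fitted fractions as
`y_zip = y_a + y_b − y_a·y_b`; per-well delta is
`100·(y_obs − y_zip)` with observed fractions clipped to [0, 1], and
the low-dose summary averages wells with both concentrations in
[1, 300] nM inclusive (the mean, not the maximum, is used for
ranking). Ranking assigns within-case ascending ranks (highest delta =
rank k, mid-ranks on ties); rank-sums always total n·k(k+1)/2. The
Friedman test uses scipy's tie-corrected implementation; pairwise
comparisons are two-sided Wilcoxon signed-rank tests.

## Synthetic cohort

The generator emulates the platform structure of the study cohort at
desk scale — 83 array cases, of which the first 54 carry exome calls,
70 expression profiles and 13 drug screens — with every record traced
to a truth entry. Defaults, chosen once as the study conditions:

| knob | default | rationale |
|---|---|---|
| burden | 70 calls/case | ≈ 1.1 Mut/Mb over a 64 Mb target |
| depth | Poisson(80) | exome-typical coverage |
| clonal / subclonal VAF | 0.35 / 0.12 | sorted tumors, single-copy events |
| purity | U[0.9, 1.0] | highly sorted samples; keeps CCF near-identity |
| oxo artifact rate | 0.15 | visible oxidative contamination |
| C:G>A:T class fraction | 0.35 | oxidative excess over the 0.2 background |
| survival probes | 3 of 500, loading ±1.5 log2/SD | planted-recovery scenario |
| survival | Exp(1/700 d) · e^(1.2·u), uniform censoring | closed-form recoverable |
| plates | 13 cases × 6 combos, 7 doses 1–1000 nM | screen geometry |
| Hill emax | 0.6 | keeps a +10-point shift unclipped |

Alternate read counts are binomial; artifact calls concentrate
alternate reads on the damage orientation (0.98) so FoxoG ≈ 1, carry
low tumor loads (U[3, 12]) and low VAFs, and therefore fail the oxo
line, while genuine calls (TLOD U[20, 90]) pass it. CN states are
gene-run based; a planted common deletion is deleted exactly (zero
extension) by its first affected case and extended by up to three
genes in the others, with random runs excluded from the span plus that
margin — this guarantees the flanking frequency stays strictly below
the planted frequency, making exact minimal-region recovery a property
of the construction rather than of chance. All randomness flows from
one seed through substreams keyed by stable labels (SHA-256 of the
label), so adding an output never shifts another and equal configs
yield byte-identical files.

*What passing tests do not show.* The generator has no germline
contamination structure, no marker-level segmentation noise, no probe
cross-hybridization, batch or GC effects, no inter-gene mutation-rate
covariates, and exponential (proportional-hazards-exact) survival;
real-data performance of the filter thresholds, the FDR calibration
and the index training is therefore not established by these tests —
only the correctness of the procedures under their stated models.

## Numerical conventions

Coordinates are 1-based inclusive throughout (BED input converted on
read). Percentages round half-up at the printed precision. Median
polish iterates to tol 1e-6 or 100 sweeps. Hill fits use tightened
least-squares tolerances (1e-13) so noiseless round-trips recover
parameters to ~1e-6 or better. Analysis problem sizes (cohort of 83
cases, 1000 genes, 500 probes; 100 permutations; 50-replicate
recovery suites) are the package's chosen desk-scale defaults.
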