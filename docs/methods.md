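# Methods

## Model and procedure

The pipeline implements two-bulk QTL-seq. A segregating population is
phenotyped for a bounded rate trait (haploid induction rate, HIR, in
percent); the k highest and k lowest lines are pooled into a high and a low
bulk and each pool is sequenced. At every biallelic SNP the SNP-index of a
bulk is the alternative-allele read fraction k/n, and the ΔSNP-index is
index(high) − index(low). Near a locus whose alternative allele raises the
trait, selection drives the high bulk towards that allele and the low bulk
away from it, so the ΔSNP-index rises above its null fluctuation; elsewhere
it is centred on 0. Windowed means of the per-site values are compared with
simulated null confidence bands and runs of significant windows are reported
as QTL intervals. Individual-line marker validation is single-marker OLS of
the trait on allele dosage.

Sign convention: Δ = high − low, so trait-enriching alleles produce
*positive* peaks; interval calling is one-sided high by default and a
two-sided mode also reports negative-side intervals.

## Filters

Two per-site filters precede windowing, applied in a fixed order so audit
counts are unambiguous (first failure wins, one reason code per site):

1. **LOW_DEPTH** — total depth < `min_depth` (default 7) in *either* bulk.
   The read-support rule is read as per-bulk support.
2. **LOW_INDEX_BOTH** — SNP-index < `low_index` (default 0.3) in *both*
   bulks. Sites low in both bulks are likely sequencing/alignment artifacts;
   a site low in only one bulk is precisely the signal being sought and is
   kept. The stricter either-bulk reading is available as
   `low_index_mode="either"` because published descriptions of this rule are
   ambiguous.

PASS + exclusion counts always sum to the input site count, and the run
manifest records each stage's tally.

## Sliding windows and interval calling

Windows are 1 Mb wide advancing in 100 kb steps (both configurable),
anchored at position 1, with 1-based inclusive coordinates; a site exactly at
a window end is inside. Full windows are enumerated while they fit; one final
end-clipped window is appended when needed so every bp is covered, and a
chromosome shorter than the window yields a single spanning window. Window
means are unweighted arithmetic means over PASS sites; empty windows are
reported with undefined means and are never significant.

Significant windows (mean Δ above the 99% — or 95% — upper band) merge into
intervals when consecutive; a gap of more than `max_gap_windows`
non-significant windows splits intervals (default 0: any gap splits).
Interval span in Mb is (end − start)/10⁶ rounded **half-up** to 2 decimals.
The peak is the window with the largest |mean Δ|.

## Null confidence bands

The null ΔSNP-index distribution is simulated with a two-stage sampling
model per depth:

1. each bulk independently pools `bulk_size` individuals (default 30) with
   F2-like genotype dosages ~ Binomial(2, ½), giving pool frequency
   p = Σdosage/(2N);
2. alt reads ~ Binomial(depth, p); index = alt/depth; Δ = index_H − index_L.

The exact variance, used as a test oracle, is
Var(Δ) = 2·[p̄(1−p̄)/depth + Var(p)(1 − 1/depth)] with p̄ = ½ and
Var(p) = 1/(8N). Bands are two-sided empirical quantiles
((1±level)/2) over 100,000 replicates per grid depth, type-7 (linear
interpolation) quantiles so results are reproducible across implementations.
A monotone post-pass (running min of the upper bound, running max of the
lower, in increasing depth) removes Monte-Carlo wiggle so band width is
non-increasing in depth. Bands are tabulated on a depth grid and linearly
interpolated at each window's mean depth; a depth outside the grid by more
than 2× is an error rather than an extrapolation. Window-level significance
reuses the site-level band evaluated at the window's mean depth — a
pragmatic approximation (a mean over sites has smaller dispersion than one
site, making calls conservative) rather than a window-specific null.

Because read counts are discrete, the empirical 99.5% quantile sits on an
atom with at most 0.5% mass beyond it on each side; the realised exceedance
rate of the 99% band is therefore slightly *below* 1% — conservative, and
visible in the calibration checks.

## Synthetic population generator

The generator reproduces the statistical structure of an S2-like maize
haploid-inducer mapping population. Defaults are the study conditions the
analysis targets:

| parameter | default | meaning |
|---|---|---|
| `population_size` | 337 | segregating lines |
| `bulk_size` | 30 | lines per extreme bulk |
| `chrom_lengths` | 2 × 50 Mb | desk-scale genome for minutes-scale runs |
| `marker_spacing` | 50 kb | distance between simulated SNPs |
| `cm_per_mb` | 1.0 | recombination rate; Haldane map r = (1−e^(−2d))/2 |
| `baseline_hir` | 6% | trait mean without QTL effects |
| `trait_sd` | 4% | residual (non-genetic) spread |
| `mean_bulk_depth` | 100× | Poisson read depth per bulk per site |
| `mean_parent_depth` | 10× | parental depth (metadata; parents optional) |
| `seq_error` | 0.001 | symmetric per-read allele flip probability |

Genotypes: each line is the sum of two independent F1 gametes per
chromosome; a gamete is a Markov haplotype whose switch probability between
adjacent sites is the Haldane recombination fraction; chromosomes assort
freely. This models the S2-from-intercrossed-S1-groups pedigree as F2-like
Mendelian segregation — the published pedigree detail is insufficient for an
exact S2 model, and the F2 approximation preserves the two properties the
statistics rely on (1:2:1 segregation, map-distance-decaying linkage).

Trait: HIR = clamp(baseline + Σ effect·(dosage−1) + N(0, sd), 0, 100).
Clamping at 0 produces the left-skew pile-up of low-rate lines seen in real
inducer populations. Planted QTLs snap to the nearest simulated site and are
written, with realised bulk allele frequencies and bulk membership, to a
truth JSON for recovery scoring.

Reads: per bulk and site, depth ~ Poisson(mean depth) and alt reads ~
Binomial(depth, p(1−e) + (1−p)e) with p the pool allele frequency.

What the generator does *not* emulate: alignment and variant-calling
artifacts (mapping bias, paralogy, indel realignment), non-biallelic sites,
depth overdispersion beyond Poisson, genotyping error in the lines, shared
ancestry structure beyond a single F2-like cross, and field/phenotyping
error beyond Gaussian noise. Passing calibration and recovery tests
therefore demonstrates the statistical chain is correct under its own
assumptions, not that real sequencing data will be this clean.

A calibration note: the genome-wide mean ΔSNP-index under the null is
unbiased, but its seed-to-seed spread is governed by the number of
independent linkage segments, not the number of sites (bulk composition is
shared along a chromosome). Bias tests therefore average over seeds and use
many-chromosome layouts; single-run genome means of ±0.05 are ordinary for a
two-chromosome genome.

## Marker–trait association

Genotype classes come from biallelic calls (e.g. KASP assays) encoded as
additive dosage 0/1/2 — the coding that yields a single R² per marker, as in
standard marker-validation tables; a class-factor alternative was considered
and rejected as the default because the published analyses report one R² per
marker from a simple regression. Missing genotypes are dropped pairwise per
marker, not listwise, so each marker keeps its own n. R² equals the squared
Pearson correlation; PVE = 100·R²; p-values are unadjusted (a
Benjamini–Hochberg helper exists but is off by default, matching common
practice for a handful of validation markers). Candidate screening keeps
markers with R² strictly greater than the threshold (default 0.3). Two-marker
joint classes are summarised on a 3×3 grid with a Welch t comparison between
the two homozygous-extreme joint classes, reported descriptively; the
favourable homozygote at each marker is the one with the higher marginal
class mean.

Degenerate inputs: constant dosage is an error (`CONSTANT_GENOTYPE`);
constant phenotype returns R² = 0 with a warning; fewer than 3 complete
pairs is an error; a zero seed set is an error naming the line (no
imputation). Extreme-bulk ties are broken by (HIR, line id) with the low
bulk drawn from lines remaining after the high bulk is filled, so the bulks
are always disjoint and selection is reproducible.

## Problem sizes used in the test and acceptance runs

The packaged checks run the full chain at desk scale: a 2 × 50 Mb genome
with sites every 50 kb (2,000 sites), 337 lines, 30+30 bulks, ~100× depth,
100,000 null replicates per grid depth; calibration averages 5 seeded runs
and recovery scores 50 seeded runs. These sizes keep the whole suite in the
low tens of seconds while leaving every stage statistically meaningful
(≈2,000 PASS sites per run, ≈1,000 windows).

## Known limitations

- The window-level significance approximation (site-level band at mean
  depth) is conservative; a per-window null would sharpen power.
- Only the F2-like generation model is implemented; RIL/backcross nulls
  would need a different dosage distribution in both the generator and the
  band simulation (the sampling stage is shared, so the extension point is
  the dosage draw).
- Indels are counted and reportable but excluded from the index statistics
  by default.
- The CLI's `qtlseq` plot is cosmetic; no numbers are derived from figures.
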