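# bsaqtl

Bulked-segregant QTL-seq analysis for quantitative traits, built around the
maize haploid-induction-rate (HIR) mapping design: a segregating biparental
population is phenotyped, the extreme tails are pooled into a high and a low
DNA bulk, both bulks are whole-genome sequenced, and loci linked to the trait
reveal themselves as allele-frequency skews between the bulks.

## Who this is for

Plant geneticists and breeders running bulked-segregant analysis (BSA) from a
two-sample VCF with allele depths, and method developers who need a fully
synthetic, ground-truthed BSA data generator to calibrate or benchmark
sliding-window allele-frequency statistics.

## The statistic

At each biallelic site, the **SNP-index** of a bulk is the fraction of reads
carrying the non-reference allele,

```
SNP-index = k / n
```

with *k* the alternative-allele read count and *n* the total depth. The
**ΔSNP-index** is

```
ΔSNP-index = SNP-index(high bulk) − SNP-index(low bulk)
```

Under no linkage to the trait it fluctuates around 0; near a locus enriched
in the high bulk it rises towards +1. Sites with depth < 7 in either bulk, or
with SNP-index < 0.3 in *both* bulks (likely spurious calls), are excluded.
Per-site values are averaged in sliding windows (1 Mb wide, 100 kb steps) and
compared with Monte-Carlo 95%/99% confidence bands simulated under the null:
each bulk pools N individuals with F2-like Binomial(2, ½) genotypes, then the
sequencer draws Binomial(depth, p) reads from the pool. Runs of windows whose
mean ΔSNP-index exceeds the 99% band merge into QTL intervals.

Marker–trait association on individual lines is simple OLS regression of the
trait on allele dosage (0/1/2), reporting R², the slope's two-sided p-value
(t, n−2 df), and PVE = 100·R², plus per-genotype-class trait summaries.

The haploid induction rate itself is
`HIR (%) = 100 × haploid seeds / (haploid + diploid + unmarked seeds)`.

## Worked example

Simulate a 337-line population with one planted QTL (additive effect 8% HIR
at chr1:25 Mb), select 30+30 extreme bulks, sequence them at ~100×, and scan:

```
bsaqtl simulate --outdir demo/sim --seed 7 --qtl chr1:25000000:8
bsaqtl qtlseq --vcf demo/sim/bulks.vcf --chrom-sizes demo/sim/chrom_sizes.tsv \
              --outdir demo/run --seed 7
```

which prints

```
1 interval(s) -> demo/run/intervals.tsv
```

and `demo/run/intervals.tsv` contains

```
chrom	start	end	span_mb	peak_delta	peak_pos	n_sites	ci_level
chr1	1	50000000	50.00	0.842349	25800000	20	0.99
```

The called 99%-level interval sits on the simulated chromosome 1 and its peak
ΔSNP-index (0.84 at 25.8 Mb) lands next to the planted QTL at 25 Mb — with a
single strong QTL on a 50 Mb chromosome, linkage keeps the whole chromosome
above the null band, hence the broad interval. `demo/run/manifest.json`
records the seed, parameters, and per-stage filter counts; `sites.tsv` and
`windows.tsv` hold the per-site and per-window statistics with the attached
confidence bands.

The same analysis is available as estimator classes:

```python
import bsaqtl as b

sim = b.simulate_population(b.SimConfig(planted_qtls=(("chr1", 25_000_000, 8.0),), seed=7))
scan = b.QtlSeqScan().fit(sim.counts, sim.config.chrom_lengths)
scan.intervals_          # called QTL intervals
scan.filter_counts_      # {'PASS': ..., 'LOW_DEPTH': ..., ...}

reg = b.MarkerTraitRegression().fit(dosage.reshape(-1, 1), hir)
reg.r_squared_, reg.p_value_, reg.pve_
```

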