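"""Synthetic bulked-segregant population generator.

Emulates the experimental design the analysis assumes: a biparental
intercross population (S2-like, modelled as F2 Mendelian segregation with
Haldane-map recombination along chromosomes and free recombination between
them), a 0–100%-bounded quantitative trait with planted additive QTLs and a
left-skew from clamping at 0, selection of phenotypic extremes into two
bulks, and Poisson–binomial read sampling per bulk. A ground-truth record
accompanies every simulation so interval-recovery tests can be scored.

The defaults mirror the study design the statistics target: 337 lines,
30+30 extreme bulks, ~100x bulk depth, ~10x parental depth, a baseline
trait mean of 6% with 4% residual spread (which, clamped at 0, reproduces
the characteristic pile-up of low-rate lines).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .phenotype import PhenotypeRecord, select_extreme_bulks, write_phenotypes
from .variant_io import AlleleCountTable, VariantSite


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic bulked-segregant experiment.

    ``planted_qtls`` lists (chrom, pos-bp, additive effect in trait %):
    each QTL adds ``effect * (dosage - 1)`` so heterozygotes sit at the
    baseline and the two homozygotes at ±effect.
    """

    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 50_000_000), ("chr2", 50_000_000))
    marker_spacing: int = 50_000
    cm_per_mb: float = 1.0
    population_size: int = 337
    bulk_size: int = 30
    planted_qtls: tuple[tuple[str, int, float], ...] = ()
    baseline_hir: float = 6.0
    trait_sd: float = 4.0
    mean_bulk_depth: float = 100.0
    mean_parent_depth: float = 10.0
    seq_error: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 1 <= self.bulk_size <= self.population_size // 2:
            raise ValueError(
                f"bulk_size must satisfy 1 <= bulk_size <= population_size/2, "
                f"got {self.bulk_size} of {self.population_size}"
            )
        if self.mean_bulk_depth <= 0 or self.mean_parent_depth <= 0:
            raise ValueError("mean depths must be positive")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must lie in [0, 0.5)")
        if self.marker_spacing < 1:
            raise ValueError("marker_spacing must be >= 1")
        if self.cm_per_mb < 0:
            raise ValueError("cm_per_mb must be non-negative")
        chroms = {c for c, _ in self.chrom_lengths}
        lengths = dict(self.chrom_lengths)
        for chrom, pos, effect in self.planted_qtls:
            if chrom not in chroms:
                raise ValueError(f"planted QTL on unknown chromosome {chrom!r}")
            if not 1 <= pos <= lengths[chrom]:
                raise ValueError(f"planted QTL position {pos} outside {chrom}")
            if not np.isfinite(effect):
                raise ValueError("planted QTL effects must be finite")


def site_positions(config: SimConfig) -> list[tuple[str, np.ndarray]]:
    """Variant-site coordinates: every ``marker_spacing`` bp per chromosome."""
    out = []
    for chrom, length in config.chrom_lengths:
        pos = np.arange(config.marker_spacing, length + 1, config.marker_spacing, dtype=np.int64)
        out.append((chrom, pos))
    return out


def _haldane_recomb_fraction(dist_bp: np.ndarray, cm_per_mb: float) -> np.ndarray:
    """Haldane map: r = (1 - exp(-2d)) / 2 with d in Morgans."""
    morgans = dist_bp * cm_per_mb / 1e6 / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def _simulate_gametes(
    n_gametes: int, positions: np.ndarray, cm_per_mb: float, rng: np.random.Generator
) -> np.ndarray:
    """Haplotypes (0/1) from an F1 parent: Markov switching along the map."""
    n_sites = len(positions)
    hap = np.empty((n_gametes, n_sites), dtype=np.int8)
    hap[:, 0] = rng.integers(0, 2, size=n_gametes)
    if n_sites > 1:
        r = _haldane_recomb_fraction(np.diff(positions).astype(float), cm_per_mb)
        switches = rng.random((n_gametes, n_sites - 1)) < r
        parity = np.cumsum(switches, axis=1) & 1
        hap[:, 1:] = hap[:, :1] ^ parity.astype(np.int8)
    return hap


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[tuple[str, np.ndarray]]]:
    """Line-by-site dosage matrix (values 0/1/2) for the whole population.

    Each line is the sum of two independent F1 gametes per chromosome, so
    every site segregates 1:2:1 (expected alt-allele frequency 0.5) and
    linkage decays with the Haldane recombination fraction; chromosomes are
    independent.
    """
    rng = rng or np.random.default_rng(config.seed)
    sites = site_positions(config)
    blocks = []
    for _, positions in sites:
        g1 = _simulate_gametes(config.population_size, positions, config.cm_per_mb, rng)
        g2 = _simulate_gametes(config.population_size, positions, config.cm_per_mb, rng)
        blocks.append((g1 + g2).astype(np.int8))
    return np.concatenate(blocks, axis=1), sites


def _qtl_site_indices(
    config: SimConfig, sites: Sequence[tuple[str, np.ndarray]]
) -> list[tuple[int, float, str, int]]:
    """Map each planted QTL to the nearest simulated site (global column index)."""
    offsets = {}
    offset = 0
    for chrom, positions in sites:
        offsets[chrom] = (offset, positions)
        offset += len(positions)
    out = []
    for chrom, pos, effect in config.planted_qtls:
        base, positions = offsets[chrom]
        j = int(np.argmin(np.abs(positions - pos)))
        out.append((base + j, effect, chrom, int(positions[j])))
    return out


def simulate_trait(
    genotypes: np.ndarray,
    config: SimConfig,
    sites: Sequence[tuple[str, np.ndarray]],
    rng: np.random.Generator | None = None,
) -> list[PhenotypeRecord]:
    """Bounded trait values per line.

    trait = clamp(baseline + Σ effect_q (dosage_q − 1) + N(0, sd), 0, 100).
    With a low baseline relative to the spread, clamping at 0 produces the
    left-skew pile-up typical of induction-rate distributions.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = genotypes.shape[0]
    trait = np.full(n, config.baseline_hir, dtype=float)
    for col, effect, _, _ in _qtl_site_indices(config, sites):
        trait += effect * (genotypes[:, col] - 1.0)
    if config.trait_sd > 0:
        trait += rng.normal(0.0, config.trait_sd, size=n)
    trait = np.clip(trait, 0.0, 100.0)
    width = len(str(n))
    return [PhenotypeRecord(line_id=f"L{i:0{width}d}", hir=float(trait[i])) for i in range(n)]


def simulate_bulk_reads(
    genotypes_high: np.ndarray,
    genotypes_low: np.ndarray,
    config: SimConfig,
    sites: Sequence[tuple[str, np.ndarray]],
    rng: np.random.Generator | None = None,
) -> tuple[AlleleCountTable, np.ndarray, np.ndarray]:
    """Sequence the two bulks: Poisson depth, binomial allele sampling.

    Per site and bulk, the pool allele frequency is mean(dosage)/2; a read
    reports the wrong allele with probability ``seq_error`` (symmetric
    flip), so the observed alt probability is p(1−e) + (1−p)e.

    Returns the allele-count table plus the realized (error-free) bulk
    allele frequencies, which go into the truth record.
    """
    if genotypes_high.shape[0] == 0 or genotypes_low.shape[0] == 0:
        raise ValueError("both bulks must be non-empty")
    rng = rng or np.random.default_rng(config.seed + 2)
    p_h = genotypes_high.mean(axis=0) / 2.0
    p_l = genotypes_low.mean(axis=0) / 2.0
    e = config.seq_error

    def draw(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        depth = rng.poisson(config.mean_bulk_depth, size=p.shape)
        p_obs = p * (1 - e) + (1 - p) * e
        alt = rng.binomial(depth, p_obs)
        return depth - alt, alt

    ref_h, alt_h = draw(p_h)
    ref_l, alt_l = draw(p_l)

    bases = ("A", "C", "G", "T")
    records: list[VariantSite] = []
    j = 0
    for chrom, positions in sites:
        for pos in positions:
            ref = bases[j % 4]
            alt = bases[(j + 1) % 4]
            records.append(
                VariantSite(
                    chrom=chrom,
                    pos=int(pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    ref_H=int(ref_h[j]),
                    alt_H=int(alt_h[j]),
                    ref_L=int(ref_l[j]),
                    alt_L=int(alt_l[j]),
                )
            )
            j += 1
    table = AlleleCountTable(sites=records, source="simulation")
    return table, p_h, p_l


@dataclass
class BsaSimulation:
    """One complete synthetic experiment with its ground truth."""

    config: SimConfig
    genotypes: np.ndarray
    sites: list[tuple[str, np.ndarray]]
    phenotypes: list[PhenotypeRecord]
    high_ids: list[str]
    low_ids: list[str]
    counts: AlleleCountTable
    truth: dict = field(default_factory=dict)

    @property
    def line_index(self) -> dict[str, int]:
        return {p.line_id: i for i, p in enumerate(self.phenotypes)}


def simulate_population(config: SimConfig) -> BsaSimulation:
    """Run the full generator: genotypes → trait → bulks → reads → truth.

    All randomness flows from one generator seeded with ``config.seed``;
    bulk selection reuses the deterministic phenotype-module tie-break.
    """
    rng = np.random.default_rng(config.seed)
    genotypes, sites = simulate_genotypes(config, rng)
    phenotypes = simulate_trait(genotypes, config, sites, rng)
    high_ids, low_ids = select_extreme_bulks(phenotypes, config.bulk_size)
    idx = {p.line_id: i for i, p in enumerate(phenotypes)}
    g_high = genotypes[[idx[i] for i in high_ids]]
    g_low = genotypes[[idx[i] for i in low_ids]]
    counts, p_h, p_l = simulate_bulk_reads(g_high, g_low, config, sites, rng)

    qtl_truth = [
        {"chrom": chrom, "pos": pos_used, "effect": effect, "site_column": col}
        for col, effect, chrom, pos_used in _qtl_site_indices(config, sites)
    ]
    truth = {
        "seed": config.seed,
        "planted_qtls": qtl_truth,
        "high_bulk": high_ids,
        "low_bulk": low_ids,
        "bulk_allele_freq_high": [round(float(x), 6) for x in p_h],
        "bulk_allele_freq_low": [round(float(x), 6) for x in p_l],
    }
    return BsaSimulation(
        config=config,
        genotypes=genotypes,
        sites=sites,
        phenotypes=phenotypes,
        high_ids=high_ids,
        low_ids=low_ids,
        counts=counts,
        truth=truth,
    )


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=bsaqtl-simulate
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_simulation(sim: BsaSimulation, outdir: str | Path) -> dict[str, Path]:
    """Write VCF, chromosome sizes, phenotype TSV, and truth JSON.

    Deterministic given the simulation (byte-identical for equal seeds).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "bulks.vcf",
        "chrom_sizes": outdir / "chrom_sizes.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.json",
    }

    with open(paths["vcf"], "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        for chrom, length in sim.config.chrom_lengths:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tHIGH_BULK\tLOW_BULK\n")
        for s in sim.counts:
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\tPASS\t.\t"
                f"AD:DP\t{s.ref_H},{s.alt_H}:{s.depth_H}\t{s.ref_L},{s.alt_L}:{s.depth_L}\n"
            )

    with open(paths["chrom_sizes"], "w", encoding="utf-8") as fh:
        for chrom, length in sim.config.chrom_lengths:
            fh.write(f"{chrom}\t{length}\n")

    write_phenotypes(sim.phenotypes, paths["phenotypes"])

    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(sim.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
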