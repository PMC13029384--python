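"""End-to-end orchestration of the QTL-seq stages with a run manifest.

``run_qtlseq`` executes read → filter → index → windows → CI → intervals and
writes sites.tsv, windows.tsv, intervals.tsv plus a machine-readable
manifest (parameters, seed, per-stage counts). ``run_association`` fits
every marker in a genotype table against the phenotype table and writes
association.tsv. Both are thin layers over the estimator classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .association import (
    class_summary,
    fit_simple_regression,
    genotype_class,
    read_genotypes,
)
from .estimators import QtlSeqScan
from .phenotype import read_phenotypes
from .variant_io import read_chrom_sizes, read_vcf_bulks, write_table

logger = logging.getLogger(__name__)


@dataclass
class QtlSeqConfig:
    """Inputs and knobs of one QTL-seq run."""

    vcf: str
    chrom_sizes: str
    outdir: str
    high_sample: str = "HIGH_BULK"
    low_sample: str = "LOW_BULK"
    min_depth: int = 7
    low_index: float = 0.3
    low_index_mode: str = "both"
    window_bp: int = 1_000_000
    step_bp: int = 100_000
    bulk_size: int = 30
    replicates: int = 100_000
    level: float = 0.99
    max_gap_windows: int = 0
    two_sided: bool = False
    seed: int = 0
    ci_cache: str | None = None
    depth_grid: list[int] | None = field(default=None)


def run_qtlseq(config: QtlSeqConfig) -> dict:
    """Run the full scan and write sites/windows/intervals + manifest.

    Returns the manifest dict. Filter-stage counts in the manifest always
    reconcile: input sites = PASS + each exclusion reason.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage read: %s", config.vcf)
    table = read_vcf_bulks(config.vcf, config.high_sample, config.low_sample)
    chrom_lengths = read_chrom_sizes(config.chrom_sizes)
    logger.info(
        "read %d sites (%d multiallelic skipped, %d missing-AD skipped, %d indels)",
        len(table), table.n_skipped_multiallelic, table.n_skipped_missing_ad, table.n_indels,
    )

    scan = QtlSeqScan(
        min_depth=config.min_depth,
        low_index=config.low_index,
        low_index_mode=config.low_index_mode,
        window_bp=config.window_bp,
        step_bp=config.step_bp,
        bulk_size=config.bulk_size,
        replicates=config.replicates,
        depth_grid=config.depth_grid,
        level=config.level,
        max_gap_windows=config.max_gap_windows,
        two_sided=config.two_sided,
        random_state=config.seed,
    )
    ci = None
    if config.ci_cache and Path(config.ci_cache).exists():
        from .null_ci import NullCiTable

        ci = NullCiTable.from_tsv(config.ci_cache)
        logger.info("stage ci: reusing cached table %s", config.ci_cache)
    scan.fit(table, chrom_lengths, ci_table=ci)
    if config.ci_cache and ci is None:
        scan.ci_table_.to_tsv(config.ci_cache)
    logger.info("stage filter: %s", scan.filter_counts_)
    logger.info("stage intervals: %d called at level %.2f", len(scan.intervals_), config.level)

    comments = [f"bsaqtl {__version__}", f"seed={config.seed}"]
    write_table(scan.records_, outdir / "sites.tsv", "snp_index", comments)
    write_table(scan.windows_, outdir / "windows.tsv", "window", comments)
    write_table(scan.intervals_, outdir / "intervals.tsv", "interval", comments)

    manifest = {
        "tool": "bsaqtl",
        "version": __version__,
        "command": "qtlseq",
        "parameters": asdict(config),
        "counts": {
            "input_sites": len(table),
            "skipped_multiallelic": table.n_skipped_multiallelic,
            "skipped_missing_ad": table.n_skipped_missing_ad,
            "indels": table.n_indels,
            "filters": scan.filter_counts_,
            "windows": len(scan.windows_),
            "intervals": len(scan.intervals_),
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


@dataclass
class AssociationConfig:
    genotypes: str
    phenotypes: str
    outdir: str
    r2_threshold: float = 0.3
    seed: int = 0


def run_association(config: AssociationConfig) -> dict:
    """Fit every marker against the trait and write association.tsv.

    Ref/alt per marker are taken as the lexicographically first/second
    allele observed at that marker (KASP tables do not orient alleles);
    R², p and PVE are invariant to that orientation.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls = read_genotypes(config.genotypes)
    phenos = {p.line_id: p.hir for p in read_phenotypes(config.phenotypes)}
    by_marker: dict[str, list] = {}
    for c in calls:
        by_marker.setdefault(c.marker_id, []).append(c)
    if not any(c.line_id in phenos for c in calls):
        raise ValueError("genotype and phenotype tables share no line ids")

    results = []
    summaries = {}
    for marker_id, marker_calls in sorted(by_marker.items()):
        alleles = sorted(
            {a for c in marker_calls for a in (c.allele1, c.allele2) if a is not None}
        )
        if len(alleles) != 2:
            logger.warning("marker %s is not biallelic in the data; skipped", marker_id)
            continue
        ref, alt = alleles
        dosage, hir = [], []
        for c in marker_calls:
            if c.line_id not in phenos:
                continue
            cls = genotype_class(c, ref, alt)
            dosage.append(None if cls == "missing" else ("AA", "AB", "BB").index(cls))
            hir.append(phenos[c.line_id])
        res = fit_simple_regression(dosage, hir, marker_id=marker_id)
        results.append(res)
        summaries[marker_id] = class_summary(marker_calls, phenos, ref, alt)
        logger.info("marker %s: n=%d R2=%.3f p=%.3g", marker_id, res.n, res.r_squared, res.p_value)

    write_table(results, outdir / "association.tsv", "association", [f"seed={config.seed}"])
    manifest = {
        "tool": "bsaqtl",
        "version": __version__,
        "command": "associate",
        "parameters": asdict(config),
        "counts": {"markers": len(results)},
        "class_summaries": {
            m: [asdict(s) for s in ss] for m, ss in summaries.items()
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def plot_scan(windows, path, title: str = "") -> None:
    """Three-panel per-chromosome plot of index_H, index_L and Δ with bands.

    Cosmetic convenience only; no statistics are read from the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({w.chrom for w in windows})
    fig, axes = plt.subplots(3, len(chroms), figsize=(4 * len(chroms), 7), squeeze=False)
    for j, chrom in enumerate(chroms):
        ws = sorted((w for w in windows if w.chrom == chrom and w.n_sites > 0), key=lambda w: w.start)
        x = [w.midpoint / 1e6 for w in ws]
        for i, attr in enumerate(("mean_index_H", "mean_index_L", "mean_delta")):
            ax = axes[i][j]
            ax.plot(x, [getattr(w, attr) for w in ws], lw=0.8, color="k")
            if attr == "mean_delta":
                ax.plot(x, [w.ci95_hi for w in ws], lw=0.6, color="tab:blue")
                ax.plot(x, [w.ci95_lo for w in ws], lw=0.6, color="tab:blue")
                ax.plot(x, [w.ci99_hi for w in ws], lw=0.6, color="tab:red")
                ax.plot(x, [w.ci99_lo for w in ws], lw=0.6, color="tab:red")
                ax.axhline(0, lw=0.4, color="grey")
            ax.set_xlabel(f"{chrom} (Mb)")
            ax.set_ylabel(attr)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
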