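"""Read/write the variant-level data the pipeline consumes.

Bulk allele depths come from a VCF with per-sample AD (ref,alt read counts);
chromosome sizes from a two-column TSV; statistic outputs go to TSV with a
named schema. Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from cyvcf2 import VCF

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantSite:
    """One biallelic site with per-bulk ref/alt read counts."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    ref_H: int
    alt_H: int
    ref_L: int
    alt_L: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("ref_H", "alt_H", "ref_L", "alt_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative at {self.chrom}:{self.pos}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def depth_H(self) -> int:
        return self.ref_H + self.alt_H

    @property
    def depth_L(self) -> int:
        return self.ref_L + self.alt_L


@dataclass
class AlleleCountTable:
    """Ordered collection of variant sites plus provenance metadata.

    Sites are kept sorted by (chromosome, position) with chromosomes
    contiguous in first-appearance order, and deduplicated.
    """

    sites: list[VariantSite]
    high_label: str = "HIGH_BULK"
    low_label: str = "LOW_BULK"
    source: str | None = None
    reference: str | None = None
    n_skipped_multiallelic: int = 0
    n_skipped_missing_ad: int = 0
    n_indels: int = 0
    chrom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chrom_order:
            seen: dict[str, None] = {}
            for s in self.sites:
                seen.setdefault(s.chrom, None)
            self.chrom_order = list(seen)
        self._sort_dedup()

    def _sort_dedup(self) -> None:
        rank = {c: i for i, c in enumerate(self.chrom_order)}
        self.sites.sort(key=lambda s: (rank.get(s.chrom, len(rank)), s.chrom, s.pos))
        deduped: list[VariantSite] = []
        last: tuple[str, int] | None = None
        for s in self.sites:
            key = (s.chrom, s.pos)
            if key == last:
                logger.warning("duplicate site %s:%d dropped (kept first)", s.chrom, s.pos)
                continue
            deduped.append(s)
            last = key
        self.sites = deduped

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


def read_vcf_bulks(
    path: str | Path,
    high_sample: str = "HIGH_BULK",
    low_sample: str = "LOW_BULK",
    include_indels: bool = False,
) -> AlleleCountTable:
    """Read per-bulk allele depths (FORMAT/AD) from a VCF.

    Multiallelic records are skipped with a counted warning, as are records
    with missing AD in either bulk. Indels are parsed but routed to a
    separate count and excluded from the site list unless
    ``include_indels=True``; the index statistics run on SNPs by default.
    Sites with zero depth are *retained* here and removed only by the filter
    stage, so filter counts stay auditable.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    for name in (high_sample, low_sample):
        if name not in samples:
            raise ValueError(
                f"sample {name!r} not found in {path}; available samples: {samples}"
            )
    ih = samples.index(high_sample)
    il = samples.index(low_sample)

    sites: list[VariantSite] = []
    chrom_order: dict[str, None] = {}
    n_multi = 0
    n_missing_ad = 0
    n_indels = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            n_missing_ad += 1
            continue
        ref_h, alt_h = int(ad[ih][0]), int(ad[ih][1])
        ref_l, alt_l = int(ad[il][0]), int(ad[il][1])
        if min(ref_h, alt_h, ref_l, alt_l) < 0:  # cyvcf2 encodes missing as negative
            n_missing_ad += 1
            continue
        site = VariantSite(
            chrom=rec.CHROM,
            pos=rec.POS,
            ref_allele=rec.REF,
            alt_allele=rec.ALT[0],
            ref_H=ref_h,
            alt_H=alt_h,
            ref_L=ref_l,
            alt_L=alt_l,
        )
        if not site.is_snp:
            n_indels += 1
            if not include_indels:
                continue
        chrom_order.setdefault(site.chrom, None)
        sites.append(site)
    vcf.close()
    if n_multi:
        logger.warning("%s: skipped %d multiallelic records", path, n_multi)
    if n_missing_ad:
        logger.warning("%s: skipped %d records with missing AD", path, n_missing_ad)
    return AlleleCountTable(
        sites=sites,
        high_label=high_sample,
        low_label=low_sample,
        source=path,
        n_skipped_multiallelic=n_multi,
        n_skipped_missing_ad=n_missing_ad,
        n_indels=n_indels,
        chrom_order=list(chrom_order),
    )


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    """Read a two-column (chromosome, length-bp) TSV, order preserved."""
    out: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            chrom, raw_len = parts
            try:
                length = int(raw_len)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer length {raw_len!r}") from exc
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: length must be positive, got {length}")
            if chrom in seen:
                raise ValueError(f"{path}:{lineno}: duplicated chromosome {chrom!r}")
            seen.add(chrom)
            out.append((chrom, length))
    return out


def aggregate_variant_counts(
    per_chrom_counts: Iterable[tuple[str, int, int]],
) -> tuple[int, int]:
    """Exact integer totals of per-chromosome (SNP, indel) counts."""
    total_snp = 0
    total_indel = 0
    for chrom, n_snp, n_indel in per_chrom_counts:
        if n_snp < 0 or n_indel < 0:
            raise ValueError(f"negative variant count for {chrom!r}")
        total_snp += int(n_snp)
        total_indel += int(n_indel)
    return total_snp, total_indel


# Output schemas: (column, format) pairs; attribute lookup falls back to dict access.
SCHEMAS: Mapping[str, Sequence[tuple[str, str]]] = {
    "snp_index": (
        ("chrom", "{}"),
        ("pos", "{:d}"),
        ("depth_H", "{:d}"),
        ("depth_L", "{:d}"),
        ("index_H", "{:.6f}"),
        ("index_L", "{:.6f}"),
        ("delta", "{:.6f}"),
        ("status", "{}"),
    ),
    "window": (
        ("chrom", "{}"),
        ("start", "{:d}"),
        ("end", "{:d}"),
        ("midpoint", "{:.1f}"),
        ("n_sites", "{:d}"),
        ("mean_index_H", "{:.6f}"),
        ("mean_index_L", "{:.6f}"),
        ("mean_delta", "{:.6f}"),
        ("mean_depth", "{:.2f}"),
        ("ci95_lo", "{:.6f}"),
        ("ci95_hi", "{:.6f}"),
        ("ci99_lo", "{:.6f}"),
        ("ci99_hi", "{:.6f}"),
        ("significant_95", "{}"),
        ("significant_99", "{}"),
    ),
    "interval": (
        ("chrom", "{}"),
        ("start", "{:d}"),
        ("end", "{:d}"),
        ("span_mb", "{:.2f}"),
        ("peak_delta", "{:.6f}"),
        ("peak_pos", "{:d}"),
        ("n_sites", "{:d}"),
        ("ci_level", "{:.2f}"),
    ),
    "association": (
        ("marker_id", "{}"),
        ("n", "{:d}"),
        ("slope", "{:.6f}"),
        ("intercept", "{:.6f}"),
        ("r_squared", "{:.6f}"),
        ("p_value", "{:.6g}"),
        ("pve", "{:.2f}"),
    ),
}


def _get(record, name):
    if hasattr(record, name):
        return getattr(record, name)
    return record[name]


def write_table(records: Iterable, path: str | Path, schema: str, header_comments: Sequence[str] = ()) -> None:
    """Write records to a tab-delimited file under a named schema.

    Missing/undefined numeric values (None or NaN) are rendered as ``NA``.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    columns = SCHEMAS[schema]
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(name for name, _ in columns) + "\n")
        for rec in records:
            cells = []
            for name, fmt in columns:
                value = _get(rec, name)
                if value is None or (isinstance(value, float) and value != value):
                    cells.append("NA")
                else:
                    cells.append(fmt.format(value))
            fh.write("\t".join(cells) + "\n")


def read_table(path: str | Path, schema: str):
    """Read back a TSV written by :func:`write_table` as a DataFrame."""
    import pandas as pd

    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
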