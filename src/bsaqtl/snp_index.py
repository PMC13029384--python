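"""Per-site SNP-index, filtering, and the ΔSNP-index.

The SNP-index of a bulk at a site is k/n: the fraction of reads carrying the
non-reference allele. The ΔSNP-index is the high bulk's index minus the low
bulk's index; under no-QTL segregation it is centred on 0, and near a locus
enriched in the high bulk it deviates towards +1.

Filters follow QTL-seq practice: sites with read depth below a minimum in
either bulk are excluded (default 7), and sites whose index is below a
threshold (default 0.3) in *both* bulks are excluded as likely spurious
calls from sequencing or alignment error. A site below 0.3 in only one bulk
is informative — that asymmetry is the signal — and is kept by default;
``low_index_mode="either"`` gives the stricter reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .variant_io import AlleleCountTable, VariantSite

PASS = "PASS"
LOW_DEPTH = "LOW_DEPTH"
LOW_INDEX_BOTH = "LOW_INDEX_BOTH"
LOW_INDEX_EITHER = "LOW_INDEX_EITHER"


def site_snp_index(alt_reads: int, total_reads: int) -> float:
    """SNP-index k/n at one site in one bulk: exact quotient in [0, 1]."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive; pre-filter zero-depth sites")
    if not 0 <= alt_reads <= total_reads:
        raise ValueError(f"alt_reads must lie in [0, total_reads], got {alt_reads}/{total_reads}")
    return alt_reads / total_reads


def delta_snp_index(index_H: float, index_L: float) -> float:
    """ΔSNP-index: high-bulk index minus low-bulk index, in [-1, 1]."""
    for v in (index_H, index_L):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"SNP-index must lie in [0, 1], got {v}")
    return index_H - index_L


@dataclass(frozen=True)
class SnpIndexRecord:
    """Per-site index statistics plus filter status.

    ``index_H``/``index_L``/``delta`` are NaN when a bulk has zero depth;
    ``delta`` is meaningful only for PASS records.
    """

    chrom: str
    pos: int
    depth_H: int
    depth_L: int
    index_H: float
    index_L: float
    delta: float
    status: str

    @property
    def passed(self) -> bool:
        return self.status == PASS


def _classify(
    site: VariantSite, min_depth: int, low_index: float, low_index_mode: str
) -> SnpIndexRecord:
    depth_h, depth_l = site.depth_H, site.depth_L
    index_h = site.alt_H / depth_h if depth_h > 0 else math.nan
    index_l = site.alt_L / depth_l if depth_l > 0 else math.nan
    delta = index_h - index_l

    # Depth first, then low-index; first failure wins so audit counts are unambiguous.
    if depth_h < min_depth or depth_l < min_depth:
        status = LOW_DEPTH
    elif low_index_mode == "both" and index_h < low_index and index_l < low_index:
        status = LOW_INDEX_BOTH
    elif low_index_mode == "either" and (index_h < low_index or index_l < low_index):
        status = LOW_INDEX_EITHER
    else:
        status = PASS
    return SnpIndexRecord(
        chrom=site.chrom,
        pos=site.pos,
        depth_H=depth_h,
        depth_L=depth_l,
        index_H=index_h,
        index_L=index_l,
        delta=delta,
        status=status,
    )


def apply_filters(
    table: AlleleCountTable | Sequence[VariantSite],
    min_depth: int = 7,
    low_index: float = 0.3,
    low_index_mode: str = "both",
) -> list[SnpIndexRecord]:
    """Compute per-site indices and assign a filter status to every site.

    Every input site appears exactly once in the output with exactly one
    reason code, so PASS + exclusion counts always reconcile with the input.
    """
    if low_index_mode not in ("both", "either"):
        raise ValueError(f"low_index_mode must be 'both' or 'either', got {low_index_mode!r}")
    if min_depth < 1:
        raise ValueError(f"min_depth must be >= 1, got {min_depth}")
    sites = table.sites if isinstance(table, AlleleCountTable) else list(table)
    return [_classify(s, min_depth, low_index, low_index_mode) for s in sites]


def filter_counts(records: Sequence[SnpIndexRecord]) -> dict[str, int]:
    """Audit tally of filter reasons; values sum to the input site count."""
    counts: dict[str, int] = {PASS: 0, LOW_DEPTH: 0, LOW_INDEX_BOTH: 0, LOW_INDEX_EITHER: 0}
    for rec in records:
        counts[rec.status] += 1
    return counts
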