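"""Haploid-induction-rate phenotyping and extreme-bulk selection.

The haploid induction rate (HIR) of an inducer line is the percentage of
putative haploid seeds among all seeds set on an induction cross, where the
seed set counts haploid seeds, diploid seeds, and seeds that cannot be
scored with the R1-nj anthocyanin marker:

    HIR (%) = 100 * n_haploid / (n_haploid + n_diploid + n_unmarked)

Bulked-segregant designs select the k highest- and k lowest-HIR lines from
a segregating population into a high and a low DNA pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedCounts:
    """Seed classification for one inducer line.

    ``n_unmarked`` counts seeds lacking the R1-nj marker, which cannot be
    classified as haploid or diploid but still belong to the seed set.
    """

    line_id: str
    n_haploid: int
    n_diploid: int
    n_unmarked: int = 0

    def __post_init__(self) -> None:
        for name in ("n_haploid", "n_diploid", "n_unmarked"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise TypeError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative for line {self.line_id!r}")

    @property
    def seed_set(self) -> int:
        return self.n_haploid + self.n_diploid + self.n_unmarked


@dataclass(frozen=True)
class PhenotypeRecord:
    """A line id with its HIR percentage in [0, 100]."""

    line_id: str
    hir: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.hir <= 100.0:
            raise ValueError(
                f"hir must lie in [0, 100], got {self.hir} for line {self.line_id!r}"
            )


def compute_hir(counts: SeedCounts) -> PhenotypeRecord:
    """Haploid induction rate of one line from its seed counts.

    Computed in exact rational arithmetic and converted to float only at the
    end; display rounding (2 decimals) is left to the output layer.

    Raises
    ------
    ValueError
        If the line set no seeds at all (zero seed set).
    """
    total = counts.seed_set
    if total == 0:
        raise ValueError(f"line {counts.line_id!r} has a zero total seed set; cannot compute HIR")
    hir = Fraction(100 * counts.n_haploid, total)
    return PhenotypeRecord(line_id=counts.line_id, hir=float(hir))


def select_extreme_bulks(
    phenotypes: Sequence[PhenotypeRecord], k: int
) -> tuple[list[str], list[str]]:
    """Pick the k highest- and k lowest-HIR lines for the two bulks.

    Ties at the bulk boundary are broken deterministically: the high bulk is
    filled in (HIR descending, line_id ascending) order, then the low bulk in
    (HIR ascending, line_id ascending) order from the remaining lines, so
    re-running on the same table always yields the same pools and the two
    bulks are disjoint even when ties span the boundary.

    Returns ``(high_ids, low_ids)``; every selected high line has
    HIR >= every selected low line.
    """
    if k < 1:
        raise ValueError(f"bulk size k must be >= 1, got {k}")
    if 2 * k > len(phenotypes):
        raise ValueError(
            f"cannot select two disjoint bulks of {k} from {len(phenotypes)} lines"
        )
    ids = {p.line_id for p in phenotypes}
    if len(ids) != len(phenotypes):
        raise ValueError("duplicate line_id in phenotype table")
    high_order = sorted(phenotypes, key=lambda p: (-p.hir, p.line_id))
    high_ids = [p.line_id for p in high_order[:k]]
    taken = set(high_ids)
    low_order = sorted(
        (p for p in phenotypes if p.line_id not in taken),
        key=lambda p: (p.hir, p.line_id),
    )
    low_ids = [p.line_id for p in low_order[:k]]
    return high_ids, low_ids


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read a phenotype TSV.

    Two layouts are accepted: seed counts (``line_id, n_haploid, n_diploid,
    n_unmarked``) from which HIR is computed, or precomputed rates
    (``line_id, hir``). A missing ``n_unmarked`` column defaults to zero with
    a logged warning, never silently.
    """
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str}, comment="#")
    cols = set(df.columns)
    if "hir" in cols:
        return [
            PhenotypeRecord(line_id=str(r.line_id), hir=float(r.hir))
            for r in df.itertuples(index=False)
        ]
    if not {"line_id", "n_haploid", "n_diploid"} <= cols:
        raise ValueError(
            f"{path}: expected columns (line_id, n_haploid, n_diploid[, n_unmarked]) "
            f"or (line_id, hir); found {sorted(cols)}"
        )
    if "n_unmarked" not in cols:
        logger.warning("%s: no n_unmarked column; defaulting unmarked seed counts to 0", path)
        df["n_unmarked"] = 0
    return [
        compute_hir(
            SeedCounts(
                line_id=str(r.line_id),
                n_haploid=int(r.n_haploid),
                n_diploid=int(r.n_diploid),
                n_unmarked=int(r.n_unmarked),
            )
        )
        for r in df.itertuples(index=False)
    ]


def write_phenotypes(records: Iterable[PhenotypeRecord], path: str | Path) -> None:
    """Write phenotypes as a two-column TSV (HIR to 2 decimals)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("line_id\thir\n")
        for rec in records:
            fh.write(f"{rec.line_id}\t{rec.hir:.2f}\n")
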