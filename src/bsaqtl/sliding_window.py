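"""Sliding-window smoothing of per-site statistics and QTL-interval calling.

Per-site SNP-index values are noisy at realistic depths, so QTL-seq averages
them in overlapping windows (1 Mb wide, advancing in 100 kb steps by
default). Windows whose mean ΔSNP-index exceeds the null confidence band are
significant; runs of consecutive significant windows merge into QTL
intervals reported with their span in Mb and peak statistic.

All coordinates are 1-based inclusive; a site exactly at a window's end
coordinate is inside the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .snp_index import SnpIndexRecord


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad window [{self.start}, {self.end}] on {self.chrom}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class WindowStat:
    """Windowed means with (optionally attached) null CI bounds.

    Means are NaN when ``n_sites == 0``; such windows are never significant.
    """

    chrom: str
    start: int
    end: int
    midpoint: float
    n_sites: int
    mean_index_H: float
    mean_index_L: float
    mean_delta: float
    mean_depth: float
    ci95_lo: float = math.nan
    ci95_hi: float = math.nan
    ci99_lo: float = math.nan
    ci99_hi: float = math.nan
    significant_95: bool = False
    significant_99: bool = False

    @property
    def has_ci(self) -> bool:
        return not math.isnan(self.ci99_hi)


@dataclass(frozen=True)
class QtlInterval:
    """A merged run of significant windows."""

    chrom: str
    start: int
    end: int
    span_mb: float
    peak_delta: float
    peak_pos: int
    n_sites: int
    ci_level: float


def interval_span_mb(start: int, end: int) -> float:
    """Interval span in Mb: (end - start) / 1e6, rounded half-up to 2 dp."""
    if end < start:
        raise ValueError(f"end ({end}) must be >= start ({start})")
    span = Decimal(end - start) / Decimal(10**6)
    return float(span.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def make_windows(
    chrom_lengths: Sequence[tuple[str, int]],
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
) -> list[Window]:
    """Enumerate sliding windows anchored at position 1 on each chromosome.

    Full windows start at 1, 1+step, ... while they fit on the chromosome;
    if the last full window stops short of the chromosome end, one final
    window clipped at the end is appended so every bp is covered. A
    chromosome shorter than the window yields a single window spanning it.
    """
    if not (1 <= step_bp <= window_bp):
        raise ValueError(f"need window_bp >= step_bp >= 1, got {window_bp}, {step_bp}")
    windows: list[Window] = []
    for chrom, length in chrom_lengths:
        if length < 1:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        if length < window_bp:
            windows.append(Window(chrom, 1, length))
            continue
        start = 1
        last_end = 0
        while start + window_bp - 1 <= length:
            last_end = start + window_bp - 1
            windows.append(Window(chrom, start, last_end))
            start += step_bp
        if last_end < length:
            windows.append(Window(chrom, start, length))
    return windows


def window_means(
    records: Sequence[SnpIndexRecord],
    windows: Sequence[Window],
    passing_only: bool = True,
) -> list[WindowStat]:
    """Unweighted per-window means of index_H, index_L, ΔSNP-index and depth.

    Only PASS sites contribute (by default). ``mean_depth`` is the mean of
    the per-site average bulk depth, (depth_H + depth_L)/2, and feeds the
    depth-dependent CI lookup downstream.
    """
    import bisect

    if passing_only:
        records = [r for r in records if r.passed]
    by_chrom: dict[str, list[SnpIndexRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for recs in by_chrom.values():
        recs.sort(key=lambda r: r.pos)
    positions = {c: [r.pos for r in recs] for c, recs in by_chrom.items()}

    stats: list[WindowStat] = []
    for win in windows:
        recs = by_chrom.get(win.chrom, [])
        pos = positions.get(win.chrom, [])
        lo = bisect.bisect_left(pos, win.start)
        hi = bisect.bisect_right(pos, win.end)  # inclusive end
        inside = recs[lo:hi]
        n = len(inside)
        if n == 0:
            stats.append(
                WindowStat(
                    chrom=win.chrom,
                    start=win.start,
                    end=win.end,
                    midpoint=win.midpoint,
                    n_sites=0,
                    mean_index_H=math.nan,
                    mean_index_L=math.nan,
                    mean_delta=math.nan,
                    mean_depth=math.nan,
                )
            )
            continue
        stats.append(
            WindowStat(
                chrom=win.chrom,
                start=win.start,
                end=win.end,
                midpoint=win.midpoint,
                n_sites=n,
                mean_index_H=sum(r.index_H for r in inside) / n,
                mean_index_L=sum(r.index_L for r in inside) / n,
                mean_delta=sum(r.delta for r in inside) / n,
                mean_depth=sum((r.depth_H + r.depth_L) / 2 for r in inside) / n,
            )
        )
    return stats


def call_qtl_intervals(
    stats: Sequence[WindowStat],
    level: float = 0.99,
    step_bp: int = 100_000,
    max_gap_windows: int = 0,
    two_sided: bool = False,
) -> list[QtlInterval]:
    """Merge runs of significant windows into QTL intervals.

    A window is significant when its mean ΔSNP-index exceeds the upper null
    CI bound at ``level`` (one-sided high: the trait allele is enriched in
    the high bulk). With ``two_sided=True`` windows below the lower bound
    are also called (peak reported by |Δ|). Consecutive significant windows
    on a chromosome merge; a gap of more than ``max_gap_windows``
    intervening non-significant windows splits intervals.
    """
    if level not in (0.95, 0.99):
        raise ValueError(f"level must be 0.95 or 0.99, got {level}")
    for st in stats:
        if st.n_sites > 0 and not st.has_ci:
            raise ValueError(
                f"window {st.chrom}:{st.start}-{st.end} lacks CI bounds; run attach_ci first"
            )

    def is_sig(st: WindowStat) -> bool:
        if st.n_sites == 0 or math.isnan(st.mean_delta):
            return False
        hi = st.ci99_hi if level == 0.99 else st.ci95_hi
        lo = st.ci99_lo if level == 0.99 else st.ci95_lo
        if st.mean_delta > hi:
            return True
        return two_sided and st.mean_delta < lo

    intervals: list[QtlInterval] = []
    run: list[WindowStat] = []

    def flush() -> None:
        if not run:
            return
        start = min(w.start for w in run)
        end = max(w.end for w in run)
        peak = max(run, key=lambda w: abs(w.mean_delta))
        # Site count of the merged region: union of overlapping windows is
        # approximated by the max per-window count to avoid double counting.
        n_sites = max(w.n_sites for w in run)
        intervals.append(
            QtlInterval(
                chrom=run[0].chrom,
                start=start,
                end=end,
                span_mb=interval_span_mb(start, end),
                peak_delta=peak.mean_delta,
                peak_pos=int(peak.midpoint),
                n_sites=n_sites,
                ci_level=level,
            )
        )
        run.clear()

    max_gap_bp = (1 + max_gap_windows) * step_bp
    for st in sorted(stats, key=lambda w: (w.chrom, w.start)):
        if not is_sig(st):
            continue
        if run and (st.chrom != run[-1].chrom or st.start - run[-1].start > max_gap_bp):
            flush()
        run.append(st)
    flush()
    return intervals


def reattach_flags(stats: Sequence[WindowStat]) -> list[WindowStat]:
    """Recompute significance flags from each window's own bounds."""
    out = []
    for st in stats:
        sig95 = st.n_sites > 0 and st.has_ci and st.mean_delta > st.ci95_hi
        sig99 = st.n_sites > 0 and st.has_ci and st.mean_delta > st.ci99_hi
        out.append(replace(st, significant_95=sig95, significant_99=sig99))
    return out
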