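"""Monte-Carlo null distribution of the ΔSNP-index and confidence bands.

Under no linkage to the trait, both bulks sample alleles from the same
segregating population, so the ΔSNP-index fluctuates around zero with a
spread set by two nested sampling stages:

1. individual sampling — each bulk pools N individuals whose genotype
   dosages at an F2-like site are Binomial(2, 1/2), giving a bulk allele
   frequency p = Σdosage / 2N;
2. read sampling — the sequencer draws ``depth`` reads from the pool,
   alt reads ~ Binomial(depth, p).

The exact variance of one bulk's index is
Var = p̄(1−p̄)/depth + Var(p)·(1 − 1/depth) with p̄ = 1/2 and
Var(p) = 1/(8N); the ΔSNP-index variance is twice that. Empirical
two-sided quantiles of simulated replicates give 95%/99% bands per depth,
tabulated on a depth grid and interpolated at a window's mean depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .sliding_window import WindowStat


def simulate_null_delta(
    bulk_size: int,
    depth: int,
    replicates: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample the ΔSNP-index null at one depth.

    Each replicate draws the two bulks independently through the two-stage
    (individuals, then reads) model and returns index_H − index_L.
    """
    if bulk_size < 1:
        raise ValueError(f"bulk_size must be >= 1, got {bulk_size}")
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    deltas = np.empty(replicates)
    indices = []
    for _ in range(2):  # high bulk, low bulk: independent, identically distributed
        p = rng.binomial(2 * bulk_size, 0.5, size=replicates) / (2 * bulk_size)
        alt = rng.binomial(depth, p)
        indices.append(alt / depth)
    np.subtract(indices[0], indices[1], out=deltas)
    return deltas


def null_delta_variance(bulk_size: int, depth: int) -> float:
    """Closed-form two-stage sampling variance of the null ΔSNP-index."""
    var_p = 1.0 / (8.0 * bulk_size)
    var_index = 0.25 / depth + var_p * (1.0 - 1.0 / depth)
    return 2.0 * var_index


@dataclass(frozen=True)
class NullCiTable:
    """Depth-indexed 95%/99% null confidence bands.

    Bands are empirical type-7 quantiles, isotonically smoothed so band
    width is non-increasing in depth (removes Monte-Carlo wiggle).
    """

    depths: np.ndarray
    ci95_lo: np.ndarray
    ci95_hi: np.ndarray
    ci99_lo: np.ndarray
    ci99_hi: np.ndarray
    bulk_size: int
    replicates: int
    seed: int
    generation: str = "F2"

    def bounds_at(self, depth: float) -> dict[str, float]:
        """Linearly interpolated bounds at an arbitrary depth.

        Depths outside the grid by more than 2x at either end are refused:
        extend the grid instead of extrapolating.
        """
        dmin, dmax = self.depths[0], self.depths[-1]
        if depth < dmin / 2 or depth > dmax * 2:
            raise ValueError(
                f"depth {depth:g} outside CI grid [{dmin}, {dmax}] by more than 2x; "
                "extend the depth grid"
            )
        d = float(np.clip(depth, dmin, dmax))
        return {
            "ci95_lo": float(np.interp(d, self.depths, self.ci95_lo)),
            "ci95_hi": float(np.interp(d, self.depths, self.ci95_hi)),
            "ci99_lo": float(np.interp(d, self.depths, self.ci99_lo)),
            "ci99_hi": float(np.interp(d, self.depths, self.ci99_hi)),
        }

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                f"# bulk_size={self.bulk_size} generation={self.generation} "
                f"replicates={self.replicates} seed={self.seed}\n"
            )
            fh.write("depth\tci95_lo\tci95_hi\tci99_lo\tci99_hi\n")
            for i, d in enumerate(self.depths):
                fh.write(
                    f"{int(d)}\t{self.ci95_lo[i]:.6f}\t{self.ci95_hi[i]:.6f}"
                    f"\t{self.ci99_lo[i]:.6f}\t{self.ci99_hi[i]:.6f}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "NullCiTable":
        import re

        meta = {"bulk_size": 0, "replicates": 0, "seed": 0, "generation": "F2"}
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    for key in meta:
                        m = re.search(rf"{key}=(\S+)", line)
                        if m:
                            meta[key] = m.group(1)
                    continue
                if not line or line.startswith("depth"):
                    continue
                rows.append([float(x) for x in line.split("\t")])
        arr = np.asarray(rows)
        return cls(
            depths=arr[:, 0],
            ci95_lo=arr[:, 1],
            ci95_hi=arr[:, 2],
            ci99_lo=arr[:, 3],
            ci99_hi=arr[:, 4],
            bulk_size=int(meta["bulk_size"]),
            replicates=int(meta["replicates"]),
            seed=int(meta["seed"]),
            generation=str(meta["generation"]),
        )


def _isotonic_widths(depths: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    # Enforce |bound| non-increasing in depth on each side independently
    # (running min of the upper bound, running max of the lower).
    hi_s = np.minimum.accumulate(hi)
    lo_s = np.maximum.accumulate(lo)
    return lo_s, hi_s


def ci_table(
    bulk_size: int,
    depth_grid: Sequence[int],
    replicates: int = 100_000,
    seed: int = 0,
) -> NullCiTable:
    """Tabulate 95%/99% null bands over a depth grid.

    Requires >= 1000 replicates (tail quantiles are unstable below that).
    One generator seeded once drives all depths, so results are
    reproducible given (seed, replicates, grid).
    """
    if replicates < 1000:
        raise ValueError(f"replicates must be >= 1000 for stable quantiles, got {replicates}")
    depths = np.asarray(sorted(int(d) for d in depth_grid))
    if len(depths) == 0 or depths[0] < 1:
        raise ValueError("depth grid must contain positive depths")
    if len(np.unique(depths)) != len(depths):
        raise ValueError("depth grid contains duplicates")
    rng = np.random.default_rng(seed)
    q = {"95_lo": 0.025, "95_hi": 0.975, "99_lo": 0.005, "99_hi": 0.995}
    bands = {k: np.empty(len(depths)) for k in q}
    for i, d in enumerate(depths):
        deltas = simulate_null_delta(bulk_size, int(d), replicates, rng)
        for key, level in q.items():
            bands[key][i] = np.quantile(deltas, level)  # type-7 linear interpolation
    lo95, hi95 = _isotonic_widths(depths, bands["95_lo"], bands["95_hi"])
    lo99, hi99 = _isotonic_widths(depths, bands["99_lo"], bands["99_hi"])
    return NullCiTable(
        depths=depths.astype(float),
        ci95_lo=lo95,
        ci95_hi=hi95,
        ci99_lo=lo99,
        ci99_hi=hi99,
        bulk_size=bulk_size,
        replicates=replicates,
        seed=seed if isinstance(seed, int) else -1,
    )


def attach_ci(stats: Sequence[WindowStat], table: NullCiTable) -> list[WindowStat]:
    """Attach depth-appropriate null bounds and significance flags to windows.

    Each window's bounds come from the CI table interpolated at the window's
    mean depth; windows without sites keep NaN bounds and stay
    non-significant.
    """
    out: list[WindowStat] = []
    for st in stats:
        if st.n_sites == 0:
            out.append(st)
            continue
        b = table.bounds_at(st.mean_depth)
        out.append(
            replace(
                st,
                ci95_lo=b["ci95_lo"],
                ci95_hi=b["ci95_hi"],
                ci99_lo=b["ci99_lo"],
                ci99_hi=b["ci99_hi"],
                significant_95=st.mean_delta > b["ci95_hi"],
                significant_99=st.mean_delta > b["ci99_hi"],
            )
        )
    return out
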