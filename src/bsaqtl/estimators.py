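"""Scikit-learn-style estimators wrapping the two core analyses.

``MarkerTraitRegression`` is a bona-fide sklearn regressor (fit/predict/
score, clonable) for single-marker trait association with additive dosage
coding. ``QtlSeqScan`` follows the same conventions (constructor parameters,
``get_params``/``set_params``, fitted attributes with trailing underscores)
for the ΔSNP-index genome scan: fit consumes an allele-count table plus
chromosome sizes and exposes per-site records, window statistics with null
confidence bands, and called QTL intervals.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import null_ci as _null_ci
from . import sliding_window as _sw
from . import snp_index as _si
from .variant_io import AlleleCountTable


class MarkerTraitRegression(RegressorMixin, BaseEstimator):
    """Simple (single-marker) OLS regression of a trait on allele dosage.

    Parameters
    ----------
    min_n : int
        Minimum complete pairs required to fit (default 3).

    Attributes
    ----------
    slope_, intercept_ : float
        OLS coefficients.
    r_squared_ : float
        Squared Pearson correlation between dosage and trait.
    p_value_ : float
        Two-sided p of the slope (t statistic, n-2 df).
    pve_ : float
        Phenotypic variance explained, 100 * r_squared_.
    n_used_ : int
        Complete (non-missing) pairs used in the fit.
    """

    def __init__(self, min_n: int = 3):
        self.min_n = min_n

    def fit(self, X, y):
        import logging

        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("MarkerTraitRegression expects a single dosage column")
        y = np.asarray(y, dtype=float)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        x = X[:, 0]
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
        if len(x) < self.min_n:
            raise ValueError(f"need >= {self.min_n} complete pairs, got {len(x)}")
        if np.ptp(x) == 0:
            raise ValueError("CONSTANT_GENOTYPE: dosage has no variation")
        if np.ptp(y) == 0:
            logging.getLogger(__name__).warning("constant phenotype: r_squared set to 0")
            self.slope_ = 0.0
            self.intercept_ = float(y[0])
            self.r_squared_ = 0.0
            self.p_value_ = 1.0
        else:
            res = sps.linregress(x, y)
            self.slope_ = float(res.slope)
            self.intercept_ = float(res.intercept)
            self.r_squared_ = float(res.rvalue**2)
            self.p_value_ = float(res.pvalue)
        self.n_used_ = int(len(x))
        self.pve_ = 100.0 * self.r_squared_
        self.stderr_ = float(getattr(res, "stderr", np.nan)) if np.ptp(y) != 0 else math.nan
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        return self.intercept_ + self.slope_ * X[:, 0]


class QtlSeqScan(BaseEstimator):
    """ΔSNP-index genome scan with Monte-Carlo null confidence bands.

    fit() runs: per-site SNP-index and filtering → sliding-window means →
    null-CI attachment at each window's mean depth → QTL-interval calling.

    Parameters
    ----------
    min_depth : int
        Per-bulk minimum read depth; sites below it in either bulk are
        excluded (default 7).
    low_index : float
        Low-index threshold for the spurious-SNP filter (default 0.3).
    low_index_mode : {"both", "either"}
        Exclude a site when its index is below ``low_index`` in both bulks
        (default) or in either bulk.
    window_bp, step_bp : int
        Sliding-window width and increment (defaults 1 Mb / 100 kb).
    bulk_size : int
        Individuals per bulk for the null model (default 30).
    replicates : int
        Monte-Carlo replicates per grid depth (default 100,000).
    depth_grid : sequence of int or None
        Depths at which the null band is tabulated; None derives a grid
        from the data's depth range.
    level : float
        CI level for interval calling, 0.95 or 0.99 (default 0.99).
    max_gap_windows : int
        Non-significant windows tolerated inside one interval (default 0).
    two_sided : bool
        Also call negative-delta intervals (default False).
    random_state : int
        Seed for the Monte-Carlo null (default 0).

    Attributes
    ----------
    records_ : list of SnpIndexRecord
    filter_counts_ : dict mapping status to count
    windows_ : list of WindowStat (CI attached)
    ci_table_ : NullCiTable
    intervals_ : list of QtlInterval
    """

    def __init__(
        self,
        min_depth: int = 7,
        low_index: float = 0.3,
        low_index_mode: str = "both",
        window_bp: int = 1_000_000,
        step_bp: int = 100_000,
        bulk_size: int = 30,
        replicates: int = 100_000,
        depth_grid=None,
        level: float = 0.99,
        max_gap_windows: int = 0,
        two_sided: bool = False,
        random_state: int = 0,
    ):
        self.min_depth = min_depth
        self.low_index = low_index
        self.low_index_mode = low_index_mode
        self.window_bp = window_bp
        self.step_bp = step_bp
        self.bulk_size = bulk_size
        self.replicates = replicates
        self.depth_grid = depth_grid
        self.level = level
        self.max_gap_windows = max_gap_windows
        self.two_sided = two_sided
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _resolve_depth_grid(self, records) -> list[int]:
        if self.depth_grid is not None:
            return list(self.depth_grid)
        depths = [
            (r.depth_H + r.depth_L) / 2 for r in records if r.passed
        ]
        if not depths:
            return [self.min_depth, 2 * self.min_depth]
        lo = max(1, int(min(depths) * 0.8))
        hi = max(lo + 1, int(max(depths) * 1.2) + 1)
        step = max(1, (hi - lo) // 20)
        grid = list(range(lo, hi + step, step))
        return grid

    # -- sklearn-style API -------------------------------------------------
    def fit(self, table: AlleleCountTable, chrom_lengths, ci_table=None):
        """Run the scan.

        Parameters
        ----------
        table : AlleleCountTable
            Per-site bulk allele depths.
        chrom_lengths : sequence of (chrom, length)
            Chromosome sizes for window construction.
        ci_table : NullCiTable, optional
            Pre-computed null band table (reused across runs); computed
            from ``bulk_size``/``replicates``/``depth_grid`` when absent.
        """
        if self.level not in (0.95, 0.99):
            raise ValueError(f"level must be 0.95 or 0.99, got {self.level}")
        self.records_ = _si.apply_filters(
            table,
            min_depth=self.min_depth,
            low_index=self.low_index,
            low_index_mode=self.low_index_mode,
        )
        self.filter_counts_ = _si.filter_counts(self.records_)
        windows = _sw.make_windows(chrom_lengths, self.window_bp, self.step_bp)
        stats = _sw.window_means(self.records_, windows)
        if ci_table is None:
            grid = self._resolve_depth_grid(self.records_)
            ci_table = _null_ci.ci_table(
                self.bulk_size, grid, replicates=self.replicates, seed=self.random_state
            )
        self.ci_table_ = ci_table
        self.windows_ = _null_ci.attach_ci(stats, ci_table)
        self.intervals_ = _sw.call_qtl_intervals(
            self.windows_,
            level=self.level,
            step_bp=self.step_bp,
            max_gap_windows=self.max_gap_windows,
            two_sided=self.two_sided,
        )
        return self

    def transform(self, table=None):
        """Return the called QTL intervals (fit output)."""
        check_is_fitted(self, "intervals_")
        return self.intervals_
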