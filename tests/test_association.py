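import math

import numpy as np
import pytest

from bsaqtl import (
    GenotypeCall,
    class_summary,
    combined_classes,
    encode_dosage,
    fit_simple_regression,
    pve,
    screen_candidates,
)
from bsaqtl.association import AssociationResult, benjamini_hochberg


def call(lid, g, marker="M1"):
    if g is None:
        return GenotypeCall(lid, marker, None, None)
    return GenotypeCall(lid, marker, g[0], g[1])


class TestEncoding:
    @pytest.mark.parametrize("g, expected", [("TT", 0), ("TC", 1), ("CT", 1), ("CC", 2)])
    def test_dosage_counts_alt_copies(self, g, expected):
        assert encode_dosage(call("L1", g), "T", "C") == expected

    def test_missing_propagates(self):
        assert encode_dosage(call("L1", None), "T", "C") is None

    def test_unknown_allele_errors(self):
        with pytest.raises(ValueError, match="neither"):
            encode_dosage(call("L1", "TG"), "T", "C")


class TestPve:
    @pytest.mark.parametrize("r2, expected", [(0.08, 8.0), (0.03, 3.0), (0.0, 0.0), (1.0, 100.0)])
    def test_pve_is_percent_r2(self, r2, expected):
        assert pve(r2) == expected

    def test_pve_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            pve(1.5)

    def test_pve_order_preserving(self):
        r = np.linspace(0, 1, 11)
        assert np.all(np.diff([pve(x) for x in r]) > 0)


def ols_oracle(x, y):
    """Normal-equations OLS: direct matrix solve, independent of the fit path."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1 - np.sum(resid**2) / sst
    n = len(x)
    se = math.sqrt(np.sum(resid**2) / (n - 2) / np.sum((x - x.mean()) ** 2))
    from scipy.stats import t as tdist

    tstat = beta[1] / se
    p = 2 * tdist.sf(abs(tstat), n - 2)
    return beta[1], beta[0], r2, p


class TestRegression:
    def test_exactly_linear_gives_r2_one(self):
        res = fit_simple_regression([0, 1, 2, 0, 1, 2], [1.0, 3.0, 5.0, 1.0, 3.0, 5.0])
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_orthogonal_vectors_give_r2_zero(self):
        # dosage and trait constructed orthogonal after centering
        dosage = [0, 1, 2, 1]
        hir = [5.0, 8.0, 5.0, 2.0]  # cov with dosage = 0
        res = fit_simple_regression(dosage, hir)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_eight_point_fixture_matches_normal_equations_oracle(self):
        x = np.array([0, 0, 1, 1, 1, 2, 2, 2], dtype=float)
        y = np.array([2.1, 3.0, 4.9, 5.4, 4.4, 8.2, 7.9, 9.1])
        res = fit_simple_regression(x, y)
        slope, intercept, r2, p = ols_oracle(x, y)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-8)
        assert res.pve == pytest.approx(100 * r2, abs=1e-8)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.integers(0, 3, size=30).astype(float)
            if np.ptp(x) == 0:
                continue
            y = rng.normal(size=30)
            res = fit_simple_regression(x, y)
            assert res.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_missing_dropped_pairwise(self):
        res = fit_simple_regression([0, None, 2, 1, None], [1.0, 9.0, 5.0, 3.0, 9.0])
        assert res.n == 3
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_dosage_errors(self):
        with pytest.raises(ValueError, match="CONSTANT_GENOTYPE"):
            fit_simple_regression([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])

    def test_constant_phenotype_warns_r2_zero(self, caplog):
        with caplog.at_level("WARNING"):
            res = fit_simple_regression([0, 1, 2, 0], [4.0, 4.0, 4.0, 4.0])
        assert res.r_squared == 0.0
        assert "constant phenotype" in caplog.text

    def test_slope_recovered_within_two_se(self):
        """Parameter recovery: planted per-dosage effect inside slope ± 2 SE
        in at least 90% of seeded runs."""
        from bsaqtl.estimators import MarkerTraitRegression

        effect, hits, runs = 3.0, 0, 50
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            dosage = rng.binomial(2, 0.5, size=200).astype(float)
            y = 6.0 + effect * (dosage - 1) + rng.normal(0, 4.0, size=200)
            est = MarkerTraitRegression().fit(dosage.reshape(-1, 1), y)
            if abs(est.slope_ - effect) <= 2 * est.stderr_:
                hits += 1
        assert hits >= 0.9 * runs


class TestClassSummary:
    def test_single_class(self):
        calls = [call(f"L{i}", "TT") for i in range(3)]
        phenos = {"L0": 1.0, "L1": 2.0, "L2": 3.0}
        [s] = class_summary(calls, phenos, "T", "C")
        assert (s.genotype_class, s.n, s.mean_hir, s.min_hir, s.max_hir) == ("AA", 3, 2.0, 1.0, 3.0)

    def test_nine_line_fixture_matches_hand_computation(self):
        genos = ["TT", "TT", "TC", "TC", "TC", "CC", "CC", "CC", "CC"]
        hirs = [2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0]
        calls = [call(f"L{i}", g) for i, g in enumerate(genos)]
        phenos = {f"L{i}": h for i, h in enumerate(hirs)}
        summaries = {s.genotype_class: s for s in class_summary(calls, phenos, "T", "C")}
        assert summaries["AA"].mean_hir == 3.0 and summaries["AA"].n == 2
        assert summaries["AB"].mean_hir == 8.0 and summaries["AB"].min_hir == 6.0
        assert summaries["BB"].mean_hir == 15.0 and summaries["BB"].max_hir == 18.0
        assert list(summaries) == ["AA", "AB", "BB"]

    def test_all_missing_warns_and_returns_empty(self, caplog):
        calls = [call("L1", None), call("L2", None)]
        with caplog.at_level("WARNING"):
            assert class_summary(calls, {"L1": 1.0, "L2": 2.0}, "T", "C") == []
        assert "missing" in caplog.text


class TestCombinedClasses:
    def test_identical_markers_collapse_to_diagonal(self):
        genos = ["TT", "TC", "CC", "TT", "CC", "TC"]
        calls_a = [call(f"L{i}", g, "A") for i, g in enumerate(genos)]
        calls_b = [call(f"L{i}", g, "B") for i, g in enumerate(genos)]
        phenos = {f"L{i}": float(i) for i in range(6)}
        res = combined_classes(calls_a, calls_b, phenos, ("T", "C"), ("T", "C"))
        assert all(a == b for a, b in res.summaries)

    def test_toy_fixture_matches_group_by_oracle(self):
        import pandas as pd

        genos_a = ["TT", "TT", "TC", "CC", "CC", "CC", "TC", "TT"]
        genos_b = ["GG", "GC", "GG", "CC", "CC", "GC", "GC", "CC"]
        hirs = [12.0, 10.0, 9.0, 5.0, 6.0, 7.0, 8.0, 11.0]
        calls_a = [call(f"L{i}", g, "A") for i, g in enumerate(genos_a)]
        calls_b = [call(f"L{i}", g, "B") for i, g in enumerate(genos_b)]
        phenos = {f"L{i}": h for i, h in enumerate(hirs)}
        res = combined_classes(calls_a, calls_b, phenos, ("T", "C"), ("C", "G"))
        df = pd.DataFrame({"a": genos_a, "b": genos_b, "hir": hirs})
        # oracle: pandas group-by on the raw genotype strings
        cls_map_a = {"TT": "AA", "TC": "AB", "CC": "BB"}
        cls_map_b = {"CC": "AA", "GC": "AB", "CG": "AB", "GG": "BB"}
        df["ca"] = df["a"].map(cls_map_a)
        df["cb"] = df["b"].map(cls_map_b)
        grouped = df.groupby(["ca", "cb"])["hir"].agg(["count", "mean", "min", "max"])
        for (ca, cb), row in grouped.iterrows():
            s = res.summaries[(ca, cb)]
            assert (s.n, s.mean_hir, s.min_hir, s.max_hir) == (
                row["count"], row["mean"], row["min"], row["max"],
            )

    def test_disjoint_lines_error(self):
        a = [call("L1", "TT", "A")]
        b = [call("L2", "TT", "B")]
        with pytest.raises(ValueError, match="share no lines"):
            combined_classes(a, b, {"L1": 1.0, "L2": 2.0}, ("T", "C"), ("T", "C"))

    def test_two_planted_qtls_favour_double_homozygote(self):
        """With two additive QTLs of effect 3%, (favourable, favourable)
        lines out-average (unfavourable, unfavourable) in >= 95% of runs."""
        hits, runs = 0, 50
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            n = 337
            d_a = rng.binomial(2, 0.5, size=n)
            d_b = rng.binomial(2, 0.5, size=n)
            y = np.clip(6.0 + 3.0 * (d_a - 1) + 3.0 * (d_b - 1) + rng.normal(0, 4.0, n), 0, 100)
            to_g = {0: "TT", 1: "TC", 2: "CC"}
            calls_a = [call(f"L{i}", to_g[d], "A") for i, d in enumerate(d_a)]
            calls_b = [call(f"L{i}", to_g[d], "B") for i, d in enumerate(d_b)]
            phenos = {f"L{i}": float(v) for i, v in enumerate(y)}
            res = combined_classes(calls_a, calls_b, phenos, ("T", "C"), ("T", "C"))
            fav = res.summaries.get(res.favorable_class)
            unf = res.summaries.get(res.unfavorable_class)
            if fav and unf and fav.mean_hir > unf.mean_hir:
                hits += 1
        assert hits >= 0.95 * runs


class TestScreening:
    def fixture(self):
        r2s = [0.05, 0.31, 0.3, 0.72, 0.29, 0.5, 0.1, 0.301, 0.0, 0.2]
        return [
            AssociationResult(f"M{i}", 10, 1.0, 0.0, r2, 0.05, 100 * r2)
            for i, r2 in enumerate(r2s)
        ]

    def test_strict_threshold(self):
        kept = screen_candidates(self.fixture(), 0.3)
        assert [r.marker_id for r in kept] == ["M1", "M3", "M5", "M7"]

    def test_exactly_at_threshold_excluded(self):
        [res] = screen_candidates(
            [AssociationResult("M", 10, 1.0, 0.0, 0.3, 0.05, 30.0)] , 0.299999
        )
        assert res.r_squared == 0.3
        assert screen_candidates([res], 0.3) == []

    def test_empty_input(self):
        assert screen_candidates([], 0.3) == []


def test_benjamini_hochberg_bounds_and_order():
    p = [0.001, 0.04, 0.03, 0.9]
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p) and np.all(adj <= 1.0)
    assert np.argmin(adj) == 0
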