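import filecmp
import json

import numpy as np
import pytest

import bsaqtl as b
from bsaqtl.simulate import (
    SimConfig,
    _haldane_recomb_fraction,
    simulate_bulk_reads,
    simulate_genotypes,
    simulate_population,
    simulate_trait,
    site_positions,
    write_simulation,
)


def small_config(**kw):
    defaults = dict(
        chrom_lengths=(("chr1", 10_000_000),),
        marker_spacing=1_000_000,
        population_size=100,
        bulk_size=10,
        seed=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_mendelian_allele_frequency():
    """F2-like segregation: expected alt frequency 0.5 at every site."""
    cfg = small_config(population_size=10_000, chrom_lengths=(("chr1", 3_000_000),))
    g, _ = simulate_genotypes(cfg)
    freq = g.mean(axis=0) / 2
    assert np.all(np.abs(freq - 0.5) < 0.02)


def test_adjacent_sites_nearly_identical():
    """1 bp apart: recombination fraction ~0, genotypes co-segregate."""
    cfg = SimConfig(
        chrom_lengths=(("chr1", 2),), marker_spacing=1, population_size=2000,
        bulk_size=10, seed=3,
    )
    g, _ = simulate_genotypes(cfg)
    corr = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
    assert corr > 0.999


def two_locus_dosage_corr_oracle(r: float) -> float:
    """Enumerate F1 gamete types (coupling): AB/(1-r)/2, ab/(1-r)/2, Ab/r/2, aB/r/2.

    A line is two independent gametes; enumerate all 16 gamete pairs to get
    the exact dosage correlation between the two loci.
    """
    gametes = [((1, 1), (1 - r) / 2), ((0, 0), (1 - r) / 2), ((1, 0), r / 2), ((0, 1), r / 2)]
    e_a = e_b = e_ab = e_a2 = e_b2 = 0.0
    for (a1, b1), p1 in gametes:
        for (a2, b2), p2 in gametes:
            p = p1 * p2
            da, db = a1 + a2, b1 + b2
            e_a += p * da
            e_b += p * db
            e_ab += p * da * db
            e_a2 += p * da * da
            e_b2 += p * db * db
    cov = e_ab - e_a * e_b
    return cov / np.sqrt((e_a2 - e_a**2) * (e_b2 - e_b**2))


def test_two_locus_correlation_matches_gamete_enumeration():
    """Dosage correlation at 50 Mb (1 cM/Mb) matches the exact 2-locus oracle."""
    cfg = SimConfig(
        chrom_lengths=(("chr1", 100_000_000),), marker_spacing=50_000_000,
        population_size=20_000, bulk_size=10, seed=5,
    )
    g, sites = simulate_genotypes(cfg)
    assert g.shape[1] == 2
    r = float(_haldane_recomb_fraction(np.array([50e6]), cfg.cm_per_mb)[0])
    expected = two_locus_dosage_corr_oracle(r)
    observed = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
    assert observed == pytest.approx(expected, abs=0.03)


def test_trait_deterministic_when_no_noise():
    cfg = small_config(trait_sd=0.0, baseline_hir=7.5)
    g, sites = simulate_genotypes(cfg)
    phenos = simulate_trait(g, cfg, sites)
    assert all(p.hir == 7.5 for p in phenos)


def test_trait_slope_recovery_by_ols():
    """Regression of the trait on the planted QTL dosage recovers its effect."""
    from scipy.stats import linregress

    cfg = small_config(
        population_size=5000,
        planted_qtls=(("chr1", 5_000_000, 5.0),),
        baseline_hir=50.0,  # keep clear of the 0-clamp so OLS is unbiased
        seed=7,
    )
    g, sites = simulate_genotypes(cfg)
    phenos = simulate_trait(g, cfg, sites)
    col = 4  # site at 5 Mb with 1 Mb spacing
    res = linregress(g[:, col], [p.hir for p in phenos])
    assert res.slope == pytest.approx(5.0, abs=0.3)


def test_low_baseline_piles_up_at_zero():
    cfg = small_config(baseline_hir=2.0, trait_sd=4.0, population_size=2000, seed=9)
    g, sites = simulate_genotypes(cfg)
    phenos = simulate_trait(g, cfg, sites)
    assert sum(p.hir == 0.0 for p in phenos) > 0


def test_bulk_fixed_for_ref_yields_no_alt_reads():
    cfg = small_config(seq_error=0.0)
    sites = site_positions(cfg)
    n_sites = sum(len(p) for _, p in sites)
    g = np.zeros((10, n_sites), dtype=np.int8)
    table, p_h, p_l = simulate_bulk_reads(g, g, cfg, sites)
    assert all(s.alt_H == 0 and s.alt_L == 0 for s in table)
    assert np.all(p_h == 0)


def test_balanced_bulk_alt_fraction_near_half():
    cfg = small_config(seq_error=0.0, mean_bulk_depth=400.0)
    sites = site_positions(cfg)
    n_sites = sum(len(p) for _, p in sites)
    g = np.ones((10, n_sites), dtype=np.int8)  # all heterozygous: p = 0.5
    table, _, _ = simulate_bulk_reads(g, g, cfg, sites)
    for s in table:
        frac = s.alt_H / s.depth_H
        sigma = 0.5 / np.sqrt(s.depth_H)
        assert abs(frac - 0.5) < 3.5 * sigma


def test_realized_depth_mean_matches_poisson_rate():
    cfg = SimConfig(
        chrom_lengths=(("chr1", 50_000_000),), marker_spacing=5_000,
        population_size=20, bulk_size=5, mean_bulk_depth=100.0, seed=13,
    )
    sites = site_positions(cfg)
    n_sites = sum(len(p) for _, p in sites)
    assert n_sites == 10_000
    g = np.ones((5, n_sites), dtype=np.int8)
    table, _, _ = simulate_bulk_reads(g, g, cfg, sites)
    mean_depth = np.mean([s.depth_H for s in table])
    assert mean_depth == pytest.approx(100.0, rel=0.01)


def test_write_simulation_deterministic(tmp_path):
    cfg = small_config(planted_qtls=(("chr1", 5_000_000, 8.0),), seed=21)
    paths1 = write_simulation(simulate_population(cfg), tmp_path / "a")
    paths2 = write_simulation(simulate_population(cfg), tmp_path / "b")
    for key in paths1:
        assert filecmp.cmp(paths1[key], paths2[key], shallow=False), key


def test_vcf_roundtrip_matches_in_memory_counts(tmp_path):
    sim = simulate_population(small_config(seed=4))
    paths = write_simulation(sim, tmp_path)
    table = b.read_vcf_bulks(paths["vcf"])
    assert len(table) == len(sim.counts)
    for got, want in zip(table, sim.counts):
        assert (got.chrom, got.pos) == (want.chrom, want.pos)
        assert (got.ref_H, got.alt_H, got.ref_L, got.alt_L) == (
            want.ref_H, want.alt_H, want.ref_L, want.alt_L,
        )


def test_truth_json_lists_planted_qtls(tmp_path):
    cfg = small_config(planted_qtls=(("chr1", 2_000_000, 3.0), ("chr1", 8_000_000, -2.0)))
    paths = write_simulation(simulate_population(cfg), tmp_path)
    truth = json.loads(paths["truth"].read_text())
    assert len(truth["planted_qtls"]) == 2
    assert {q["chrom"] for q in truth["planted_qtls"]} == {"chr1"}


def test_no_qtl_mean_delta_near_zero():
    """Extreme-bulk selection without QTLs induces no allele-frequency skew.

    The genome-wide mean ΔSNP-index is unbiased under the null, but its
    seed-to-seed spread is governed by the number of independent linkage
    segments, not the site count, so the check uses many short chromosomes
    (~1000 effectively independent segments over 10 seeds, 20,000 sites
    each) to pin the grand mean within 0.01 of zero.
    """
    chroms = tuple((f"c{i:02d}", 1_000_000) for i in range(100))
    grand = []
    for seed in range(10):
        cfg = SimConfig(
            chrom_lengths=chroms, marker_spacing=5_000, seed=170 + seed, seq_error=0.0,
        )
        sim = simulate_population(cfg)
        recs = b.apply_filters(sim.counts)
        deltas = np.array([r.delta for r in recs if r.passed])
        assert len(deltas) > 19_000
        grand.append(deltas.mean())
    assert abs(np.mean(grand)) < 0.01


def test_site_delta_variance_matches_read_sampling_oracle():
    """Conditional on realized bulk frequencies, delta varies by read sampling:
    Var(delta - (p_H - p_L)) = p_H(1-p_H)/d_H + p_L(1-p_L)/d_L per site."""
    cfg = SimConfig(
        chrom_lengths=(("chr1", 50_000_000), ("chr2", 50_000_000)),
        marker_spacing=5_000, seed=19, seq_error=0.0,
    )
    sim = simulate_population(cfg)
    p_h = np.array(sim.truth["bulk_allele_freq_high"])
    p_l = np.array(sim.truth["bulk_allele_freq_low"])
    recs = b.apply_filters(sim.counts)
    resid, expected = [], []
    for j, r in enumerate(recs):
        if not r.passed:
            continue
        resid.append(r.delta - (p_h[j] - p_l[j]))
        expected.append(p_h[j] * (1 - p_h[j]) / r.depth_H + p_l[j] * (1 - p_l[j]) / r.depth_L)
    assert np.var(resid) == pytest.approx(np.mean(expected), rel=0.10)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(bulk_size=200, population_size=100)
    with pytest.raises(ValueError):
        SimConfig(planted_qtls=(("chrX", 1000, 1.0),))
    with pytest.raises(ValueError):
        SimConfig(planted_qtls=(("chr1", 10**9, 1.0),))
    with pytest.raises(ValueError):
        SimConfig(seq_error=0.7)
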