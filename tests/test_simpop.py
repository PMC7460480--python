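"""Simulator tests: locus placement, inheritance, drift-mutation balance,
effect scaling and phenotype calibration."""

import numpy as np
import pandas as pd
import pytest

from mdagwas import simpop
from mdagwas.simpop import (
    DegenerateSimulationError,
    SimConfig,
    SimulationError,
    place_loci,
    simulate_historical,
    simulate_recent,
    subsample,
)

from conftest import tiny_config


# ---------------------------------------------------------------------------
# locus map


@pytest.mark.parametrize(
    "n_chrom,n_snps,n_qtls",
    [(29, 2900, 0), (29, 2900, 29), (3, 10, 5), (5, 13, 7), (2, 0, 4), (1, 1, 1)],
)
def test_locus_counts_match_config(n_chrom, n_snps, n_qtls):
    cfg = SimConfig(
        n_chromosomes=n_chrom, n_snps=n_snps, n_qtls=n_qtls, seed=3,
        chrom_length_bp=1_000_000,
    )
    loci = place_loci(cfg)
    assert (loci["role"] == "SNP").sum() == n_snps
    assert (loci["role"] == "QTL").sum() == n_qtls
    # sorted, unique positions per chromosome
    for _, grp in loci.groupby("chrom"):
        bp = grp["bp"].to_numpy()
        assert np.all(np.diff(bp) > 0)


def test_even_snp_allocation_on_divisible_config():
    cfg = SimConfig(n_chromosomes=29, n_snps=2900, n_qtls=0, seed=1)
    loci = place_loci(cfg)
    per_chrom = loci[loci["role"] == "SNP"].groupby("chrom").size()
    assert (per_chrom == 100).all()
    # residual SNPs go one per chromosome from chromosome 1 upward
    cfg2 = SimConfig(n_chromosomes=5, n_snps=23, n_qtls=0, seed=1)
    sizes = place_loci(cfg2).groupby("chrom").size()
    assert sizes.tolist() == [5, 5, 5, 4, 4]


def test_snp_free_map_is_valid():
    cfg = SimConfig(n_chromosomes=4, n_snps=0, n_qtls=11, seed=9)
    loci = place_loci(cfg)
    assert len(loci) == 11 and (loci["role"] == "QTL").all()


def test_too_many_loci_is_a_configuration_error():
    with pytest.raises(SimulationError):
        SimConfig(n_chromosomes=1, chrom_length_bp=10, n_snps=20, n_qtls=0).validate()


# ---------------------------------------------------------------------------
# historical phase


def test_no_variation_can_arise_without_mutation():
    cfg = tiny_config(7, n_snps=50, n_qtls=0, mutation_rate=0.0,
                      n_hist_generations=15, hist_pop_size=20)
    pool = simulate_historical(cfg, founder_frequency=0.0)
    assert pool.haplotypes.sum() == 0


def test_most_loci_stay_polymorphic_at_default_mutation_rate():
    cfg = tiny_config(8, n_snps=400, n_qtls=0, n_hist_generations=60,
                      hist_pop_size=80)
    pool = simulate_historical(cfg)
    freq = pool.haplotypes.reshape(-1, 400).mean(axis=0)
    assert np.mean((freq > 0) & (freq < 1)) > 0.5


def test_heterozygosity_matches_mutation_drift_equilibrium():
    """Mean 2p(1-p) converges to theta/(1+2*theta), theta = 4*N*mu, the
    stationary expectation of the symmetric two-way biallelic model."""
    N, mu, L = 30, 1e-3, 200
    theta = 4 * N * mu
    expected = theta / (1 + 2 * theta)
    hets = []
    for rep in range(20):
        cfg = SimConfig(n_chromosomes=2, n_snps=L, n_qtls=0, mutation_rate=mu,
                        n_hist_generations=300, hist_pop_size=N, seed=1000 + rep)
        pool = simulate_historical(cfg)
        p = pool.haplotypes.reshape(2 * N, L).mean(axis=0)
        hets.append(np.mean(2 * p * (1 - p)))
    hets = np.asarray(hets)
    sem = hets.std(ddof=1) / np.sqrt(len(hets))
    assert abs(hets.mean() - expected) <= 3 * sem


def test_ld_decays_with_genetic_distance():
    """Tightly linked pairs keep far more r^2 than pairs Morgans apart."""
    loci = pd.DataFrame(
        {
            "chrom": [1] * 6,
            "bp": [1_000_000, 1_010_000, 20_000_000, 20_010_000,
                   70_000_000, 95_000_000],
            "role": ["SNP"] * 6,
        }
    )

    def r2(h, i, j):
        a, b = h[:, i].astype(float), h[:, j].astype(float)
        if a.std() == 0 or b.std() == 0:
            return np.nan
        return np.corrcoef(a, b)[0, 1] ** 2

    adj, dist = [], []
    for rep in range(10):
        cfg = SimConfig(n_chromosomes=1, n_snps=6, n_qtls=0,
                        n_hist_generations=150, hist_pop_size=60,
                        seed=2000 + rep)
        pool = simulate_historical(cfg, loci=loci)
        h = pool.haplotypes.reshape(-1, 6)
        adj += [r2(h, 0, 1), r2(h, 2, 3)]
        dist += [r2(h, 0, 4), r2(h, 1, 5), r2(h, 2, 5)]
    assert np.nanmean(adj) > np.nanmean(dist)


# ---------------------------------------------------------------------------
# recent pedigreed phase


def test_genotyped_cohort_size_is_dams_times_genotyped_generations(tiny_population):
    pop, cfg = tiny_population
    assert pop.pedigree["genotyped"].sum() == cfg.n_dams * cfg.n_genotyped_generations


def test_single_generation_all_offspring_genotyped():
    cfg = tiny_config(3, n_snps=40, n_qtls=2, n_recent_generations=1,
                      n_genotyped_generations=1, hist_pop_size=60,
                      n_hist_generations=5, n_sires=3, n_dams=20)
    pop = simulate_recent(simulate_historical(cfg), cfg)
    off = pop.pedigree[pop.pedigree["generation"] > 0]
    assert off["genotyped"].all() and len(off) == 20


def test_parents_belong_to_earlier_rows(tiny_population):
    pop, _ = tiny_population
    ped = pop.pedigree
    id_gen = dict(zip(ped["id"], ped["generation"]))
    off = ped[ped["generation"] > 0]
    assert (off.apply(lambda r: id_gen[r["sire"]] < r["generation"], axis=1)).all()
    assert (off.apply(lambda r: id_gen[r["dam"]] < r["generation"], axis=1)).all()


def _mendelian_consistent(go, gs, gd):
    alleles = {0: {0}, 1: {0, 1}, 2: {1}}
    return any(a + b == go for a in alleles[gs] for b in alleles[gd])


def test_offspring_genotypes_are_mendelian_consistent():
    """Brute-force transmission check at every locus of a small pedigree
    (mutation off so inheritance is exact)."""
    cfg = tiny_config(17, n_snps=60, n_qtls=3, mutation_rate=0.0,
                      hist_pop_size=30, n_hist_generations=8,
                      n_sires=2, n_dams=8, n_recent_generations=2,
                      n_genotyped_generations=2)
    pop = simulate_recent(simulate_historical(cfg), cfg)
    G = pop.genotypes()
    row_of = {i: k for k, i in enumerate(pop.pedigree["id"])}
    off = pop.pedigree[pop.pedigree["generation"] > 0]
    for _, r in off.iterrows():
        go = G[row_of[r["id"]]]
        gs = G[row_of[r["sire"]]]
        gd = G[row_of[r["dam"]]]
        assert all(
            _mendelian_consistent(int(a), int(b), int(c))
            for a, b, c in zip(go, gs, gd)
        )


def test_same_seed_gives_identical_population():
    cfg = tiny_config(99, n_snps=50, n_qtls=4, hist_pop_size=40,
                      n_hist_generations=6, n_sires=3, n_dams=15,
                      n_recent_generations=2, n_genotyped_generations=1)

    def build():
        pop = simulate_recent(simulate_historical(cfg), cfg)
        eff = simpop.assign_effects(pop, cfg)
        simpop.compute_phenotypes(pop, eff, cfg)
        return pop

    a, b = build(), build()
    pd.testing.assert_frame_equal(a.pedigree, b.pedigree)
    assert np.array_equal(a.haplotypes, b.haplotypes)


def test_empty_founder_pool_is_an_error(tiny_population):
    _, cfg = tiny_population
    empty = simpop.FounderPool(
        haplotypes=np.empty((0, 2, 10), dtype=np.uint8),
        loci=place_loci(tiny_config(1, n_snps=8, n_qtls=2)),
        config=cfg,
    )
    with pytest.raises(SimulationError):
        simulate_recent(empty, cfg)


# ---------------------------------------------------------------------------
# effects and phenotypes


def test_qtl_score_variance_is_scaled_to_target(tiny_population):
    pop, cfg = tiny_population
    g = pop.pedigree[pop.pedigree["genotyped"]]
    share = g["qtl_score"].var(ddof=1)
    assert share == pytest.approx(cfg.h2_qtl * cfg.var_phenotypic, abs=1e-9)


def test_zero_qtl_heritability_gives_zero_effects():
    cfg = tiny_config(5, h2_qtl=0.0, n_snps=40, n_qtls=4, hist_pop_size=30,
                      n_hist_generations=5, n_sires=2, n_dams=10,
                      n_recent_generations=2, n_genotyped_generations=1)
    pop = simulate_recent(simulate_historical(cfg), cfg)
    eff = simpop.assign_effects(pop, cfg)
    assert np.all(eff == 0)


def test_single_locus_effect_matches_closed_form():
    """With one polymorphic QTL, |a| must equal sqrt(target / var(g))."""
    cfg = tiny_config(21, n_snps=30, n_qtls=1, hist_pop_size=40,
                      n_hist_generations=10, n_sires=2, n_dams=12,
                      n_recent_generations=2, n_genotyped_generations=2)
    pop = simulate_recent(simulate_historical(cfg), cfg)
    eff = simpop.assign_effects(pop, cfg)
    qtl_col = np.flatnonzero((pop.loci["role"] == "QTL").to_numpy())
    g = pop.haplotypes[pop.genotyped_rows][:, :, qtl_col].sum(axis=1).ravel()
    target = cfg.h2_qtl * cfg.var_phenotypic
    assert abs(eff[0]) == pytest.approx(np.sqrt(target / g.var(ddof=1)), rel=1e-9)


def test_monomorphic_qtls_cannot_be_scaled():
    cfg = tiny_config(2, n_snps=20, n_qtls=2, mutation_rate=0.0,
                      hist_pop_size=20, n_hist_generations=3, n_sires=2,
                      n_dams=8, n_recent_generations=1, n_genotyped_generations=1)
    pool = simulate_historical(cfg, founder_frequency=0.0)
    pop = simulate_recent(pool, cfg)
    with pytest.raises(DegenerateSimulationError):
        simpop.assign_effects(pop, cfg)


def test_pure_noise_trait_has_exactly_the_phenotypic_variance():
    cfg = tiny_config(13, h2_total=0.0, h2_qtl=0.0, n_snps=60, n_qtls=3,
                      hist_pop_size=40, n_hist_generations=5, n_sires=3,
                      n_dams=30, n_recent_generations=2, n_genotyped_generations=2)
    pop = simulate_recent(simulate_historical(cfg), cfg)
    eff = simpop.assign_effects(pop, cfg)
    simpop.compute_phenotypes(pop, eff, cfg)
    g = pop.pedigree[pop.pedigree["genotyped"]]
    # residual is variance-calibrated in-sample, so equality is near-exact
    assert g["phenotype"].var(ddof=1) == pytest.approx(cfg.var_phenotypic, abs=1e-9)
    assert (g["tbv"] == 0).all()


def test_fully_genetic_trait_equals_qtl_score():
    cfg = tiny_config(14, h2_total=1.0, h2_qtl=1.0, n_snps=60, n_qtls=5,
                      hist_pop_size=40, n_hist_generations=5, n_sires=3,
                      n_dams=30, n_recent_generations=2, n_genotyped_generations=2)
    pop = simulate_recent(simulate_historical(cfg), cfg)
    eff = simpop.assign_effects(pop, cfg)
    simpop.compute_phenotypes(pop, eff, cfg)
    assert np.allclose(pop.pedigree["phenotype"], pop.pedigree["qtl_score"])


def test_phenotype_variance_and_realized_heritability(tiny_population):
    pop, cfg = tiny_population
    g = pop.pedigree[pop.pedigree["genotyped"]]
    assert g["phenotype"].var(ddof=1) == pytest.approx(1.0, abs=0.12)
    # cov(y, tbv)/var(y) is the realized heritability of the sample
    h2 = np.cov(g["phenotype"], g["tbv"])[0, 1] / g["phenotype"].var(ddof=1)
    assert h2 == pytest.approx(cfg.h2_total, abs=0.1)


# ---------------------------------------------------------------------------
# subsampling


def test_subsample_is_deterministic_and_well_shaped(tiny_population):
    pop, _ = tiny_population
    a = subsample(pop, 50, seed=3)
    b = subsample(pop, 50, seed=3)
    assert list(a.genotypes.iids) == list(b.genotypes.iids)
    assert a.genotypes.genotypes.shape == (50, 1500)
    full = subsample(pop, int(pop.pedigree["genotyped"].sum()), seed=1)
    genotyped_ids = set(
        pop.pedigree.loc[pop.pedigree["genotyped"], "id"].astype(str)
    )
    assert set(full.genotypes.iids) == genotyped_ids


def test_subsample_larger_than_cohort_errors(tiny_population):
    pop, _ = tiny_population
    with pytest.raises(SimulationError):
        subsample(pop, 10_000, seed=1)
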