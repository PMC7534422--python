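"""Population simulation: meiosis, segregation, architectures, GBS noise."""

import math

import numpy as np
import pandas as pd
import pytest

from squashgs import simpop


def test_founders_are_opposite_homozygotes(small_map):
    a, b = simpop.make_founders(small_map.n_markers, small_map)
    assert np.all(a.haplotypes == 0) and np.all(b.haplotypes == 1)
    assert np.all(np.abs(a.dosage().astype(int) - b.dosage().astype(int)) == 2)
    f1 = simpop.cross(a, b, small_map, simpop.child_rng(0, 0))
    assert np.all(f1.dosage() == 1)  # forced heterozygosity everywhere


def test_founders_require_matching_map(small_map):
    with pytest.raises(ValueError):
        simpop.make_founders(small_map.n_markers + 1, small_map)


def test_meiosis_of_homozygote_returns_intact_haplotype(small_map):
    a, _ = simpop.make_founders(small_map.n_markers, small_map)
    gamete = simpop.meiosis(a, small_map, simpop.child_rng(1, 0))
    assert np.array_equal(gamete, a.haplotypes[0])


def test_meiosis_single_marker_chromosome_has_no_crossover():
    gmap = simpop.GeneticMap((("chr1", [50.0]),))
    g = simpop.Genome(np.array([[0], [1]], dtype=np.uint8))
    rng = simpop.child_rng(2, 0)
    gametes = [simpop.meiosis(g, gmap, rng)[0] for _ in range(200)]
    assert set(gametes) <= {0, 1}  # intact single-marker haplotypes


def test_recombination_fraction_matches_haldane():
    # two markers 100 cM apart: c = (1 - exp(-2)) / 2 ~ 0.4323
    gmap = simpop.GeneticMap((("chr1", [0.0, 100.0]),))
    het = simpop.Genome(np.array([[0, 0], [1, 1]], dtype=np.uint8))
    rng = simpop.child_rng(3, 0)
    n = 10_000
    rec = 0
    for _ in range(n):
        gam = simpop.meiosis(het, gmap, rng)
        rec += gam[0] != gam[1]
    c = 0.5 * (1.0 - math.exp(-2.0))
    se = math.sqrt(c * (1 - c) / n)
    assert abs(rec / n - c) < 3 * se


def test_f2_segregation_is_1_2_1():
    gmap = simpop.GeneticMap.uniform(2, 2, 100.0)
    founders = simpop.make_founders(4, gmap)
    pop = simpop.make_f2_population(founders, 10_000, gmap, simpop.child_rng(4, 0))
    d = pop.dosage_matrix()
    n = len(pop)
    for expected, value in ((0.25, 0), (0.5, 1), (0.25, 2)):
        freq = (d == value).mean(axis=0)
        se = math.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(freq - expected) < 3 * se)
    # mean allele frequency 0.5 per marker
    se_f = math.sqrt(0.5 * 0.5 / (2 * n))
    assert np.all(np.abs(d.mean(axis=0) / 2.0 - 0.5) < 3 * se_f)
    assert pop.generation == "C0"


def test_f2_population_of_one(small_map):
    founders = simpop.make_founders(small_map.n_markers, small_map)
    pop = simpop.make_f2_population(founders, 1, small_map, simpop.child_rng(5, 0))
    assert len(pop) == 1
    assert pop[0].dam_id == "F1" and pop[0].sire_id == "F1"


def test_random_mate_balances_progeny(f2_pop):
    dams = f2_pop.ids[:20]
    prog = simpop.random_mate(f2_pop, dams, 200, sires_per_dam=4, rng=simpop.child_rng(6, 0))
    counts = pd.Series([p.dam_id for p in prog.individuals]).value_counts()
    assert (counts == 10).all()
    assert prog.generation == "C1"
    sires = {p.sire_id for p in prog.individuals}
    assert sires <= set(dams)
    assert not any(p.dam_id == p.sire_id for p in prog.individuals)  # no selfing


def test_random_mate_single_parent_selfs(f2_pop):
    prog = simpop.random_mate(f2_pop, [f2_pop.ids[0]], 10, rng=simpop.child_rng(6, 1))
    assert all(p.dam_id == p.sire_id == f2_pop.ids[0] for p in prog.individuals)


def test_random_mate_sire_usage_is_uniform(small_map):
    founders = simpop.make_founders(small_map.n_markers, small_map)
    pop = simpop.make_f2_population(founders, 5, small_map, simpop.child_rng(7, 0))
    prog = simpop.random_mate(pop, pop.ids, 10_000, sires_per_dam=4, rng=simpop.child_rng(7, 1))
    counts = pd.Series([p.sire_id for p in prog.individuals]).value_counts()
    # each of 5 parents expected in 1/5 of matings
    se = math.sqrt(0.2 * 0.8 / 10_000)
    assert np.all(np.abs(counts / 10_000 - 0.2) < 3 * se)


def test_random_mate_rejects_empty_selection(f2_pop):
    with pytest.raises(ValueError):
        simpop.random_mate(f2_pop, [], 10, rng=simpop.child_rng(0, 0))


def test_architecture_variance_budget(small_map):
    arch = simpop.assign_architecture(small_map, [0.25], [0.55], rng=simpop.child_rng(8, 0))
    assert arch.sigma_u2[0] == pytest.approx(0.25)
    assert arch.sigma_p2[0] == pytest.approx(0.30)
    assert arch.sigma_e2[0] == pytest.approx(0.45)


def test_architecture_rejects_t_below_h2(small_map):
    with pytest.raises(ValueError):
        simpop.assign_architecture(small_map, [0.5], [0.3], rng=simpop.child_rng(8, 1))


def test_realized_additive_variance_hits_target(small_map):
    founders = simpop.make_founders(small_map.n_markers, small_map)
    pop = simpop.make_f2_population(founders, 2000, small_map, simpop.child_rng(9, 0))
    arch = simpop.assign_architecture(small_map, [0.25], [0.55], rng=simpop.child_rng(9, 1))
    u = arch.true_bv(pop.dosage_matrix())
    assert abs(u.var(ddof=1) - 0.25) < 0.025  # within 10% of sigma_u2


def test_identity_correlation_gives_uncorrelated_effects(small_map):
    arch = simpop.assign_architecture(small_map, [0.2, 0.3], [0.5, 0.6], np.eye(2),
                                      rng=simpop.child_rng(9, 2))
    r = np.corrcoef(arch.effects.T)[0, 1]
    assert abs(r) < 3 / math.sqrt(small_map.n_markers)


def test_fruit_intraclass_correlation_matches_repeatability(small_map):
    founders = simpop.make_founders(small_map.n_markers, small_map)
    pop = simpop.make_f2_population(founders, 500, small_map, simpop.child_rng(10, 0))
    arch = simpop.assign_architecture(small_map, [0.25], [0.55], rng=simpop.child_rng(10, 1),
                                      sites=("S1",))
    rec = simpop.simulate_records(pop, arch, simpop.child_rng(10, 2), n_fruit_range=(5, 5))
    # one-way ANOVA intraclass correlation over plants
    g = rec.groupby("plant")["trait1"]
    k = 5
    msb = g.mean().var(ddof=1) * k
    msw = (rec["trait1"] - rec["plant"].map(g.mean())).pow(2).sum() / (len(rec) - g.ngroups)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    assert abs(icc - 0.55) < 0.05


def test_plant_mean_variance_declines_with_fruit_number(small_map):
    founders = simpop.make_founders(small_map.n_markers, small_map)
    pop = simpop.make_f2_population(founders, 4000, small_map, simpop.child_rng(12, 0))
    arch = simpop.assign_architecture(small_map, [0.25], [0.55], rng=simpop.child_rng(12, 1),
                                      sites=("S1",))
    for n in (1, 4, 10):
        rec = simpop.simulate_records(pop, arch, simpop.child_rng(12, 2 + n),
                                      n_fruit_range=(n, n))
        v = simpop.plant_means(rec, ["trait1"])["trait1"].var(ddof=1)
        expected = 0.25 + 0.30 + 0.45 / n
        assert abs(v - expected) / expected < 0.10


def test_single_plant_single_fruit(small_map):
    founders = simpop.make_founders(small_map.n_markers, small_map)
    pop = simpop.make_f2_population(founders, 1, small_map, simpop.child_rng(13, 0))
    arch = simpop.assign_architecture(small_map, [0.25], [0.55], rng=simpop.child_rng(13, 1),
                                      sites=("S1",))
    rec = simpop.simulate_records(pop, arch, simpop.child_rng(13, 2), n_fruit_range=(1, 1))
    assert len(rec) == 1


def test_yield_traits_recorded_once_per_plant(small_map, f2_pop):
    arch = simpop.assign_architecture(
        small_map, [0.25, 0.12], [0.55, 0.45], rng=simpop.child_rng(14, 0),
        trait_names=["brix", "total_wt"], yield_traits=["total_wt"], sites=("S1",),
    )
    rec = simpop.simulate_records(f2_pop, arch, simpop.child_rng(14, 1))
    per_plant = rec.dropna(subset=["total_wt"]).groupby("plant").size()
    assert (per_plant == 1).all()
    assert rec.loc[rec["total_wt"].notna(), "fruit"].isna().all()
    fruit_rows = rec[rec["brix"].notna()]
    assert fruit_rows.groupby("plant").size().between(4, 6).all()


def test_degrade_identity_at_high_depth(f2_pop):
    d = f2_pop.dosage_matrix()
    out, depth = simpop.degrade_genotypes(d, simpop.child_rng(15, 0), miss_rate=0.0,
                                          depth_lambda=1000.0, min_depth=2)
    assert np.array_equal(out, d)


def test_degrade_missing_fraction_matches_poisson_tail(f2_pop):
    d = f2_pop.dosage_matrix()
    out, _ = simpop.degrade_genotypes(d, simpop.child_rng(15, 1), miss_rate=0.0,
                                      depth_lambda=3.0, min_depth=2, het_miscall=False)
    expected = math.exp(-3.0) * 4.0  # P(Poisson(3) < 2)
    frac = (out == -1).mean()
    se = math.sqrt(expected * (1 - expected) / out.size)
    assert abs(frac - expected) < 3 * se


def test_degrade_all_missing_at_rate_one(f2_pop):
    out, _ = simpop.degrade_genotypes(f2_pop.dosage_matrix(), simpop.child_rng(15, 2),
                                      miss_rate=1.0)
    assert np.all(out == -1)


def test_stochastic_operations_are_bit_reproducible(small_map):
    founders = simpop.make_founders(small_map.n_markers, small_map)

    def run():
        pop = simpop.make_f2_population(founders, 30, small_map, simpop.child_rng(16, 0))
        arch = simpop.assign_architecture(small_map, [0.2], [0.5], rng=simpop.child_rng(16, 1))
        rec = simpop.simulate_records(pop, arch, simpop.child_rng(16, 2))
        deg, _ = simpop.degrade_genotypes(pop.dosage_matrix(), simpop.child_rng(16, 3),
                                          miss_rate=0.1, depth_lambda=4.0)
        return pop.dosage_matrix(), rec, deg

    d1, r1, g1 = run()
    d2, r2, g2 = run()
    assert np.array_equal(d1, d2) and np.array_equal(g1, g2)
    pd.testing.assert_frame_equal(r1, r2)


def test_phenotype_csv_round_trip(tmp_path, sim_trait_data):
    _, records = sim_trait_data
    path = tmp_path / "pheno.csv"
    simpop.write_phenotypes(records, path)
    back = simpop.read_phenotypes(path)
    assert list(back.columns) == list(records.columns)
    assert len(back) == len(records)
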