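"""REML engine: closed-form equivalences, monotonicity, recovery, tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from squashgs import markers, mixedmodel, simpop
from squashgs.mixedmodel import ModelSpec, RandomTerm


def _group_design(n_groups, reps):
    Z = np.kron(np.eye(n_groups), np.ones((reps, 1)))
    return Z


def test_balanced_one_way_matches_anova_closed_form():
    """In a balanced one-way layout REML equals the ANOVA (MS-based) estimators."""
    rng = simpop.child_rng(30, 0)
    g, r = 10, 5
    effects = rng.normal(0, math.sqrt(2.0), g)
    y = np.repeat(effects, r) + rng.normal(0, 1.0, g * r)
    Z = _group_design(g, r)
    spec = ModelSpec(y=y, X=np.ones((g * r, 1)), random=[RandomTerm(Z=Z, name="group")])
    fit = mixedmodel.reml_fit(spec, method="em", tol=1e-12)
    means = y.reshape(g, r).mean(axis=1)
    msb = r * means.var(ddof=1)
    msw = (y.reshape(g, r) - means[:, None]).ravel() @ (y.reshape(g, r) - means[:, None]).ravel() / (g * (r - 1))
    assert fit.variances["residual"] == pytest.approx(msw, abs=1e-6)
    assert fit.variances["group"] == pytest.approx((msb - msw) / r, abs=1e-6)


def test_profiled_solver_agrees_with_em_on_random_instances():
    for i in range(10):
        rng = simpop.child_rng(31, i)
        n = 30
        gmap = simpop.GeneticMap.uniform(2, 15, 100.0)
        pop = simpop.make_f2_population(simpop.make_founders(30, gmap), n, gmap, rng)
        K = markers.vanraden_grm(pop.dosage_matrix().astype(float)).K
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        y = 1.0 + 0.8 * (L @ rng.standard_normal(n)) + 0.7 * rng.standard_normal(n)
        spec = ModelSpec(y=y, X=np.ones((n, 1)),
                         random=[RandomTerm(Z=np.eye(n), cov=K, name="g")])
        fp = mixedmodel.reml_fit(spec, method="profile")
        fe = mixedmodel.reml_fit(spec, method="em", tol=1e-11)
        h2 = lambda f: f.variances["g"] / (f.variances["g"] + f.variances["residual"])
        assert abs(h2(fp) - h2(fe)) < 1e-4


@pytest.mark.parametrize("accelerate", [False, True])
def test_em_loglik_history_is_monotone(accelerate, sim_trait_data, f2_kinship):
    _, records = sim_trait_data
    fit = mixedmodel.repeatability_fit(records, "brix", f2_kinship, accelerate=accelerate)
    h = np.asarray(fit.loglik_history)
    assert np.all(np.diff(h) >= -1e-9)
    assert fit.converged


def test_null_genetic_variance_estimates_near_zero():
    """Pure-noise phenotypes: the genetic variance collapses toward zero."""
    gmap = simpop.GeneticMap.uniform(5, 20, 100.0)
    pop = simpop.make_f2_population(simpop.make_founders(100, gmap), 200, gmap,
                                    simpop.child_rng(32, 0))
    K = markers.vanraden_grm(pop.dosage_matrix().astype(float)).K
    hits = 0
    n_seeds = 50
    for s in range(n_seeds):
        rng = simpop.child_rng(33, s)
        y = rng.standard_normal(200)
        spec = ModelSpec(y=y, X=np.ones((200, 1)),
                         random=[RandomTerm(Z=np.eye(200), cov=K, name="g")])
        fit = mixedmodel.reml_fit(spec, method="profile")
        hits += fit.variances["g"] <= 0.05
    assert hits >= 0.9 * n_seeds


def test_restricted_loglik_beats_perturbed_grid_points():
    """The EM optimum dominates a local grid of perturbed parameter points."""
    from squashgs.cli import restricted_loglik_direct

    rng = simpop.child_rng(34, 0)
    n = 20
    gmap = simpop.GeneticMap.uniform(2, 10, 100.0)
    pop = simpop.make_f2_population(simpop.make_founders(20, gmap), n, gmap, rng)
    K = markers.vanraden_grm(pop.dosage_matrix().astype(float)).K
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    y = 0.3 + 0.7 * (L @ rng.standard_normal(n)) + 0.6 * rng.standard_normal(n)
    X = np.ones((n, 1))
    spec = ModelSpec(y=y, X=X, random=[RandomTerm(Z=np.eye(n), cov=K, name="g")])
    fit = mixedmodel.reml_fit(spec, method="em", tol=1e-12)
    su, se = fit.variances["g"], fit.variances["residual"]
    ll_opt = restricted_loglik_direct(y, X, su * K + se * np.eye(n))
    for fu in (0.7, 1.0, 1.4):
        for fe in (0.7, 1.0, 1.4):
            if fu == fe == 1.0:
                continue
            ll = restricted_loglik_direct(y, X, fu * su * K + fe * se * np.eye(n))
            assert ll <= ll_opt + 1e-8


def test_repeatability_requires_repeated_measures(f2_kinship, f2_pop, small_map):
    arch = simpop.assign_architecture(small_map, [0.25], [0.55],
                                      rng=simpop.child_rng(35, 0), sites=("S1",))
    rec = simpop.simulate_records(f2_pop, arch, simpop.child_rng(35, 1), n_fruit_range=(1, 1))
    with pytest.raises(ValueError, match="confounded"):
        mixedmodel.repeatability_fit(rec, "trait1", f2_kinship)


def test_duplicating_records_shrinks_residual_only(sim_trait_data, f2_kinship):
    _, records = sim_trait_data
    fit1 = mixedmodel.repeatability_fit(records, "brix", f2_kinship)
    doubled = pd.concat([records, records.assign(fruit=records["fruit"] + 100)],
                        ignore_index=True)
    fit2 = mixedmodel.repeatability_fit(doubled, "brix", f2_kinship)
    assert fit2.sigma_e2 == pytest.approx(fit1.sigma_e2, rel=0.15)
    between1 = fit1.sigma_u2 + fit1.sigma_p2
    between2 = fit2.sigma_u2 + fit2.sigma_p2
    assert between2 == pytest.approx(between1, rel=0.10)


def test_blup_shrinks_to_zero_without_genetic_signal(f2_kinship):
    rng = simpop.child_rng(36, 0)
    plants = list(f2_kinship.ids)
    rec = pd.DataFrame({
        "plant": np.repeat(plants, 3),
        "site": "S1",
        "brix": rng.standard_normal(3 * len(plants)),
    })
    fit = mixedmodel.repeatability_fit(rec, "brix", f2_kinship)
    bv = mixedmodel.blup(fit)
    assert np.abs(bv["brix"]).max() < 0.15  # shrinkage toward the mean


def test_blup_with_identity_k_preserves_plant_mean_ranking(f2_pop, small_map):
    arch = simpop.assign_architecture(small_map, [0.3], [0.6],
                                      rng=simpop.child_rng(37, 0), sites=("S1",))
    rec = simpop.simulate_records(f2_pop, arch, simpop.child_rng(37, 1), n_fruit_range=(4, 4))
    K_I = markers.Kinship(ids=np.asarray(f2_pop.ids, dtype=object), K=np.eye(len(f2_pop)))
    fit = mixedmodel.repeatability_fit(rec, "trait1", K_I)
    bv = mixedmodel.blup(fit)["trait1"]
    pm = simpop.plant_means(rec, ["trait1"]).set_index("plant")["trait1"]
    order_bv = bv.loc[pm.index].rank()
    assert (order_bv == pm.rank()).all()


def test_blup_predicts_unphenotyped_relatives(small_map):
    founders = simpop.make_founders(small_map.n_markers, small_map)
    pop = simpop.make_f2_population(founders, 250, small_map, simpop.child_rng(38, 0))
    arch = simpop.assign_architecture(small_map, [0.3], [0.6],
                                      rng=simpop.child_rng(38, 1), sites=("S1",))
    rec = simpop.simulate_records(pop, arch, simpop.child_rng(38, 2))
    K = markers.vanraden_grm(pop.dosage_matrix().astype(float), ids=pop.ids)
    masked = rec[rec["plant"].isin(set(pop.ids[:200]))]
    fit = mixedmodel.repeatability_fit(masked, "trait1", K)
    bv = mixedmodel.blup(fit)["trait1"]
    truth = arch.true_bv(pop.dosage_matrix())[:, 0]
    unpheno = pop.ids[200:]
    r, p = stats.pearsonr(bv.loc[unpheno], truth[200:])
    assert r > 0 and p < 0.01


def test_mt_diagonal_loglik_never_exceeds_unstructured(sim_trait_data, f2_pop, small_map, f2_kinship):
    arch = simpop.assign_architecture(small_map, [0.25, 0.25], [0.55, 0.55],
                                      np.array([[1, 0.7], [0.7, 1]]),
                                      rng=simpop.child_rng(39, 0), sites=("S1", "S2"))
    rec = simpop.simulate_records(f2_pop, arch, simpop.child_rng(39, 1))
    full = mixedmodel.mt_reml_fit(rec, ["trait1", "trait2"], f2_kinship)
    red = mixedmodel.mt_reml_fit(rec, ["trait1", "trait2"], f2_kinship, structure="diagonal")
    assert red.loglik <= full.loglik + 1e-6
    assert np.allclose(red.G, np.diag(np.diag(red.G)))
    stat, df, p = mixedmodel.lrt(full, red)
    assert df == 1 and stat >= 0
    # G and R symmetric, PSD after bending
    for M in (full.G, full.R, red.G, red.R):
        assert np.allclose(M, M.T, atol=1e-10)
        assert np.linalg.eigvalsh(M).min() > -1e-10


def test_mt_independent_traits_have_small_genetic_correlation(small_map, f2_pop, f2_kinship):
    rgs = []
    for s in range(8):
        arch = simpop.assign_architecture(small_map, [0.3, 0.3], [0.6, 0.6], np.eye(2),
                                          rng=simpop.child_rng(40, s), sites=("S1",))
        rec = simpop.simulate_records(f2_pop, arch, simpop.child_rng(41, s))
        fit = mixedmodel.mt_reml_fit(rec, ["trait1", "trait2"], f2_kinship)
        g = fit.G
        rgs.append(g[0, 1] / math.sqrt(max(g[0, 0] * g[1, 1], 1e-12)))
    mean_rg = np.mean(rgs)
    assert abs(mean_rg) < 3 * np.std(rgs, ddof=1) / math.sqrt(len(rgs)) + 0.1


def test_lrt_identical_fits_and_optimizer_failure(sim_trait_data, f2_kinship):
    _, records = sim_trait_data
    rng = simpop.child_rng(44, 0)
    rec = records.rename(columns={"brix": "t1"})
    rec = rec.assign(t2=rec["t1"] * 0.5 + rng.normal(0, 0.8, len(rec)))
    full = mixedmodel.mt_reml_fit(rec, ["t1", "t2"], f2_kinship)
    stat, df, p = mixedmodel.lrt(full, full)
    assert stat == 0.0 and p == 1.0
    red = mixedmodel.mt_reml_fit(rec, ["t1", "t2"], f2_kinship, structure="diagonal")
    with pytest.raises(ValueError, match="optimizer failure"):
        mixedmodel.lrt(red, full)  # reversed: 'full' loglik below 'reduced'


def test_wald_f_is_scale_invariant():
    rng = simpop.child_rng(42, 0)
    n = 60
    groups = np.repeat(np.arange(6), 10)
    Z = pd.get_dummies(groups).to_numpy(float)
    x = rng.normal(size=n)
    y = 0.4 * x + Z @ rng.normal(0, 0.5, 6) + rng.normal(0, 1, n)
    spec = ModelSpec(y=y, X=np.column_stack([np.ones(n), x]), x_names=["intercept", "slope"],
                     random=[RandomTerm(Z=Z, name="block")])
    fit = mixedmodel.reml_fit(spec, method="em")
    F1, ddf1, p1 = mixedmodel.wald_f(fit, "slope")
    spec2 = ModelSpec(y=2.0 * y, X=spec.X, x_names=spec.x_names,
                      random=[RandomTerm(Z=Z, name="block")])
    fit2 = mixedmodel.reml_fit(spec2, method="em")
    F2, ddf2, p2 = mixedmodel.wald_f(fit2, "slope")
    assert F1 == pytest.approx(F2, rel=1e-4)
    assert ddf1 == ddf2 == n - 2 - 6  # containment df
    with pytest.raises(ValueError):
        mixedmodel.wald_f(fit, "absent")


def test_translation_equivariance_of_predictions(sim_trait_data, f2_kinship):
    _, records = sim_trait_data
    fit = mixedmodel.repeatability_fit(records, "brix", f2_kinship)
    shifted = records.assign(brix=records["brix"] + 7.0)
    fit2 = mixedmodel.repeatability_fit(shifted, "brix", f2_kinship)
    bv1 = mixedmodel.blup(fit)["brix"]
    bv2 = mixedmodel.blup(fit2)["brix"]
    assert np.allclose(bv1, bv2, atol=1e-5)  # the intercept absorbs the shift


def test_aliased_fixed_columns_are_dropped():
    rng = simpop.child_rng(43, 0)
    n = 40
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x, 2 * x])  # third column aliased
    y = 1.0 + x + rng.normal(0, 1, n)
    Z = pd.get_dummies(np.repeat(np.arange(4), 10)).to_numpy(float)
    spec = ModelSpec(y=y, X=X, x_names=["intercept", "x", "x2"],
                     random=[RandomTerm(Z=Z, name="g")])
    fit = mixedmodel.reml_fit(spec, method="em")
    assert len(fit.x_names) == 2
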