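"""Selection indices, culling rules and the recurrent genomic-selection driver.

Two index modes are supported: the equal-weight GEBV index
``I = sum_t a_t GEBV_t`` used for within-program genomic selection, and the
Smith-Hazel phenotypic index ``b = P^-1 G a`` used when candidates carry
phenotypes but no marker data (e.g. realized-gain trials).

``run_recurrent_gs`` executes the full scheme on synthetic data: a base
population selected by independent culling on single-plant phenotypes,
followed by cycles of genomic selection on a multi-trait GBLUP index with
the model retrained whenever a field generation provides new phenotypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import markers, mixedmodel, simpop

log = logging.getLogger(__name__)

__all__ = [
    "smith_hazel",
    "gebv_index",
    "select_fraction",
    "independent_cull",
    "SelectionResult",
    "RecurrentGSConfig",
    "run_recurrent_gs",
]


def smith_hazel(P: np.ndarray, G: np.ndarray, a) -> np.ndarray:
    """Smith-Hazel index coefficients ``b = P^-1 G a``.

    ``P`` is the phenotypic and ``G`` the genetic covariance matrix of the
    component traits; ``a`` holds the economic weights.
    """
    P = np.asarray(P, float)
    G = np.asarray(G, float)
    a = np.asarray(a, float).ravel()
    if P.shape != G.shape or P.shape[0] != a.size:
        raise ValueError("P, G and a have inconsistent dimensions")
    if not np.allclose(G, G.T):
        raise ValueError("G must be symmetric")
    ev = np.linalg.eigvalsh(0.5 * (P + P.T))
    if ev.min() <= 0:
        cond = np.inf if ev.min() <= 0 else ev.max() / ev.min()
        raise ValueError(f"P is singular or indefinite (condition number {cond:.3g})")
    return np.linalg.solve(P, G @ a)


def gebv_index(bv: pd.DataFrame, a=None) -> pd.Series:
    """Per-individual index ``I = sum_t a_t GEBV_t`` (equal weights default)."""
    if a is None:
        a = np.ones(bv.shape[1])
    a = np.asarray(a, float).ravel()
    if a.size != bv.shape[1]:
        raise ValueError("weight vector length does not match traits")
    if bv.isna().any().any():
        raise ValueError("missing GEBV for at least one individual/trait")
    return pd.Series(bv.to_numpy() @ a, index=bv.index, name="index")


@dataclass
class SelectionResult:
    """Ranked candidates, the selected id set and the realized fraction."""

    table: pd.DataFrame  # columns: id, index, rank, selected
    selected_ids: list
    fraction: float
    shortfall: int = 0


def select_fraction(index_values: pd.Series, fraction: float) -> SelectionResult:
    """Truncation selection of the top ``ceil(fraction * n)`` candidates.

    Descending index order; ties broken by ascending individual id so the
    selected set is deterministic and invariant to input row order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(index_values) == 0:
        raise ValueError("no candidates to select from")
    df = pd.DataFrame({"id": index_values.index.astype(str), "index": index_values.to_numpy(float)})
    df = df.sort_values(["index", "id"], ascending=[False, True], kind="mergesort").reset_index(drop=True)
    n_sel = math.ceil(fraction * len(df))
    df["rank"] = np.arange(1, len(df) + 1)
    df["selected"] = df["rank"] <= n_sel
    return SelectionResult(table=df, selected_ids=df.loc[df["selected"], "id"].tolist(), fraction=fraction)


def independent_cull(
    summaries: pd.DataFrame,
    top_traits,
    yield_trait: str,
    top_frac: float = 0.20,
    bottom_frac: float = 0.50,
    target_n: int | None = None,
) -> SelectionResult:
    """Phenotypic independent culling for the base population.

    Eligible plants sit in the top ``top_frac`` for every listed trait
    (value >= the (1 - top_frac) quantile, inclusive) and not in the bottom
    ``bottom_frac`` for yield.  When more than ``target_n`` qualify, the
    eligibles are ranked by mean within-trait rank over all four criteria
    and truncated; a shortfall returns every eligible plant with the
    deficit logged.
    """
    top_traits = list(top_traits)
    for tr in top_traits + [yield_trait]:
        if tr not in summaries.columns:
            raise ValueError(f"trait {tr!r} missing from plant summaries")
    idx = summaries.index.astype(str)
    ok = pd.Series(True, index=summaries.index)
    for tr in top_traits:
        thr = np.quantile(summaries[tr].to_numpy(float), 1.0 - top_frac)  # type-7 interpolation
        ok &= summaries[tr] >= thr
    if bottom_frac > 0:
        thr_y = np.quantile(summaries[yield_trait].to_numpy(float), bottom_frac)
        ok &= summaries[yield_trait] >= thr_y
    eligible = summaries.loc[ok].copy()
    shortfall = 0
    if target_n is not None and len(eligible) > target_n:
        ranks = pd.DataFrame(
            {tr: eligible[tr].rank(ascending=False, method="average") for tr in top_traits + [yield_trait]}
        )
        eligible["_mean_rank"] = ranks.mean(axis=1)
        eligible["_id"] = eligible.index.astype(str)
        eligible = eligible.sort_values(["_mean_rank", "_id"], kind="mergesort").head(target_n)
    elif target_n is not None and len(eligible) < target_n:
        shortfall = target_n - len(eligible)
        log.warning("independent_cull: only %d eligible plants for target %d", len(eligible), target_n)
    sel = sorted(eligible.index.astype(str))
    table = pd.DataFrame({"id": idx, "selected": idx.isin(sel)})
    return SelectionResult(table=table, selected_ids=sel,
                           fraction=len(sel) / max(len(summaries), 1), shortfall=shortfall)


# ---------------------------------------------------------------------------
# recurrent genomic selection on synthetic populations


def _default_g_corr() -> np.ndarray:
    # index traits (brix, pct_dm, a_star) plus yield; pattern of moderate
    # favorable quality-quality and unfavorable quality-yield correlations
    return np.array(
        [
            [1.00, 0.93, 0.24, -0.40],
            [0.93, 1.00, 0.32, -0.24],
            [0.24, 0.32, 1.00, -0.17],
            [-0.40, -0.24, -0.17, 1.00],
        ]
    )


@dataclass
class RecurrentGSConfig:
    """Study conditions for the recurrent-GS driver.

    Defaults emulate a small squash program: ~200 plants per generation,
    three fruit-quality index traits with low heritabilities and one yield
    trait, genotyping-by-sequencing noise, 10% selection on an equal-weight
    GEBV index, and model training at the field generations (cycles 0 and 2).
    """

    n_plants: int = 200
    n_chrom: int = 20
    markers_per_chrom: int = 60
    chrom_length_cm: float = 100.0
    index_traits: tuple = ("brix", "pct_dm", "a_star")
    yield_trait: str = "total_wt"
    h2: tuple = (0.10, 0.13, 0.23, 0.12)
    t: tuple = (0.45, 0.51, 0.62, 0.45)
    g_corr: np.ndarray = field(default_factory=_default_g_corr)
    sites: tuple = ("S1", "S2")
    site_sd: float = 0.5
    n_fruit_range: tuple = (4, 6)
    cycles: int = 3
    fraction: float = 0.10
    sires_per_dam: int = 4
    retrain_at: tuple = (0, 2)
    cull_top_frac: float = 0.20
    cull_bottom_frac: float = 0.50
    use_gbs_noise: bool = True
    miss_rate: float = 0.05
    depth_lambda: float = 7.0
    min_depth: int = 2
    qc_maf_min: float = 0.05
    qc_max_marker_missing: float = 0.2
    qc_max_ind_missing: float = 0.4


@dataclass
class RecurrentGSResult:
    trajectory: pd.DataFrame
    config: RecurrentGSConfig
    architecture: simpop.TraitArchitecture


def _genotype(pop, gmap, cfg: RecurrentGSConfig, rng) -> markers.GenotypeMatrix:
    dos = pop.dosage_matrix()
    if cfg.use_gbs_noise:
        dos, depth = simpop.degrade_genotypes(
            dos, rng, miss_rate=cfg.miss_rate, depth_lambda=cfg.depth_lambda, min_depth=cfg.min_depth
        )
        return markers.GenotypeMatrix(ids=np.asarray(pop.ids, dtype=object),
                                      markers=gmap.marker_table(), dosage=dos, depth=depth)
    return markers.GenotypeMatrix(ids=np.asarray(pop.ids, dtype=object),
                                  markers=gmap.marker_table(), dosage=dos)


def _joint_grm(train_geno, cand_geno, cfg: RecurrentGSConfig) -> markers.Kinship:
    merged = markers.merge_common(train_geno, cand_geno)
    filtered, _ = markers.qc_filter(
        merged, maf_min=cfg.qc_maf_min,
        max_marker_missing=cfg.qc_max_marker_missing,
        max_ind_missing=cfg.qc_max_ind_missing,
    )
    imputed = markers.mean_impute(filtered)
    return markers.vanraden_grm(imputed, ids=filtered.ids)


def run_recurrent_gs(config: RecurrentGSConfig | None = None, seed: int = 0, **overrides) -> RecurrentGSResult:
    """Phenotypic culling at cycle 0, then GS cycles on a GEBV index.

    Tracks per generation the mean and SD of the true index breeding value
    (the sum of true BVs over the index traits), the realized selection
    differential, and the mean GEBV index of candidates where a model was
    used.  ``fraction=1.0`` is the drift-only control (everything mates).
    """
    cfg = config or RecurrentGSConfig(**overrides)
    if config is not None and overrides:
        raise ValueError("pass either a config object or keyword overrides, not both")
    gmap = simpop.GeneticMap.uniform(cfg.n_chrom, cfg.markers_per_chrom, cfg.chrom_length_cm)
    all_traits = tuple(cfg.index_traits) + (cfg.yield_trait,)
    rng_pop = simpop.child_rng(seed, 0)
    rng_arch = simpop.child_rng(seed, 1)
    rng_pheno = simpop.child_rng(seed, 2)
    rng_geno = simpop.child_rng(seed, 3)
    rng_mate = simpop.child_rng(seed, 4)

    founders = simpop.make_founders(gmap.n_markers, gmap)
    pop = simpop.make_f2_population(founders, cfg.n_plants, gmap, rng_pop)
    arch = simpop.assign_architecture(
        gmap, cfg.h2, cfg.t, cfg.g_corr, rng_arch,
        trait_names=all_traits, sites=cfg.sites, site_sd=cfg.site_sd,
        yield_traits=(cfg.yield_trait,),
    )
    a_equal = np.ones(len(cfg.index_traits))

    def true_index(p) -> np.ndarray:
        bv = arch.true_bv(p.dosage_matrix())
        cols = [all_traits.index(tr) for tr in cfg.index_traits]
        return bv[:, cols] @ a_equal

    rows = []
    trained = {}  # cycle -> (records, genotype matrix); filled at field generations
    for cycle in range(cfg.cycles + 2):  # C0 .. C(cycles+1)
        ti = true_index(pop)
        row = {
            "generation": pop.generation,
            "cycle": cycle,
            "n": len(pop),
            "mean_true_index": float(ti.mean()),
            "sd_true_index": float(ti.std(ddof=1)),
            "mean_index_gebv": np.nan,
            "selection_differential": np.nan,
        }
        if cycle == cfg.cycles + 1:
            rows.append(row)
            break  # final population is evaluated, not selected

        if cycle == 0:
            records = simpop.simulate_records(pop, arch, rng_pheno, sites=cfg.sites,
                                              n_fruit_range=cfg.n_fruit_range)
            pm = simpop.plant_means(records, list(all_traits)).set_index("plant")
            target = math.ceil(cfg.fraction * len(pop))
            if cfg.fraction >= 1.0:
                selected = list(pop.ids)
            else:
                cull = independent_cull(
                    pm, cfg.index_traits, cfg.yield_trait,
                    top_frac=cfg.cull_top_frac, bottom_frac=cfg.cull_bottom_frac,
                    target_n=target,
                )
                selected = list(cull.selected_ids)
                if len(selected) < target:
                    # top up to the target count with the best remaining plants
                    # by mean within-trait rank over the culling criteria
                    crit = list(cfg.index_traits) + [cfg.yield_trait]
                    ranks = pd.DataFrame(
                        {tr: pm[tr].rank(ascending=False, method="average") for tr in crit}
                    ).mean(axis=1)
                    pool = ranks.drop(index=selected).sort_values(kind="mergesort")
                    selected += [str(i) for i in pool.index[: target - len(selected)]]
            if cycle in cfg.retrain_at:
                trained[cycle] = (records, _genotype(pop, gmap, cfg, rng_geno))
        else:
            if cycle in cfg.retrain_at:
                # field generation: phenotype and genotype for later retraining
                records = simpop.simulate_records(pop, arch, rng_pheno, sites=cfg.sites,
                                                  n_fruit_range=cfg.n_fruit_range)
                trained[cycle] = (records, _genotype(pop, gmap, cfg, rng_geno))
            # selection uses the newest model trained at an earlier cycle
            usable = [r for r in trained if r < cycle]
            if not usable:
                raise ValueError("no trained model available before the first GS cycle")
            train_records, train_geno = trained[max(usable)]
            cand_geno = trained[cycle][1] if cycle in trained else _genotype(pop, gmap, cfg, rng_geno)
            K = _joint_grm(train_geno, cand_geno, cfg)
            k_ids = set(K.ids)
            fit = mixedmodel.mt_reml_fit(
                train_records[train_records["plant"].isin(k_ids)], list(cfg.index_traits), K
            )
            bv = mixedmodel.blup(fit)
            cand_bv = bv.loc[[i for i in pop.ids if i in k_ids]]
            gebv_i = gebv_index(cand_bv, a_equal)
            row["mean_index_gebv"] = float(gebv_i.mean())
            if cfg.fraction >= 1.0:
                selected = list(gebv_i.index)
            else:
                selected = select_fraction(gebv_i, cfg.fraction).selected_ids

        sel_pos = [pop.ids.index(s) for s in selected]
        row["selection_differential"] = float(ti[sel_pos].mean() - ti.mean())
        rows.append(row)
        pop = simpop.random_mate(pop, selected, cfg.n_plants,
                                 sires_per_dam=cfg.sires_per_dam, rng=rng_mate)
    traj = pd.DataFrame(rows)
    return RecurrentGSResult(trajectory=traj, config=cfg, architecture=arch)


def _grm_single(geno, cfg: RecurrentGSConfig) -> markers.Kinship:
    filtered, _ = markers.qc_filter(
        geno, maf_min=cfg.qc_maf_min,
        max_marker_missing=cfg.qc_max_marker_missing,
        max_ind_missing=cfg.qc_max_ind_missing,
    )
    return markers.vanraden_grm(markers.mean_impute(filtered), ids=filtered.ids)
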