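"""Cross-validation of genomic prediction models and realized-gain analysis.

Three validation schemes mirror how a breeding program interrogates a
GBLUP model: ``within_cv`` (repeated random 80/20 splits inside one set,
identical partitions reused across traits), ``across_cv`` (train on one
population, predict progeny or relatives), and ``stratified_cv`` (equal
draws from several sets to probe the effect of training-population size).
Predictive ability is the Pearson correlation between GEBVs of masked
individuals and their plant-mean phenotypes.

``gain_model_fit`` estimates realized gain per selection cycle from
multi-environment trial data: random site, block-within-site with
heterogeneous per-site variances, plot-within-block only at sites with
intra-block replication, a fixed numeric cycle covariate whose slope is the
per-cycle gain, and residual variances grouped by harvesting method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import markers, simpop
from .mixedmodel import ModelSpec, RandomTerm, reml_fit, wald_f, _design_from_factor

log = logging.getLogger(__name__)

__all__ = [
    "predictive_ability",
    "within_cv",
    "across_cv",
    "stratified_cv",
    "phenotypic_index",
    "GainFit",
    "gain_model_fit",
    "simulate_gain_trial",
]


def predictive_ability(gebv, truth) -> float:
    """Pearson correlation between predicted and observed (masked) values."""
    gebv = np.asarray(gebv, float)
    truth = np.asarray(truth, float)
    if gebv.size != truth.size or gebv.size < 3:
        raise ValueError("need at least 3 aligned (gebv, truth) pairs")
    if np.std(gebv) <= 0 or np.std(truth) <= 0:
        raise ValueError("constant vector: predictive ability undefined")
    return float(stats.pearsonr(gebv, truth)[0])


def _as_kinship(geno_or_K) -> markers.Kinship:
    if isinstance(geno_or_K, markers.Kinship):
        return geno_or_K
    if isinstance(geno_or_K, markers.GenotypeMatrix):
        return markers.vanraden_grm(markers.mean_impute(geno_or_K), ids=geno_or_K.ids)
    raise TypeError("expected a GenotypeMatrix or Kinship")


def _gblup_predict(K: markers.Kinship, pm: pd.DataFrame, trait: str, train_plants) -> pd.Series:
    """Plain GBLUP on training plant means; GEBVs for every id in K."""
    sub = pm[pm["plant"].isin(train_plants)].dropna(subset=[trait]).sort_values("plant")
    pos = {v: i for i, v in enumerate(K.ids)}
    obs_idx = np.array([pos[p] for p in sub["plant"]])
    K_obs = K.K[np.ix_(obs_idx, obs_idx)]
    if sub["site"].nunique() > 1:
        X, names = _design_from_factor(sub["site"])
    else:
        X, names = np.ones((len(sub), 1)), ["intercept"]
    spec = ModelSpec(y=sub[trait].to_numpy(float), X=X, x_names=names,
                     random=[RandomTerm(Z=np.eye(len(sub)), cov=K_obs, name="genetic")])
    fit = reml_fit(spec, method="profile")
    u = fit.variances["genetic"] * (K.K[:, obs_idx] @ fit.w)
    return pd.Series(u, index=pd.Index(K.ids, name="id"))


def within_cv(
    geno_or_K,
    records: pd.DataFrame,
    traits,
    test_frac: float = 0.2,
    reps: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated random train/test splits within one population.

    Per replicate, ``test_frac`` of the phenotyped plants are masked, a
    GBLUP model is trained on the rest, and PA is the Pearson correlation
    between GEBVs and plant means in the masked set.  The same random
    partitions are used for every trait.  Replicates with an undefined
    correlation (constant fold) are recorded as missing with a warning.
    """
    K = _as_kinship(geno_or_K)
    traits = list(traits)
    pm = simpop.plant_means(records, traits)
    pm = pm[pm["plant"].isin(set(K.ids))].sort_values("plant").reset_index(drop=True)
    q = len(pm)
    if q < 10:
        raise ValueError("need at least 10 phenotyped, genotyped plants")
    n_test = max(1, int(round(test_frac * q)))
    rng = simpop.child_rng(seed, 10)
    rows = []
    for rep in range(reps):
        perm = rng.permutation(q)
        test_mask = np.zeros(q, dtype=bool)
        test_mask[perm[:n_test]] = True
        train_plants = set(pm.loc[~test_mask, "plant"])
        for trait in traits:
            gebv = _gblup_predict(K, pm, trait, train_plants)
            test = pm.loc[test_mask & pm[trait].notna(), ["plant", trait]]
            try:
                pa = predictive_ability(gebv.loc[test["plant"]].to_numpy(), test[trait].to_numpy())
            except ValueError:
                log.warning("within_cv rep %d trait %s: undefined PA (constant fold)", rep, trait)
                pa = np.nan
            rows.append({"scheme": "within", "trait": trait, "rep": rep,
                         "train_size": q - n_test, "pa": pa})
    return pd.DataFrame(rows)


def across_cv(train_geno, train_records, test_geno, test_records, traits) -> pd.DataFrame:
    """Train on one population, predict another related one (single PA per trait).

    Marker sets are merged on common markers and one relationship matrix is
    computed on the union, so prediction flows through realized relatedness
    between the two sets.
    """
    merged = markers.merge_common(train_geno, test_geno)
    K = markers.vanraden_grm(markers.mean_impute(merged), ids=merged.ids)
    traits = list(traits)
    pm_train = simpop.plant_means(train_records, traits)
    pm_test = simpop.plant_means(test_records, traits)
    pm_all = pd.concat([pm_train, pm_test], ignore_index=True)
    rows = []
    train_plants = set(pm_train["plant"]) & set(K.ids)
    for trait in traits:
        gebv = _gblup_predict(K, pm_all, trait, train_plants)
        test = pm_test.loc[pm_test[trait].notna() & pm_test["plant"].isin(set(K.ids)), ["plant", trait]]
        pa = predictive_ability(gebv.loc[test["plant"]].to_numpy(), test[trait].to_numpy())
        rows.append({"scheme": "across", "trait": trait, "rep": 0,
                     "train_size": len(train_plants), "pa": pa})
    return pd.DataFrame(rows)


def stratified_cv(
    sets,
    train_per_set,
    traits,
    test_per_set: int = 25,
    reps: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Equal draws from each set form the training composite; 25/set are tested.

    ``sets`` is a list of (GenotypeMatrix, records) pairs; ``train_per_set``
    is an int or list of ints (training individuals drawn per set, swept to
    study training-population size).  Prevents set imbalance from biasing
    the size-response curve.
    """
    if test_per_set < 1:
        raise ValueError("test_per_set must be >= 1")
    sizes = [train_per_set] if isinstance(train_per_set, (int, np.integer)) else list(train_per_set)
    traits = list(traits)
    genos = [g for g, _ in sets]
    merged = genos[0]
    for g in genos[1:]:
        merged = markers.merge_common(merged, g)
    K = markers.vanraden_grm(markers.mean_impute(merged), ids=merged.ids)
    pms = [simpop.plant_means(r, traits) for _, r in sets]
    set_plants = [sorted(set(pm["plant"]) & set(K.ids)) for pm in pms]
    pm_all = pd.concat(pms, ignore_index=True)
    rng = simpop.child_rng(seed, 11)
    rows = []
    for rep in range(reps):
        for size in sizes:
            train_plants, test_plants = [], []
            for s_i, plants in enumerate(set_plants):
                if len(plants) < size + test_per_set:
                    raise ValueError(
                        f"set {s_i} has {len(plants)} usable plants; needs {size + test_per_set}"
                    )
                perm = rng.permutation(len(plants))
                train_plants += [plants[i] for i in perm[:size]]
                test_plants += [plants[i] for i in perm[size:size + test_per_set]]
            for trait in traits:
                gebv = _gblup_predict(K, pm_all, trait, set(train_plants))
                test = pm_all[pm_all["plant"].isin(test_plants)].dropna(subset=[trait])
                try:
                    pa = predictive_ability(gebv.loc[test["plant"]].to_numpy(), test[trait].to_numpy())
                except ValueError:
                    pa = np.nan
                rows.append({"scheme": "stratified", "trait": trait, "rep": rep,
                             "train_size": size * len(sets), "pa": pa})
    return pd.DataFrame(rows)


def phenotypic_index(records: pd.DataFrame, b, traits) -> pd.Series:
    """Smith-Hazel index phenotype: weighted sum of component traits per record.

    Records missing any component are dropped (count logged).
    """
    traits = list(traits)
    b = np.asarray(b, float).ravel()
    if b.size != len(traits):
        raise ValueError("weight vector length does not match traits")
    sub = records[traits].dropna()
    n_dropped = len(records) - len(sub)
    if n_dropped:
        log.info("phenotypic_index: dropped %d records missing a component trait", n_dropped)
    return pd.Series(sub.to_numpy(float) @ b, index=sub.index, name="index")


# ---------------------------------------------------------------------------
# realized gain per cycle of selection

@dataclass
class GainFit:
    """Per-cycle gain estimate with its Wald F test and variance components."""

    trait: str
    slope: float
    se: float
    F: float
    ddf: int
    p: float
    variances: dict
    converged: bool


def gain_model_fit(
    df: pd.DataFrame,
    trait: str,
    plot_sites=(),
    harvest_col: str | None = None,
    cycle_col: str = "cycle",
    **em_kwargs,
) -> GainFit:
    """Realized gain per cycle from multi-site trial records.

    ``df`` holds one response per row (a plot mean, or a sub-plot mean at
    sites with intra-block replication) with columns ``site``, ``block``,
    ``plot``, the numeric cycle code and the trait.  Random terms: site,
    block nested in site (one variance per site), and plot nested in block
    at the sites listed in ``plot_sites``.  Residual variances are grouped
    by ``harvest_col`` when given.  The slope on the cycle covariate is the
    average gain per cycle; its significance comes from a Wald F with
    containment denominator degrees of freedom.
    """
    sub = df.dropna(subset=[trait]).reset_index(drop=True)
    cycles = pd.to_numeric(sub[cycle_col])
    if cycles.nunique() < 2:
        raise ValueError("need at least two distinct cycle codes")
    per_site = sub.groupby("site")[cycle_col].nunique()
    if (per_site < 2).all():
        raise ValueError("cycle is confounded with site: every site holds a single cycle")
    n = len(sub)
    X = np.column_stack([np.ones(n), cycles.to_numpy(float)])
    x_names = ["intercept", "cycle"]
    rand = [RandomTerm(Z=pd.get_dummies(sub["site"]).to_numpy(float), name="site")]
    for site, grp in sub.groupby("site"):
        Z = np.zeros((n, grp["block"].nunique()))
        blocks = {b: i for i, b in enumerate(sorted(grp["block"].unique(), key=str))}
        for row, b in zip(grp.index, grp["block"]):
            Z[row, blocks[b]] = 1.0
        rand.append(RandomTerm(Z=Z, name=f"block[{site}]"))
    for site in plot_sites:
        grp = sub[sub["site"] == site]
        if grp.empty:
            raise ValueError(f"plot site {site!r} not present in the data")
        plots = grp[["block", "plot"]].astype(str).agg("_".join, axis=1)
        levels = {p: i for i, p in enumerate(sorted(plots.unique()))}
        Z = np.zeros((n, len(levels)))
        for row, p in zip(grp.index, plots):
            Z[row, levels[p]] = 1.0
        rand.append(RandomTerm(Z=Z, name=f"plot[{site}]"))
    groups = sub[harvest_col].to_numpy() if harvest_col else None
    spec = ModelSpec(y=sub[trait].to_numpy(float), X=X, x_names=x_names,
                     random=rand, residual_groups=groups)
    fit = reml_fit(spec, method="em", **em_kwargs)
    F, ddf, p = wald_f(fit, "cycle")
    j = fit.x_names.index("cycle")
    return GainFit(
        trait=trait,
        slope=float(fit.beta[j]),
        se=float(np.sqrt(fit.beta_cov[j, j])),
        F=F,
        ddf=ddf,
        p=p,
        variances=fit.variances,
        converged=fit.converged,
    )


def simulate_gain_trial(
    rng: np.random.Generator,
    slope: float = 0.5,
    cycles=(1, 2, 3, 5),
    n_sites: int = 4,
    blocks_per_site: int = 3,
    intra_block_sites: int = 2,
    site_sd: float = 0.5,
    block_sd: float = 0.3,
    plot_sd: float = 0.25,
    resid_sd=(0.3, 0.45),
) -> tuple[pd.DataFrame, list]:
    """Multi-site trial records conforming to the gain model's structure.

    The first ``intra_block_sites`` sites carry two sub-plot records per
    (block, cycle) sharing a plot effect (intra-block replication); the
    rest have one record per (block, cycle) and no plot term.  Harvesting
    method alternates across sites, giving two residual-variance groups.
    Returns ``(records, plot_sites)``.
    """
    rows = []
    plot_sites = [f"site{s + 1}" for s in range(intra_block_sites)]
    for s in range(n_sites):
        site = f"site{s + 1}"
        s_eff = rng.normal(0, site_sd)
        harvest = "plot_bulk" if s % 2 == 0 else "per_plant"
        r_sd = resid_sd[s % 2]
        for b in range(blocks_per_site):
            b_eff = rng.normal(0, block_sd)
            for c in cycles:
                n_sub = 2 if s < intra_block_sites else 1
                p_eff = rng.normal(0, plot_sd) if n_sub > 1 else 0.0
                for _ in range(n_sub):
                    y = s_eff + b_eff + p_eff + slope * c + rng.normal(0, r_sd)
                    rows.append({"site": site, "block": f"b{b + 1}", "plot": f"p{c}",
                                 "cycle": c, "harvest": harvest, "y": y})
    return pd.DataFrame(rows), plot_sites
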