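"""Synthetic biparental breeding populations with repeated-measure phenotypes.

This module generates the kind of data a small fruit-crop genomic-selection
program produces: an F2-derived base population from a cross of two fully
inbred parents, additive multi-trait architectures with controlled
heritability/repeatability/genetic-correlation targets, fruit-level phenotype
records with site, permanent-environment and residual structure, and
GBS-style genotype degradation (depth-limited missingness and low-depth
heterozygote miscalls).

Meiosis follows the Haldane model: crossover counts are Poisson with mean
equal to the chromosome map length in Morgans, crossover positions are
uniform on the map, and there is no interference.

All stochastic operations take an explicit :class:`numpy.random.Generator`
and are bit-reproducible given the same generator state.  ``child_rng``
derives independent streams from one global seed by fixed offsets, so
re-ordering pipeline stages does not silently change results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "Genome",
    "Individual",
    "Population",
    "TraitArchitecture",
    "child_rng",
    "make_founders",
    "meiosis",
    "cross",
    "make_f2_population",
    "random_mate",
    "assign_architecture",
    "simulate_records",
    "degrade_genotypes",
    "plant_means",
    "write_phenotypes",
    "read_phenotypes",
]

PHENO_ID_COLS = ["plant", "site", "block", "plot", "fruit"]


def child_rng(seed: int, *offsets: int) -> np.random.Generator:
    """Independent child stream derived from a global seed by fixed offsets."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(o) for o in offsets)))


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions in centimorgans, grouped by chromosome.

    ``chromosomes`` is a tuple of ``(chrom_id, positions)`` pairs with
    positions non-negative and strictly increasing within a chromosome.
    """

    chromosomes: tuple

    def __post_init__(self):
        seen = set()
        chroms = []
        for chrom_id, pos in self.chromosomes:
            if chrom_id in seen:
                raise ValueError(f"duplicate chromosome id {chrom_id!r}")
            seen.add(chrom_id)
            pos = np.asarray(pos, dtype=float)
            if pos.ndim != 1 or pos.size == 0:
                raise ValueError(f"chromosome {chrom_id!r} needs a 1-D, non-empty position vector")
            if np.any(pos < 0):
                raise ValueError(f"negative map position on chromosome {chrom_id!r}")
            if pos.size > 1 and np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom_id!r}")
            chroms.append((str(chrom_id), pos))
        object.__setattr__(self, "chromosomes", tuple(chroms))

    @classmethod
    def uniform(cls, n_chrom: int, markers_per_chrom: int, length_cm: float = 100.0) -> "GeneticMap":
        """Evenly spaced markers on ``n_chrom`` chromosomes of ``length_cm``."""
        chroms = []
        for c in range(n_chrom):
            if markers_per_chrom == 1:
                pos = np.array([length_cm / 2.0])
            else:
                pos = np.linspace(0.0, length_cm, markers_per_chrom)
            chroms.append((f"chr{c + 1:02d}", pos))
        return cls(tuple(chroms))

    @property
    def n_markers(self) -> int:
        return sum(pos.size for _, pos in self.chromosomes)

    def marker_table(self) -> pd.DataFrame:
        """Markers as a (chrom, pos, id) table; ids are chrom_pos strings."""
        rows = []
        for chrom_id, pos in self.chromosomes:
            for p in pos:
                rows.append((chrom_id, p, f"{chrom_id}_{p:g}"))
        return pd.DataFrame(rows, columns=["chrom", "pos", "id"])

    def chrom_slices(self):
        """Yield (chrom_id, positions, slice into the global marker vector)."""
        start = 0
        for chrom_id, pos in self.chromosomes:
            yield chrom_id, pos, slice(start, start + pos.size)
            start += pos.size


@dataclass
class Genome:
    """Two haplotypes over the map's markers, allele codes {0, 1}."""

    haplotypes: np.ndarray  # (2, n_markers) uint8

    def __post_init__(self):
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 2 or h.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_markers)")
        if h.size and h.max() > 1:
            raise ValueError("haplotype allele codes must be 0/1")
        self.haplotypes = h

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(np.int8)


@dataclass(frozen=True)
class Individual:
    id: str
    genome: Genome
    dam_id: str | None = None
    sire_id: str | None = None


@dataclass
class Population:
    """A labelled generation of individuals with pedigree back-references."""

    individuals: list
    generation: str = "C0"
    gmap: GeneticMap | None = None

    @property
    def ids(self) -> list:
        return [ind.id for ind in self.individuals]

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, i):
        return self.individuals[i]

    def dosage_matrix(self) -> np.ndarray:
        """Individuals x markers dosages in {0, 1, 2}."""
        return np.stack([ind.genome.dosage() for ind in self.individuals])

    def next_generation_label(self) -> str:
        if self.generation.startswith("C") and self.generation[1:].isdigit():
            return f"C{int(self.generation[1:]) + 1}"
        return self.generation + "+1"


def make_founders(n_markers: int, gmap: GeneticMap, rng=None):
    """Fully inbred founder pair carrying opposite alleles at every marker.

    This is the maximally informative biparental cross: the F1 is
    heterozygous everywhere and every marker segregates 1:2:1 in the F2.
    ``rng`` is accepted for API symmetry and unused (the construction is
    deterministic).
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if n_markers != gmap.n_markers:
        raise ValueError(f"n_markers={n_markers} does not match map ({gmap.n_markers} markers)")
    a = Genome(np.zeros((2, n_markers), dtype=np.uint8))
    b = Genome(np.ones((2, n_markers), dtype=np.uint8))
    return a, b


def meiosis(genome: Genome, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """One gamete under the Haldane model (Poisson crossovers, no interference)."""
    if genome.n_markers != gmap.n_markers:
        raise ValueError("genome inconsistent with map")
    gamete = np.empty(gmap.n_markers, dtype=np.uint8)
    for _, pos, sl in gmap.chrom_slices():
        length_m = (pos[-1] - pos[0]) / 100.0
        n_cross = rng.poisson(length_m) if length_m > 0 else 0
        start = int(rng.integers(2))
        if n_cross == 0:
            phase = np.full(pos.size, start)
        else:
            xpos = np.sort(rng.uniform(pos[0], pos[-1], size=n_cross))
            phase = (start + np.searchsorted(xpos, pos, side="left")) % 2
        gamete[sl] = genome.haplotypes[phase, np.arange(sl.start, sl.stop)]
    return gamete


def cross(dam: Genome, sire: Genome, gmap: GeneticMap, rng: np.random.Generator) -> Genome:
    """Offspring genome from one gamete of each parent (dam first)."""
    return Genome(np.stack([meiosis(dam, gmap, rng), meiosis(sire, gmap, rng)]))


def make_f2_population(founders, n: int, gmap: GeneticMap, rng: np.random.Generator) -> Population:
    """F2 individuals from selfing the founder F1; generation label C0.

    Each F2 is formed from two independent F1 gametes, so unlinked markers
    segregate 1:2:1 and the expected allele frequency is 0.5 everywhere.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a, b = founders
    f1 = cross(a, b, gmap, rng)
    inds = []
    for i in range(n):
        g = cross(f1, f1, gmap, rng)
        inds.append(Individual(id=f"C0_{i + 1:04d}", genome=g, dam_id="F1", sire_id="F1"))
    return Population(inds, generation="C0", gmap=gmap)


def random_mate(
    pop: Population,
    selected_ids,
    n_progeny: int,
    sires_per_dam: int = 4,
    rng: np.random.Generator | None = None,
    generation: str | None = None,
) -> Population:
    """Random mating of selected plants with multi-sire pollination.

    Every selected plant acts as a dam whose fruit is pollinated by
    ``sires_per_dam`` random sires drawn from the other selected plants
    (selfing only when a single candidate exists); each seed's sire is then
    drawn uniformly from that pool.  Progeny counts are balanced across dams
    (equal seed per half-sib family), with any remainder assigned to
    randomly chosen dams.
    """
    if rng is None:
        raise ValueError("rng is required")
    if pop.gmap is None:
        raise ValueError("population carries no genetic map")
    selected_ids = list(selected_ids)
    if not selected_ids:
        raise ValueError("selected_ids is empty")
    if sires_per_dam < 1:
        raise ValueError("sires_per_dam must be >= 1")
    by_id = {ind.id: ind for ind in pop.individuals}
    missing = [s for s in selected_ids if s not in by_id]
    if missing:
        raise ValueError(f"selected ids not in population: {missing[:5]}")
    dams = sorted(selected_ids)
    n_dams = len(dams)
    counts = np.full(n_dams, n_progeny // n_dams)
    remainder = n_progeny - counts.sum()
    if remainder:
        counts[rng.choice(n_dams, size=remainder, replace=False)] += 1
    gen = generation if generation is not None else pop.next_generation_label()
    inds = []
    k = 0
    for d_i, dam_id in enumerate(dams):
        candidates = [s for s in dams if s != dam_id] if n_dams > 1 else [dam_id]
        pool = rng.choice(candidates, size=min(sires_per_dam, len(candidates)), replace=False)
        for _ in range(counts[d_i]):
            sire_id = str(rng.choice(pool))
            g = cross(by_id[dam_id].genome, by_id[sire_id].genome, pop.gmap, rng)
            k += 1
            inds.append(Individual(id=f"{gen}_{k:04d}", genome=g, dam_id=dam_id, sire_id=sire_id))
    return Population(inds, generation=gen, gmap=pop.gmap)


@dataclass
class TraitArchitecture:
    """Additive marker effects plus the variance budget per trait.

    Total phenotypic variance is normalized to 1 per trait, so
    ``sigma_u2 = h2``, ``sigma_p2 = t - h2`` and ``sigma_e2 = 1 - t`` exactly
    hit the heritability and repeatability targets.  ``site_effects`` are
    fixed per-site shifts; ``yield_traits`` are recorded once per plant (the
    permanent-environment and fruit residual variances collapse into one
    plant-level residual for them).
    """

    trait_names: tuple
    effects: np.ndarray  # markers x traits
    sigma_u2: np.ndarray
    sigma_p2: np.ndarray
    sigma_e2: np.ndarray
    site_effects: dict
    target_G_corr: np.ndarray
    yield_traits: tuple = ()

    def __post_init__(self):
        tot = self.sigma_u2 + self.sigma_p2 + self.sigma_e2
        h2 = self.sigma_u2 / tot
        t = (self.sigma_u2 + self.sigma_p2) / tot
        if np.any(h2 <= 0) or np.any(h2 >= 1) or np.any(t < h2):
            raise ValueError("implied h2 must lie in (0,1) and t >= h2")
        C = np.asarray(self.target_G_corr, float)
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("target_G_corr must be symmetric with unit diagonal")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def true_bv(self, dosage: np.ndarray) -> np.ndarray:
        """True breeding values: centered dosages (F2 mean 1) times effects."""
        return (np.asarray(dosage, float) - 1.0) @ self.effects


def assign_architecture(
    pop_or_n_markers,
    target_h2,
    target_t,
    target_G_corr=None,
    rng: np.random.Generator | None = None,
    trait_names=None,
    n_qtl: int | None = None,
    sites=("S1",),
    site_sd: float = 0.5,
    yield_traits=(),
) -> TraitArchitecture:
    """Draw a multi-trait additive architecture hitting h2/t/correlation targets.

    Marker effects are multivariate normal across traits with correlation
    ``target_G_corr``, iid across markers, then rescaled analytically so the
    additive variance implied by the F2 dosage distribution equals sigma_u2
    per trait.  All markers segregate at p = q = 0.5, and linked markers are
    in coupling-phase LD, so the implied variance is ``b' S b`` with
    ``S[j,k] = (1 - 2 c_jk)/2`` (Haldane ``c`` from the map; block-diagonal
    across chromosomes; diagonal 2pq = 0.5).  Ignoring the LD term would
    bias realized heritabilities well below target on dense maps.  By
    default all markers are causal (infinitesimal-style); pass ``n_qtl``
    to restrict.
    """
    if rng is None:
        raise ValueError("rng is required")
    gmap = None
    if isinstance(pop_or_n_markers, Population):
        gmap = pop_or_n_markers.gmap
        n_markers = pop_or_n_markers[0].genome.n_markers
    elif isinstance(pop_or_n_markers, GeneticMap):
        gmap = pop_or_n_markers
        n_markers = gmap.n_markers
    else:
        n_markers = int(pop_or_n_markers)
    h2 = np.atleast_1d(np.asarray(target_h2, float))
    t = np.atleast_1d(np.asarray(target_t, float))
    if h2.shape != t.shape:
        raise ValueError("target_h2 and target_t must have the same length")
    if np.any(t < h2):
        raise ValueError("repeatability target t must be >= h2 for every trait")
    if np.any(h2 <= 0) or np.any(t >= 1):
        raise ValueError("need 0 < h2 <= t < 1 per trait")
    n_traits = h2.size
    if trait_names is None:
        trait_names = tuple(f"trait{i + 1}" for i in range(n_traits))
    if target_G_corr is None:
        target_G_corr = np.eye(n_traits)
    C = np.asarray(target_G_corr, float)
    # eigen square root tolerates PSD-with-zero targets (e.g. r_g = 1)
    evals, evecs = np.linalg.eigh(C)
    if evals.min() < -1e-8:
        raise ValueError("target_G_corr is not positive semidefinite")
    L = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    if n_qtl is None:
        qtl = np.arange(n_markers)
    else:
        qtl = np.sort(rng.choice(n_markers, size=n_qtl, replace=False))
    raw = rng.standard_normal((qtl.size, n_traits)) @ L.T
    effects = np.zeros((n_markers, n_traits))
    if gmap is not None:
        implied = f2_additive_variance(_expand_effects(raw, qtl, n_markers), gmap)
    else:
        implied = 0.5 * np.sum(raw**2, axis=0)  # genic term only (no map: LE assumed)
    effects[qtl] = raw * np.sqrt(h2 / implied)
    site_effects = {str(s): rng.normal(0.0, site_sd, size=n_traits) for s in sites}
    return TraitArchitecture(
        trait_names=tuple(trait_names),
        effects=effects,
        sigma_u2=h2.copy(),
        sigma_p2=t - h2,
        sigma_e2=1.0 - t,
        site_effects=site_effects,
        target_G_corr=C,
        yield_traits=tuple(yield_traits),
    )


def _expand_effects(raw: np.ndarray, qtl: np.ndarray, n_markers: int) -> np.ndarray:
    out = np.zeros((n_markers, raw.shape[1]))
    out[qtl] = raw
    return out


def f2_additive_variance(effects: np.ndarray, gmap: GeneticMap) -> np.ndarray:
    """Additive variance ``b' S b`` per trait under the exact F2 dosage law.

    With founders homozygous for opposite alleles, every marker pair on a
    chromosome is in coupling-phase LD: ``cov(d_j, d_k) = (1 - 2 c_jk)/2``
    with Haldane ``c_jk = (1 - exp(-2 d_jk)) / 2`` (d in Morgans); pairs on
    different chromosomes are independent.
    """
    effects = np.atleast_2d(np.asarray(effects, float))
    var = np.zeros(effects.shape[1])
    for _, pos, sl in gmap.chrom_slices():
        d_m = np.abs(pos[:, None] - pos[None, :]) / 100.0
        c = 0.5 * (1.0 - np.exp(-2.0 * d_m))
        S = 0.5 * (1.0 - 2.0 * c)
        b = effects[sl]
        var += np.einsum("jt,jk,kt->t", b, S, b)
    return var


def simulate_records(
    pop: Population,
    arch: TraitArchitecture,
    rng: np.random.Generator,
    sites=None,
    n_fruit_range=(4, 6),
    block_per_site: int = 1,
) -> pd.DataFrame:
    """Fruit-level phenotype records: y = site + u(plant) + p(plant) + e(fruit).

    Each plant is assigned to one site (roughly balanced at random), carries
    a permanent-environment deviation shared by all its fruit, and yields a
    uniform number of fruit in ``n_fruit_range``.  Yield traits are recorded
    once per plant with an empty fruit index and plant-level residual
    variance sigma_p2 + sigma_e2, keeping their h2 on target.
    """
    if sites is None:
        sites = tuple(arch.site_effects.keys())
    sites = [str(s) for s in sites]
    if not sites:
        raise ValueError("sites must be nonempty")
    for s in sites:
        if s not in arch.site_effects:
            raise ValueError(f"site {s!r} has no effect in the architecture")
    n = len(pop)
    T = arch.n_traits
    dos = pop.dosage_matrix()
    u = arch.true_bv(dos)  # n x T
    site_idx = rng.integers(0, len(sites), size=n)
    p_dev = rng.normal(0.0, 1.0, size=(n, T)) * np.sqrt(arch.sigma_p2)
    lo, hi = n_fruit_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid n_fruit_range")
    n_fruit = rng.integers(lo, hi + 1, size=n)
    is_yield = np.array([tn in arch.yield_traits for tn in arch.trait_names])
    rows = []
    values = []
    for i, ind in enumerate(pop.individuals):
        s = sites[site_idx[i]]
        se = arch.site_effects[s]
        block = (i % block_per_site) + 1
        base = se + u[i] + p_dev[i]
        for f in range(n_fruit[i]):
            e = rng.normal(0.0, 1.0, size=T) * np.sqrt(arch.sigma_e2)
            y = base + e
            rows.append((ind.id, s, block, 1, f + 1))
            values.append(np.where(is_yield, np.nan, y))
        if is_yield.any():
            e_plant = rng.normal(0.0, 1.0, size=T) * np.sqrt(arch.sigma_p2 + arch.sigma_e2)
            y = se + u[i] + e_plant
            rows.append((ind.id, s, block, 1, np.nan))
            values.append(np.where(is_yield, y, np.nan))
    df = pd.DataFrame(rows, columns=PHENO_ID_COLS)
    vals = pd.DataFrame(np.asarray(values), columns=list(arch.trait_names))
    return pd.concat([df, vals], axis=1)


def degrade_genotypes(
    dosage: np.ndarray,
    rng: np.random.Generator,
    miss_rate: float = 0.0,
    depth_lambda: float = 7.0,
    min_depth: int = 2,
    het_miscall: bool = True,
):
    """GBS-style degradation of a clean dosage matrix.

    Per-call depths are Poisson(``depth_lambda``); calls below ``min_depth``
    are missing, plus uniform dropout at ``miss_rate``.  Below depth 7 (the
    depth at which two reads are guaranteed when calling heterozygotes from
    allele sampling) a heterozygote is miscalled as one of the homozygotes
    with probability 2 * (1/2)^depth, split evenly between the two.

    Returns ``(degraded, depth)``: int8 dosages with -1 for missing, and the
    simulated depth matrix.
    """
    if not (0.0 <= miss_rate <= 1.0):
        raise ValueError("miss_rate must be in [0, 1]")
    dosage = np.asarray(dosage)
    depth = rng.poisson(depth_lambda, size=dosage.shape)
    u_miss = rng.random(size=dosage.shape)
    out = dosage.astype(np.int8).copy()
    if het_miscall:
        u_call = rng.random(size=dosage.shape)
        direction = rng.integers(0, 2, size=dosage.shape)
        p_bad = 2.0 * (0.5 ** np.clip(depth, 0, 60))
        flip = (dosage == 1) & (depth < 7) & (u_call < p_bad)
        out[flip] = (2 * direction[flip]).astype(np.int8)
    missing = (depth < min_depth) | (u_miss < miss_rate)
    out[missing] = -1
    return out, depth


def plant_means(records: pd.DataFrame, traits) -> pd.DataFrame:
    """Per-plant trait means (fruit traits averaged; single-record traits kept).

    Also returns the plant's site and the fruit count per trait via the
    companion columns ``site`` and ``n_<trait>``.
    """
    traits = list(traits)
    out = records.groupby("plant", sort=True).agg(site=("site", "first"))
    for tr in traits:
        sub = records[["plant", tr]].dropna()
        g = sub.groupby("plant", sort=True)[tr]
        out[tr] = g.mean()
        out[f"n_{tr}"] = g.size()
    return out.reset_index()


def write_phenotypes(records: pd.DataFrame, path) -> None:
    """CSV with the canonical header plant,site,block,plot,fruit,<traits...>."""
    cols = PHENO_ID_COLS + [c for c in records.columns if c not in PHENO_ID_COLS]
    records[cols].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PHENO_ID_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks required columns: {missing}")
    return df
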