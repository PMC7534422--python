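"""Genotype QC, marker-set merging, imputation and the genomic relationship matrix.

The central object is :class:`GenotypeMatrix`: individuals x markers integer
dosages in {0, 1, 2} with -1 as the missing sentinel (the VCFtools ``--012``
dialect), optionally carrying per-call read depths.  Filters follow the
standard GBS workflow for a biparental population: depth masking first, then
individual-level missingness, then marker-level missingness and minor allele
frequency, with an optional parent-informed filter that keeps only markers
homozygous within and polymorphic between the two inbred parents.

Remaining missing calls are mean imputed (deterministic, marker-wise) and the
additive genomic relationship matrix follows VanRaden's first method:
``K = W W' / (2 * sum p(1-p))`` with ``W`` the column-centered dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "Kinship",
    "FilterReport",
    "compute_maf",
    "set_low_depth_missing",
    "qc_filter",
    "parent_filter",
    "merge_common",
    "mean_impute",
    "vanraden_grm",
    "write_012",
    "read_012",
    "write_vcf",
    "read_vcf",
]


@dataclass
class GenotypeMatrix:
    """Dosage matrix with marker metadata and optional read depths.

    ``markers`` is a (chrom, pos, id) DataFrame aligned to the dosage
    columns; ``dosage`` holds int8 values in {0, 1, 2, -1}.
    """

    ids: np.ndarray
    markers: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x markers)")
        if len(self.ids) != self.dosage.shape[0]:
            raise ValueError("ids do not match dosage rows")
        if len(self.markers) != self.dosage.shape[1]:
            raise ValueError("marker table does not match dosage columns")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        mk = self.markers["id"]
        if mk.duplicated().any():
            raise ValueError("duplicate marker ids")
        bad = ~np.isin(self.dosage, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,-1}")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.dosage.shape:
                raise ValueError("depth shape must match dosage")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_ind(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            ids=self.ids[index],
            markers=self.markers,
            dosage=self.dosage[index],
            depth=None if self.depth is None else self.depth[index],
        )

    def take_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            ids=self.ids,
            markers=self.markers.iloc[index],
            dosage=self.dosage[:, index],
            depth=None if self.depth is None else self.depth[:, index],
        )


@dataclass
class Kinship:
    """Symmetric, numerically PSD relationship matrix with individual ids."""

    ids: np.ndarray
    K: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.K = np.asarray(self.K, dtype=float)
        if self.K.shape != (len(self.ids), len(self.ids)):
            raise ValueError("K must be square and match ids")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("K must be symmetric")
        self.K = 0.5 * (self.K + self.K.T)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.K, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "Kinship":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=df.index.to_numpy(dtype=object), K=df.to_numpy())

    def subset(self, ids) -> "Kinship":
        pos = {v: i for i, v in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return Kinship(ids=np.asarray(list(ids), dtype=object), K=self.K[np.ix_(idx, idx)])


@dataclass
class FilterReport:
    """Counts dropped at each qc_filter step; input dims = output + dropped."""

    n_ind_in: int
    n_markers_in: int
    n_ind_dropped: int
    n_markers_dropped_missing: int
    n_markers_dropped_maf: int

    @property
    def n_ind_out(self) -> int:
        return self.n_ind_in - self.n_ind_dropped

    @property
    def n_markers_out(self) -> int:
        return self.n_markers_in - self.n_markers_dropped_missing - self.n_markers_dropped_maf


def compute_maf(geno: GenotypeMatrix) -> np.ndarray:
    """Per-marker minor allele frequency over non-missing calls.

    All-missing markers get NaN (undefined; they fail any MAF threshold).
    """
    d = geno.dosage.astype(float)
    miss = geno.missing_mask()
    d[miss] = 0.0
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_obs > 0, d.sum(axis=0) / np.maximum(n_obs, 1) / 2.0, np.nan)
    return np.where(np.isnan(f), np.nan, np.minimum(f, 1.0 - f))


def set_low_depth_missing(geno: GenotypeMatrix, min_depth: int = 2) -> GenotypeMatrix:
    """Set calls with read depth below ``min_depth`` to missing."""
    if geno.depth is None:
        raise ValueError("genotype matrix has no depth layer")
    dosage = geno.dosage.copy()
    dosage[geno.depth < min_depth] = MISSING
    return GenotypeMatrix(ids=geno.ids, markers=geno.markers, dosage=dosage, depth=geno.depth)


def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    max_marker_missing: float = 0.2,
    max_ind_missing: float = 0.4,
):
    """Individual-then-marker QC with a step-by-step report.

    Order is fixed: (1) drop individuals missing more than
    ``max_ind_missing`` of markers; (2) recompute marker statistics on the
    survivors; (3) drop markers with missing fraction above
    ``max_marker_missing`` or MAF below ``maf_min``.

    Returns ``(filtered, FilterReport)``.
    """
    miss = geno.missing_mask()
    ind_keep = miss.mean(axis=1) <= max_ind_missing
    g1 = geno.take_individuals(np.flatnonzero(ind_keep))
    miss1 = g1.missing_mask()
    mk_missing_ok = miss1.mean(axis=0) <= max_marker_missing
    maf = compute_maf(g1)
    maf_ok = np.where(np.isnan(maf), False, maf >= maf_min)
    dropped_missing = int((~mk_missing_ok).sum())
    dropped_maf = int((mk_missing_ok & ~maf_ok).sum())
    keep = mk_missing_ok & maf_ok
    if not keep.any():
        raise ValueError("no markers survive QC filtering")
    out = g1.take_markers(np.flatnonzero(keep))
    report = FilterReport(
        n_ind_in=geno.n_ind,
        n_markers_in=geno.n_markers,
        n_ind_dropped=int((~ind_keep).sum()),
        n_markers_dropped_missing=dropped_missing,
        n_markers_dropped_maf=dropped_maf,
    )
    log.info(
        "qc_filter: %d/%d individuals, %d/%d markers retained (maf_min=%g, "
        "max_marker_missing=%g, max_ind_missing=%g)",
        report.n_ind_out, report.n_ind_in, report.n_markers_out, report.n_markers_in,
        maf_min, max_marker_missing, max_ind_missing,
    )
    return out, report


def parent_filter(
    geno: GenotypeMatrix,
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    max_missing: float = 0.5,
    max_het: float = 0.9,
) -> GenotypeMatrix:
    """Keep markers segregating in the biparental cross.

    A marker survives when both parents are non-missing homozygotes carrying
    different alleles, its missing fraction is at most ``max_missing`` and
    its heterozygote fraction (among non-missing calls) is below ``max_het``.
    """
    parent_a = np.asarray(parent_a)
    parent_b = np.asarray(parent_b)
    if parent_a.shape != (geno.n_markers,) or parent_b.shape != (geno.n_markers,):
        raise ValueError("parent genotype vectors are misaligned with the marker set")
    hom_poly = (
        np.isin(parent_a, (0, 2))
        & np.isin(parent_b, (0, 2))
        & (parent_a != parent_b)
    )
    miss = geno.missing_mask()
    miss_frac = miss.mean(axis=0)
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_obs > 0, (geno.dosage == 1).sum(axis=0) / np.maximum(n_obs, 1), 1.0)
    keep = hom_poly & (miss_frac <= max_missing) & (het_frac < max_het)
    return geno.take_markers(np.flatnonzero(keep))


def merge_common(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Row-wise concatenation restricted to the shared markers (a's order)."""
    common = set(a.markers["id"]) & set(b.markers["id"])
    if not common:
        raise ValueError("marker sets share no common markers")
    a_idx = np.flatnonzero(a.markers["id"].isin(common).to_numpy())
    a_sub = a.take_markers(a_idx)
    b_pos = {m: i for i, m in enumerate(b.markers["id"])}
    b_idx = np.array([b_pos[m] for m in a_sub.markers["id"]])
    b_sub = b.take_markers(b_idx)
    b_ids = list(b_sub.ids)
    clash = set(a.ids) & set(b_ids)
    if clash:
        log.warning("merge_common: %d clashing individual ids suffixed with '_b'", len(clash))
        b_ids = [f"{i}_b" if i in clash else i for i in b_ids]
    depth = None
    if a_sub.depth is not None and b_sub.depth is not None:
        depth = np.vstack([a_sub.depth, b_sub.depth])
    return GenotypeMatrix(
        ids=np.concatenate([a_sub.ids, np.asarray(b_ids, dtype=object)]),
        markers=a_sub.markers,
        dosage=np.vstack([a_sub.dosage, b_sub.dosage]),
        depth=depth,
    )


def mean_impute(geno: GenotypeMatrix) -> np.ndarray:
    """Replace missing calls with the marker mean; returns a float matrix."""
    d = geno.dosage.astype(float)
    miss = geno.missing_mask()
    if miss.all(axis=0).any():
        raise ValueError("all-missing marker: filter before imputing")
    d[miss] = np.nan
    col_mean = np.nanmean(d, axis=0)
    idx = np.where(miss)
    d[idx] = col_mean[idx[1]]
    return d


def vanraden_grm(dosage: np.ndarray, ids=None) -> Kinship:
    """VanRaden additive GRM from a complete real-valued dosage matrix.

    ``K = W W' / (2 sum p(1-p))`` with ``W = dosage - 2p`` per marker and
    ``p`` the observed allele frequency.  In a large F2 (p near 0.5) the mean
    diagonal is near 1.
    """
    d = np.asarray(dosage, dtype=float)
    if d.ndim != 2 or d.shape[1] < 1:
        raise ValueError("need a 2-D dosage matrix with at least 1 marker")
    if np.isnan(d).any():
        raise ValueError("dosage matrix must be complete (impute first)")
    p = d.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    w = d - 2.0 * p
    K = (w @ w.T) / denom
    if ids is None:
        ids = np.array([f"ind{i + 1}" for i in range(d.shape[0])], dtype=object)
    return Kinship(ids=np.asarray(ids, dtype=object), K=K)


# ---------------------------------------------------------------------------
# I/O: VCFtools --012 triplet and a minimal VCF subset (GT + DP, biallelic SNPs)

def write_012(geno: GenotypeMatrix, prefix: str) -> None:
    """Write the ``.012`` / ``.012.indv`` / ``.012.pos`` triplet.

    Matches the VCFtools dialect: one row per individual, a leading row
    index column, tab separators, missing as -1.
    """
    with open(f"{prefix}.012", "w") as fh:
        for i, row in enumerate(geno.dosage):
            fh.write("\t".join([str(i)] + [str(int(v)) for v in row]) + "\n")
    with open(f"{prefix}.012.indv", "w") as fh:
        fh.write("\n".join(str(i) for i in geno.ids) + "\n")
    with open(f"{prefix}.012.pos", "w") as fh:
        for _, r in geno.markers.iterrows():
            fh.write(f"{r['chrom']}\t{r['pos']:g}\n")


def read_012(prefix: str) -> GenotypeMatrix:
    dosage = np.loadtxt(f"{prefix}.012", dtype=np.int64, ndmin=2)[:, 1:].astype(np.int8)
    with open(f"{prefix}.012.indv") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    pos = pd.read_csv(f"{prefix}.012.pos", sep="\t", header=None, names=["chrom", "pos"])
    pos["id"] = pos["chrom"].astype(str) + "_" + pos["pos"].map(lambda p: f"{p:g}")
    return GenotypeMatrix(ids=np.asarray(ids, dtype=object), markers=pos, dosage=dosage)


def write_vcf(geno: GenotypeMatrix, path: str, ref: str = "A", alt: str = "T") -> None:
    """Minimal VCF 4.2 rendering (GT:DP) of a biallelic dosage matrix."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        for chrom in pd.unique(geno.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(map(str, geno.ids)) + "\n")
        for j, (_, r) in enumerate(geno.markers.iterrows()):
            cells = []
            for i in range(geno.n_ind):
                gt = gt_code[int(geno.dosage[i, j])]
                if geno.depth is not None:
                    cells.append(f"{gt}:{int(geno.depth[i, j])}")
                else:
                    cells.append(gt)
            fmt = "GT:DP" if geno.depth is not None else "GT"
            fh.write(
                f"{r['chrom']}\t{int(round(float(r['pos'])))}\t{r['id']}\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells) + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read GT (and DP when present) from a VCF; biallelic SNPs only.

    Multi-allelic or non-SNP records are skipped with a logged count.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 is an optional extra
        raise ImportError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(path)
    ids = np.asarray(vcf.samples, dtype=object)
    rows, meta, depths = [], [], []
    n_skipped = 0
    has_depth = True
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gts = np.asarray(var.gt_types)  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dos = np.select([gts == 0, gts == 1, gts == 3], [0, 1, 2], default=MISSING).astype(np.int8)
        rows.append(dos)
        meta.append((var.CHROM, float(var.POS), var.ID or f"{var.CHROM}_{var.POS}"))
        try:
            dp = np.asarray(var.format("DP")).reshape(-1)
        except Exception:
            dp = None
        if dp is None:
            has_depth = False
        else:
            depths.append(np.where(dp < 0, 0, dp))
    if n_skipped:
        log.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    if not rows:
        raise ValueError("no biallelic SNP records in VCF")
    markers = pd.DataFrame(meta, columns=["chrom", "pos", "id"])
    dosage = np.stack(rows, axis=1)
    depth = np.stack(depths, axis=1) if has_depth and depths else None
    return GenotypeMatrix(ids=ids, markers=markers, dosage=dosage, depth=depth)
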