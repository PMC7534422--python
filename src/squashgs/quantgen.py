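"""Scalar quantitative-genetics formulas and trait-correlation estimation.

Covers the parameter summaries a breeding program reports for repeated
fruit measurements: repeatability ``t`` and narrow-sense heritability
``h2`` from the repeatability-model variance components, the accuracy gain
from measuring ``n`` fruit, the phenotypic-selection benchmark
``PAmax = sqrt(h2)``, record weights for heterogeneous error variance,
index heritability, and environment-adjusted phenotypic / bivariate-REML
genetic correlations with Bonferroni control over trait pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .markers import Kinship
from .mixedmodel import RepeatabilityFit, TraitCovariances, lrt, mt_reml_fit, repeatability_fit

log = logging.getLogger(__name__)

__all__ = [
    "repeatability_heritability",
    "accuracy_gain",
    "pa_max",
    "record_weight",
    "index_heritability",
    "env_adjusted_pearson",
    "genetic_correlation",
    "pairwise_genetic_correlations",
    "param_table",
    "bonferroni",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding, as used for printed parameter tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def repeatability_heritability(varcomp):
    """(t, h2) from variance components (sigma_u2, sigma_p2, sigma_e2).

    ``t = (su + sp) / (su + sp + se)`` and ``h2 = su / (su + sp + se)``.
    Accepts a RepeatabilityFit or a 3-tuple.
    """
    if isinstance(varcomp, RepeatabilityFit):
        su, sp, se = varcomp.sigma_u2, varcomp.sigma_p2, varcomp.sigma_e2
    else:
        su, sp, se = varcomp
    if min(su, sp, se) < 0:
        raise ValueError("variance components must be non-negative")
    tot = su + sp + se
    if tot <= 0:
        raise ValueError("total variance is zero")
    return (su + sp) / tot, su / tot


def accuracy_gain(t: float, n: int, radical: bool = True) -> float:
    """Gain in selection accuracy from the mean of ``n`` repeated records.

    ``Delta_r = sqrt(1 / (t + (1 - t)/n))``: the ratio of the accuracy of a
    mean of n records to that of a single record.  It is 1 at n = 1,
    non-decreasing in n, and approaches ``1/sqrt(t)``.  ``radical=False``
    returns the un-rooted variance ratio for comparison.
    """
    if not 0 < t <= 1:
        raise ValueError("repeatability t must be in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    ratio = 1.0 / (t + (1.0 - t) / n)
    return math.sqrt(ratio) if radical else ratio


def pa_max(h2: float) -> float:
    """Upper bound on predictive ability from phenotypic mass selection.

    The regression of true breeding value on phenotype has correlation
    ``sqrt(h2)``, which benchmarks whole-genome model PA.
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must be in [0, 1]")
    return math.sqrt(h2)


def record_weight(h2: float, t: float, n: int, c: float) -> float:
    """Weight for a plant mean of ``n`` records under heterogeneous error.

    ``w = (1 - h2) / (c*h2 + (1 + (n-1)t)/n - h2)`` with ``c`` the
    proportion of genetic variance captured by markers.
    """
    if not (0 < h2 <= t < 1):
        raise ValueError("need 0 < h2 <= t < 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < c < 1:
        raise ValueError("c must be in (0, 1)")
    denom = c * h2 + (1.0 + (n - 1) * t) / n - h2
    if denom <= 0:
        raise ValueError("non-positive weight denominator")
    return (1.0 - h2) / denom


def index_heritability(G: np.ndarray, P: np.ndarray, b) -> float:
    """Heritability of a linear index: ``h2_I = b'Gb / b'Pb``."""
    G = np.asarray(G, float)
    P = np.asarray(P, float)
    b = np.asarray(b, float).ravel()
    if not (np.allclose(G, G.T) and np.allclose(P, P.T)):
        raise ValueError("G and P must be symmetric")
    denom = float(b @ P @ b)
    if denom <= 0:
        raise ValueError("b'Pb must be positive (P positive definite, b nonzero)")
    return float(b @ G @ b) / denom


def bonferroni(p, m: int):
    """Bonferroni adjustment: ``min(1, m * p)``."""
    return np.minimum(1.0, np.asarray(p, float) * m)


def env_adjusted_pearson(df: pd.DataFrame, traits, env_col: str = "site"):
    """Pairwise Pearson correlations on environment-adjusted residuals.

    Each trait is regressed on environment indicators (least squares) and
    the residuals are correlated pairwise; two-sided t-test p-values are
    Bonferroni-adjusted over the number of pairs tested.  Returns
    ``(r, p_raw, p_adj)`` DataFrames.  A trait that is constant within
    every environment yields NaN correlations (flagged by a warning).
    """
    traits = list(traits)
    resid = {}
    for tr in traits:
        sub = df[[env_col, tr]].dropna()
        envs = sub[env_col].astype(str)
        res = pd.Series(np.nan, index=df.index, dtype=float)
        r = sub[tr].astype(float) - sub[tr].astype(float).groupby(envs).transform("mean")
        res.loc[sub.index] = r
        if np.nanstd(res.to_numpy()) <= 1e-12:
            log.warning("trait %r constant within every environment: correlations undefined", tr)
        resid[tr] = res
    k = len(traits)
    r_mat = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p_mat = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    for i, j in pairs:
        a, b = resid[traits[i]], resid[traits[j]]
        both = a.notna() & b.notna()
        if both.sum() < 3 or a[both].std() <= 1e-12 or b[both].std() <= 1e-12:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(a[both], b[both])
        r_mat.iloc[i, j] = r_mat.iloc[j, i] = r
        p_mat.iloc[i, j] = p_mat.iloc[j, i] = p
    p_adj = p_mat.copy()
    off = ~np.eye(k, dtype=bool)
    p_adj.values[off] = bonferroni(p_mat.values[off], m)
    log.info("env_adjusted_pearson: Bonferroni m = %d trait pairs", m)
    return r_mat, p_mat, p_adj


def genetic_correlation(tc: TraitCovariances, i: int = 0, j: int = 1) -> float:
    """``r_g = G_ij / sqrt(G_ii G_jj)`` from a multi-trait fit."""
    G = tc.G
    if G[i, i] <= 0 or G[j, j] <= 0:
        raise ValueError("zero genetic variance: genetic correlation undefined")
    return float(np.clip(G[i, j] / math.sqrt(G[i, i] * G[j, j]), -1.0, 1.0))


def pairwise_genetic_correlations(
    records: pd.DataFrame,
    traits,
    K: Kinship,
    env_col: str = "site",
    **fit_kwargs,
) -> pd.DataFrame:
    """Bivariate-REML genetic correlations for every trait pair.

    Each pair is fitted with unstructured and diagonal genetic covariance;
    significance of the covariance comes from the likelihood-ratio test,
    Bonferroni-adjusted over the pairs tested in this call.
    """
    traits = list(traits)
    rows = []
    pairs = list(itertools.combinations(traits, 2))
    for a, b in pairs:
        full = mt_reml_fit(records, [a, b], K, structure="unstructured", env_col=env_col, **fit_kwargs)
        red = mt_reml_fit(records, [a, b], K, structure="diagonal", env_col=env_col, **fit_kwargs)
        try:
            rg = genetic_correlation(full)
        except ValueError:
            rg = np.nan
        stat, df, p = lrt(full, red)
        rows.append({"trait_a": a, "trait_b": b, "r_g": rg, "lrt_stat": stat, "df": df, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out["p_raw"].to_numpy(), len(pairs))
    log.info("pairwise_genetic_correlations: Bonferroni m = %d pairs", len(pairs))
    return out


def param_table(records: pd.DataFrame, traits, K: Kinship, env_col: str = "site", rounded: bool = True, **fit_kwargs) -> pd.DataFrame:
    """Per-trait (h2, t, PAmax) table from repeatability-model fits.

    Values are half-up rounded to 2 decimals when ``rounded`` (printed-table
    presentation); pass ``rounded=False`` for full precision.
    """
    rows = []
    for tr in traits:
        fit = repeatability_fit(records, tr, K, env_col=env_col, **fit_kwargs)
        t, h2 = repeatability_heritability(fit)
        pam = pa_max(h2)
        if rounded:
            t, h2, pam = (round_half_up(v) for v in (t, h2, pam))
        rows.append({"trait": tr, "h2": h2, "t": t, "PAmax": pam})
    return pd.DataFrame(rows)
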