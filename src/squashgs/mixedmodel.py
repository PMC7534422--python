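"""REML variance-component estimation and BLUP for genomic prediction.

Three model families are covered, all sharing one EM-REML core:

* the univariate repeatability model ``y = Xb + Zu + Zp + e`` with
  ``u ~ N(0, sigma_u2 K)`` (additive genetic, K a genomic relationship
  matrix), ``p ~ N(0, sigma_p2 I)`` (permanent environment, one level per
  plant) and fruit-level residual ``e``;
* multi-trait GBLUP with ``u ~ N(0, K (x) G)`` and ``e ~ N(0, I (x) R)``,
  G unstructured or diagonal;
* general small mixed models with identity-covariance random terms and
  heterogeneous (grouped) residual variances, as used for realized-gain
  trials.

Numerical strategy
------------------
The engine is EM-REML: updates are guaranteed to keep variances
non-negative and the restricted log-likelihood non-decreasing.  Because EM
can crawl near the optimum, steps are optionally extrapolated
(SQUAREM-style) with a safeguard that only accepts an extrapolated point
when its restricted log-likelihood does not fall below the plain double EM
step, so the recorded likelihood history stays monotone and the fixed point
is untouched.

Two structural shortcuts keep large fits cheap without changing the
likelihood:

* the repeatability model is fitted on plant means with residual variance
  ``sigma_e2 / n_i`` plus the within-plant sum of squares, which enters the
  restricted likelihood analytically (within-plant contrasts are free of
  fixed, genetic and permanent-environment effects);
* multi-trait fits rotate the data onto the eigenbasis of K, which turns
  each iteration into batched trait-by-trait (T x T) operations.

For the single-genetic-component model without repeated measures
(plain GBLUP) an eigendecomposition-profiled likelihood over the variance
ratio is available and is the default, as in standard GBLUP software.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats
from scipy.optimize import minimize_scalar

from .markers import Kinship
from .simpop import plant_means

log = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-10
ZERO_REPORT = 1e-8  # estimates at/near the floor are reported as exactly 0

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "VarianceTerm",
    "REMLFit",
    "RepeatabilityFit",
    "TraitCovariances",
    "reml_fit",
    "em_reml",
    "reml_two_variance",
    "repeatability_fit",
    "mt_reml_fit",
    "blup",
    "lrt",
    "wald_f",
]


# ---------------------------------------------------------------------------
# design helpers

def drop_aliased_columns(X: np.ndarray, names):
    """Remove linearly dependent columns (QR with pivoting), with a warning."""
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    q, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        dropped = [names[i] for i in piv[rank:]]
        log.warning("dropping aliased fixed-effect columns: %s", dropped)
    return X[:, keep], [names[i] for i in keep]


def _design_from_factor(values) -> tuple[np.ndarray, list]:
    """Full-rank fixed design: intercept plus treatment-coded factor levels."""
    values = pd.Series(values).astype(str)
    levels = sorted(values.unique())
    X = np.ones((len(values), len(levels)))
    names = ["intercept"]
    for lev in levels[1:]:
        X[:, len(names)] = (values == lev).to_numpy(float)
        names.append(f"env[{lev}]")
    return X[:, : len(names)], names


# ---------------------------------------------------------------------------
# generic EM-REML on n x n covariance contributions

@dataclass
class VarianceTerm:
    """One variance parameter: ``V += sigma2 * A``.

    ``extra_ss`` / ``extra_df`` fold in data that was collapsed out of the
    working response but still carries information on this component (the
    within-plant sum of squares for the fruit-level residual).
    """

    name: str
    A: np.ndarray
    nlevels: int
    extra_ss: float = 0.0
    extra_df: float = 0.0
    is_residual: bool = False


@dataclass
class REMLFit:
    variances: dict
    beta: np.ndarray
    beta_cov: np.ndarray
    x_names: list
    loglik: float
    converged: bool
    n_iter: int
    loglik_history: list
    n: int
    rank_x: int
    random_levels: dict
    w: np.ndarray  # P y at the optimum
    method: str = "em"

    def variance(self, name: str) -> float:
        return self.variances[name]


def _em_eval(y, X, terms, sig):
    """Restricted log-likelihood and the E-step operators at ``sig``."""
    n = y.size
    V = np.zeros((n, n))
    for s, t in zip(sig, terms):
        V += s * t.A
    try:
        c, low = sla.cho_factor(V, lower=True)
    except sla.LinAlgError:
        V = V + np.eye(n) * (1e-10 * np.trace(V) / n + 1e-12)
        c, low = sla.cho_factor(V, lower=True)
    Vi = sla.cho_solve((c, low), np.eye(n))
    ViX = Vi @ X
    B = X.T @ ViX
    sign, logdetB = np.linalg.slogdet(B)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite (singular design)")
    Bi = sla.inv(B)
    P = Vi - ViX @ Bi @ ViX.T
    w = P @ y
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    ll = -0.5 * (logdetV + logdetB + float(y @ w))
    for s, t in zip(sig, terms):
        if t.extra_df > 0:
            ll += -0.5 * (t.extra_df * math.log(s) + t.extra_ss / s)
    beta = Bi @ (ViX.T @ y)
    return ll, P, w, beta, Bi


def _em_update(terms, sig, P, w):
    new = np.empty_like(sig)
    for k, t in enumerate(terms):
        s = sig[k]
        quad = float(w @ (t.A @ w))
        tr = float(np.sum(P * t.A))
        new[k] = (t.extra_ss + t.nlevels * s + s * s * (quad - tr)) / (t.nlevels + t.extra_df)
    return np.clip(new, VARIANCE_FLOOR, None)


def em_reml(
    y,
    X,
    terms,
    x_names=None,
    init=None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    accelerate: bool = True,
) -> REMLFit:
    """EM-REML for ``V = sum_k sigma2_k A_k`` with monotone likelihood.

    ``accelerate=True`` interleaves safeguarded log-space extrapolation
    steps; the recorded ``loglik_history`` is non-decreasing either way.
    Non-convergence within ``max_iter`` EM steps is flagged, never silent.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if x_names is None:
        x_names = [f"x{i}" for i in range(X.shape[1])]
    X, x_names = drop_aliased_columns(X, list(x_names))
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed-effect parameters than records")
    if init is None:
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        vtot = float(np.var(y - X @ beta0, ddof=1)) or 1.0
        init = [vtot / len(terms) / max(np.mean(np.diag(t.A)), 1e-8) for t in terms]
    sig = np.clip(np.asarray(init, float), VARIANCE_FLOOR, None)

    ll, P, w, beta, Bi = _em_eval(y, X, terms, sig)
    history = [ll]
    converged = False
    n_em = 0
    lfloor = math.log(VARIANCE_FLOOR)
    # components clipped at the floor make the loglik creep; parameter
    # stability then defines convergence
    ptol = 1e-9 * max(float(np.var(y)), 1e-12)

    while n_em < max_iter and not converged:
        sig1 = _em_update(terms, sig, P, w)
        param_delta = float(np.abs(sig1 - sig).max())
        ll1, P1, w1, beta1, Bi1 = _em_eval(y, X, terms, sig1)
        n_em += 1
        if ll1 < ll - 1e-6:
            # numerically ill-conditioned step: keep the better point
            log.debug("EM step decreased loglik by %.2e; keeping previous point", ll - ll1)
            ll1, P1, w1, beta1, Bi1, sig1 = ll, P, w, beta, Bi, sig
        history.append(max(ll1, ll))
        if abs(ll1 - ll) < tol or param_delta < ptol:
            sig, ll, P, w, beta, Bi = sig1, ll1, P1, w1, beta1, Bi1
            converged = True
            break
        if not accelerate:
            sig, ll, P, w, beta, Bi = sig1, ll1, P1, w1, beta1, Bi1
            continue
        sig2 = _em_update(terms, sig1, P1, w1)
        ll2, P2, w2, beta2, Bi2 = _em_eval(y, X, terms, sig2)
        n_em += 1
        history.append(max(ll2, history[-1]))
        r = np.log(np.maximum(sig1, VARIANCE_FLOOR)) - np.log(np.maximum(sig, VARIANCE_FLOOR))
        v = np.log(np.maximum(sig2, VARIANCE_FLOOR)) - np.log(np.maximum(sig1, VARIANCE_FLOOR)) - r
        vv = float(v @ v)
        accepted = False
        if vv > 1e-30:
            alpha = -math.sqrt(float(r @ r) / vv)
            if alpha < -1.0:
                logc = np.log(np.maximum(sig, VARIANCE_FLOOR)) - 2.0 * alpha * r + alpha * alpha * v
                cand = np.exp(np.clip(logc, lfloor, 50.0))
                try:
                    llc, Pc, wc, betac, Bic = _em_eval(y, X, terms, cand)
                except np.linalg.LinAlgError:
                    llc = -np.inf
                if llc >= ll2:
                    sig, ll, P, w, beta, Bi = cand, llc, Pc, wc, betac, Bic
                    history.append(llc)
                    accepted = True
        if not accepted:
            sig, ll, P, w, beta, Bi = sig2, ll2, P2, w2, beta2, Bi2
        if abs(history[-1] - history[-3]) < tol:
            converged = True

    if not converged:
        log.warning("EM-REML did not converge in %d iterations (|dll|=%.2e)", n_em,
                    abs(history[-1] - history[-2]) if len(history) > 1 else float("nan"))
    variances = {t.name: (0.0 if s <= ZERO_REPORT else float(s)) for t, s in zip(terms, sig)}
    return REMLFit(
        variances=variances,
        beta=beta,
        beta_cov=Bi,
        x_names=x_names,
        loglik=float(ll),
        converged=converged,
        n_iter=n_em,
        loglik_history=history,
        n=n,
        rank_x=p,
        random_levels={t.name: t.nlevels for t in terms if not t.is_residual},
        w=w,
        method="em",
    )


# ---------------------------------------------------------------------------
# spec-level model description

@dataclass
class RandomTerm:
    """Random effect ``Z u`` with ``u ~ N(0, sigma2 * cov)`` (cov=None -> I)."""

    Z: np.ndarray
    name: str
    cov: np.ndarray | None = None


@dataclass
class ModelSpec:
    y: np.ndarray
    X: np.ndarray
    random: list
    x_names: list | None = None
    residual_groups: np.ndarray | None = None  # labels per record


def _check_psd(C: np.ndarray, what: str) -> None:
    ev = np.linalg.eigvalsh(np.asarray(C, float))
    if ev.min() < -1e-8 * max(ev.max(), 1.0):
        raise ValueError(f"{what} is not positive semidefinite (min eigenvalue {ev.min():.3e})")


def reml_fit(spec: ModelSpec, method: str = "auto", **kwargs) -> REMLFit:
    """Fit a univariate mixed model by REML.

    ``method='profile'`` (or 'auto' when the model is a single random term
    with homogeneous residual) uses the eigendecomposition-profiled
    restricted likelihood; otherwise EM-REML.
    """
    y = np.asarray(spec.y, float).ravel()
    X = np.asarray(spec.X, float)
    x_names = list(spec.x_names) if spec.x_names is not None else [f"x{i}" for i in range(X.shape[1])]
    homogeneous = spec.residual_groups is None
    if method == "auto":
        method = "profile" if (len(spec.random) == 1 and homogeneous) else "em"
    if method == "profile":
        if len(spec.random) != 1 or not homogeneous:
            raise ValueError("profiled solver handles one random term and one residual variance")
        rt = spec.random[0]
        C = rt.Z @ rt.Z.T if rt.cov is None else rt.Z @ rt.cov @ rt.Z.T
        _check_psd(C, f"covariance of term {rt.name!r}")
        return reml_two_variance(y, X, C, x_names=x_names, term_name=rt.name,
                                 nlevels=rt.Z.shape[1])
    terms = []
    n = y.size
    for rt in spec.random:
        if rt.cov is not None:
            _check_psd(rt.cov, f"covariance of term {rt.name!r}")
            A = rt.Z @ rt.cov @ rt.Z.T
        else:
            A = rt.Z @ rt.Z.T
        terms.append(VarianceTerm(name=rt.name, A=A, nlevels=rt.Z.shape[1]))
    if homogeneous:
        terms.append(VarianceTerm(name="residual", A=np.eye(n), nlevels=n, is_residual=True))
    else:
        groups = np.asarray(spec.residual_groups)
        for g in pd.unique(groups):
            mask = (groups == g).astype(float)
            terms.append(VarianceTerm(name=f"residual[{g}]", A=np.diag(mask),
                                      nlevels=int(mask.sum()), is_residual=True))
    return em_reml(y, X, terms, x_names=x_names, **kwargs)


def reml_two_variance(y, X, K, x_names=None, term_name="genetic", nlevels=None) -> REMLFit:
    """Profiled REML for ``V = sigma_u2 K + sigma_e2 I`` via eigenrotation.

    A coarse grid over the log variance ratio guards against local optima;
    Brent refines around the grid optimum.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if x_names is None:
        x_names = [f"x{i}" for i in range(X.shape[1])]
    X, x_names = drop_aliased_columns(X, list(x_names))
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed-effect parameters than records")
    K = np.asarray(K, float)
    lam, U = np.linalg.eigh(0.5 * (K + K.T))
    if lam.min() < -1e-8 * max(lam.max(), 1.0):
        raise ValueError("relationship matrix is not positive semidefinite")
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_restricted(loglam):
        ratio = math.exp(loglam)
        d = ratio * lam + 1.0
        Xd = Xt / d[:, None]
        B = Xt.T @ Xd
        try:
            beta = sla.solve(B, Xd.T @ yt, assume_a="pos")
        except sla.LinAlgError:
            return np.inf
        r = yt - Xt @ beta
        rss = float(np.sum(r * r / d))
        if rss <= 0:
            return np.inf
        se2 = rss / (n - p)
        sign, logdetB = np.linalg.slogdet(B)
        if sign <= 0:
            return np.inf
        return 0.5 * (np.sum(np.log(d)) + (n - p) * math.log(se2) + logdetB + (n - p))

    grid = np.linspace(-14.0, 14.0, 57)
    vals = np.array([neg_restricted(g) for g in grid])
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(neg_restricted, bounds=(g0 - 1.0, g0 + 1.0), method="bounded",
                          options={"xatol": 1e-10})
    loglam = float(res.x) if res.fun <= vals.min() else float(g0)
    ratio = math.exp(loglam)
    d = ratio * lam + 1.0
    Xd = Xt / d[:, None]
    B = Xt.T @ Xd
    Bi = sla.inv(B)
    beta = Bi @ (Xd.T @ yt)
    r = yt - Xt @ beta
    rss = float(np.sum(r * r / d))
    se2 = rss / (n - p)
    su2 = ratio * se2
    ll = -0.5 * (np.sum(np.log(d)) + (n - p) * math.log(se2) + np.linalg.slogdet(B)[1] + (n - p))
    w = U @ (r / d) / se2  # V^-1 (y - X beta) = P y
    su2_rep = 0.0 if su2 <= ZERO_REPORT else su2
    return REMLFit(
        variances={term_name: su2_rep, "residual": se2},
        beta=beta,
        beta_cov=Bi * se2,
        x_names=x_names,
        loglik=float(ll),
        converged=True,
        n_iter=0,
        loglik_history=[float(ll)],
        n=n,
        rank_x=p,
        random_levels={term_name: nlevels if nlevels is not None else n},
        w=w,
        method="profile",
    )


# ---------------------------------------------------------------------------
# repeatability model (Fisherian t and narrow-sense h2 from repeated fruit)

@dataclass
class RepeatabilityFit:
    """Variance components of the repeatability model plus BLUP handles."""

    sigma_u2: float
    sigma_p2: float
    sigma_e2: float
    loglik: float
    converged: bool
    n_iter: int
    loglik_history: list
    beta: np.ndarray
    x_names: list
    kinship: Kinship
    obs_idx: np.ndarray
    w: np.ndarray
    trait: str
    n_records: int
    n_plants: int


def repeatability_fit(
    records: pd.DataFrame,
    trait: str,
    K: Kinship,
    env_col: str = "site",
    env_fixed: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
    accelerate: bool = True,
) -> RepeatabilityFit:
    """REML for ``y = Xb + Zu + Zp + e`` on fruit-level records.

    The fit is carried out on the exact collapsed representation (plant
    means + within-plant sum of squares); estimates are identical to the
    fruit-level fit because fixed and plant-level effects are constant
    within a plant.  Requires repeated measures on at least some plants,
    otherwise sigma_p2 and sigma_e2 are confounded.
    """
    sub = records[["plant", env_col, trait]].dropna(subset=[trait])
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    env_per_plant = sub.groupby("plant")[env_col].nunique()
    if (env_per_plant > 1).any():
        raise ValueError("a plant appears in multiple environments; one environment per plant is assumed")
    g = sub.groupby("plant", sort=True)[trait]
    ybar = g.mean()
    n_i = g.size()
    if int(n_i.max()) < 2:
        raise ValueError(
            "every plant has a single record: the permanent-environment variance "
            "is confounded with the residual; use a plain GBLUP model instead"
        )
    ssw = float(((sub[trait] - sub["plant"].map(ybar)) ** 2).sum())
    N = int(n_i.sum())
    plants = ybar.index.to_numpy(dtype=object)
    pos = {v: i for i, v in enumerate(K.ids)}
    missing = [p for p in plants if p not in pos]
    if missing:
        raise ValueError(f"plants absent from the relationship matrix: {missing[:5]}")
    obs_idx = np.array([pos[p] for p in plants])
    K_obs = K.K[np.ix_(obs_idx, obs_idx)]
    _check_psd(K_obs, "relationship matrix")
    q = len(plants)
    env = sub.groupby("plant", sort=True)[env_col].first()
    if env_fixed and env.nunique() > 1:
        X, x_names = _design_from_factor(env)
    else:
        X, x_names = np.ones((q, 1)), ["intercept"]

    n_vec = n_i.to_numpy(float)
    terms = [
        VarianceTerm(name="genetic", A=K_obs, nlevels=q),
        VarianceTerm(name="permanent_env", A=np.eye(q), nlevels=q),
        VarianceTerm(name="residual", A=np.diag(1.0 / n_vec), nlevels=q,
                     extra_ss=ssw, extra_df=float(N - q), is_residual=True),
    ]
    se0 = max(ssw / max(N - q, 1), 1e-6)
    beta0, *_ = np.linalg.lstsq(X, ybar.to_numpy(), rcond=None)
    vm = float(np.var(ybar.to_numpy() - X @ beta0, ddof=1))
    between = max(vm - se0 * float(np.mean(1.0 / n_vec)), 0.1 * vm)
    fit = em_reml(
        ybar.to_numpy(), X, terms, x_names=x_names,
        init=[between / 2.0, between / 2.0, se0],
        tol=tol, max_iter=max_iter, accelerate=accelerate,
    )
    return RepeatabilityFit(
        sigma_u2=fit.variances["genetic"],
        sigma_p2=fit.variances["permanent_env"],
        sigma_e2=fit.variances["residual"],
        loglik=fit.loglik,
        converged=fit.converged,
        n_iter=fit.n_iter,
        loglik_history=fit.loglik_history,
        beta=fit.beta,
        x_names=fit.x_names,
        kinship=K,
        obs_idx=obs_idx,
        w=fit.w,
        trait=trait,
        n_records=N,
        n_plants=q,
    )


# ---------------------------------------------------------------------------
# multi-trait GBLUP (K (x) G, I (x) R) via the canonical eigenrotation of K

@dataclass
class TraitCovariances:
    """Trait-level genetic (G) and residual (R) covariances from MT-REML."""

    trait_names: tuple
    G: np.ndarray
    R: np.ndarray
    structure: str
    loglik: float
    converged: bool
    n_iter: int
    beta: np.ndarray
    kinship: Kinship
    obs_idx: np.ndarray
    Py: np.ndarray  # q x T, original basis
    n_obs: int
    at_boundary: bool = False  # G held on the PSD cone by bending

    @property
    def n_free_params(self) -> int:
        T = len(self.trait_names)
        r_params = T * (T + 1) // 2
        g_params = r_params if self.structure == "unstructured" else T
        return g_params + r_params


def _bend_psd(M: np.ndarray, min_rel: float = 1e-6, floor: float = 1e-10) -> np.ndarray:
    M = 0.5 * (M + M.T)
    ev, evec = np.linalg.eigh(M)
    lo = max(min_rel * max(np.trace(M), 0.0), floor)
    if ev.min() >= lo:
        return M
    ev = np.maximum(ev, lo)
    return evec @ np.diag(ev) @ evec.T


def _mt_eval(Yt, Xt, lam, G, R):
    q, T = Yt.shape
    pe = Xt.shape[1]
    Sig = lam[:, None, None] * G[None, :, :] + R[None, :, :]
    Sinv = np.linalg.inv(Sig)
    sign, logdet = np.linalg.slogdet(Sig)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("trait covariance block not positive definite")
    B = np.einsum("qst,qi,qj->sitj", Sinv, Xt, Xt).reshape(T * pe, T * pe)
    rhs = np.einsum("qst,qi,qt->si", Sinv, Xt, Yt).reshape(T * pe)
    signB, logdetB = np.linalg.slogdet(B)
    if signB <= 0:
        raise np.linalg.LinAlgError("fixed-effect system singular in MT fit")
    beta = sla.solve(B, rhs, assume_a="pos").reshape(T, pe)
    resid = Yt - Xt @ beta.T
    w = np.einsum("qst,qt->qs", Sinv, resid)
    quad = float(np.sum(resid * w))
    ll = -0.5 * (float(logdet.sum()) + logdetB + quad)
    Binv = sla.inv(B).reshape(T, pe, T, pe)
    M = np.einsum("qi,sitj,qj->qst", Xt, Binv, Xt)
    Pii = Sinv - np.einsum("qsa,qab,qbt->qst", Sinv, M, Sinv)
    return ll, beta, w, Pii


def _mt_update(lam, G, R, w, Pii, structure):
    q = w.shape[0]
    SW = np.einsum("qs,qt->st", w, w)
    SdW = np.einsum("q,qs,qt->st", lam, w, w)
    SP = Pii.sum(axis=0)
    SdP = np.einsum("q,qst->st", lam, Pii)
    G_new = G + G @ (SdW - SdP) @ G / q
    R_new = R + R @ (SW - SP) @ R / q
    G_new = _bend_psd(G_new)
    R_new = _bend_psd(R_new)
    if structure == "diagonal":
        G_new = np.diag(np.diag(G_new))
    return G_new, R_new


def mt_reml_fit(
    records: pd.DataFrame,
    traits,
    K: Kinship,
    structure: str = "unstructured",
    env_col: str = "site",
    response: str = "plant_mean",
    tol: float = 1e-8,
    max_iter: int = 1000,
    accelerate: bool = True,
) -> TraitCovariances:
    """Multi-trait REML: ``mu ~ N(0, K (x) G)``, ``e ~ N(0, I (x) R)``.

    Responses are plant means of the fruit records (one record per plant
    and trait); plants missing any trait are dropped for the fit (logged).
    ``structure`` selects an unstructured or diagonal genetic covariance
    (the diagonal fit is the null model of the genetic-covariance LRT).
    """
    traits = list(traits)
    if not 2 <= len(traits) <= 3:
        raise ValueError("mt_reml_fit supports 2 or 3 traits")
    if structure not in ("unstructured", "diagonal"):
        raise ValueError("structure must be 'unstructured' or 'diagonal'")
    if response != "plant_mean":
        raise ValueError("only plant-mean responses are supported")
    pm = plant_means(records, traits)
    complete = pm.dropna(subset=traits)
    if len(complete) < len(pm):
        log.info("mt_reml_fit: dropped %d plants missing at least one trait", len(pm) - len(complete))
    complete = complete.sort_values("plant")
    plants = complete["plant"].to_numpy(dtype=object)
    Y = complete[traits].to_numpy(float)
    if np.any(Y.std(axis=0) <= 0):
        raise ValueError("a trait has zero variance")
    pos = {v: i for i, v in enumerate(K.ids)}
    missing = [p for p in plants if p not in pos]
    if missing:
        raise ValueError(f"plants absent from the relationship matrix: {missing[:5]}")
    obs_idx = np.array([pos[p] for p in plants])
    K_obs = K.K[np.ix_(obs_idx, obs_idx)]
    lam, U = np.linalg.eigh(0.5 * (K_obs + K_obs.T))
    if lam.min() < -1e-8 * max(lam.max(), 1.0):
        raise ValueError("relationship matrix is not positive semidefinite")
    lam = np.clip(lam, 0.0, None)
    env = complete[env_col] if env_col in complete.columns else pd.Series(["_all"] * len(complete))
    if env.nunique() > 1:
        X, _ = _design_from_factor(env)
    else:
        X = np.ones((len(complete), 1))
    Yt = U.T @ Y
    Xt = U.T @ X
    q, T = Y.shape

    beta0, *_ = np.linalg.lstsq(X, Y, rcond=None)
    S = np.cov((Y - X @ beta0).T)
    S = np.atleast_2d(S) + np.eye(T) * 1e-8
    G = np.diag(np.diag(S)) / 2.0 if structure == "diagonal" else S / 2.0
    R = S / 2.0

    ll, beta, w, Pii = _mt_eval(Yt, Xt, lam, G, R)
    history = [ll]
    converged = False
    n_em = 0
    # when G sits on the PSD boundary the bent point is not an exact EM fixed
    # point and the loglik creeps; parameter stability then defines convergence
    ptol = 1e-7 * max(np.trace(S), 1.0)
    while n_em < max_iter and not converged:
        G1, R1 = _mt_update(lam, G, R, w, Pii, structure)
        param_delta = max(np.abs(G1 - G).max(), np.abs(R1 - R).max())
        ll1, beta1, w1, Pii1 = _mt_eval(Yt, Xt, lam, G1, R1)
        n_em += 1
        if ll1 < ll - 1e-6:
            log.debug("MT EM step decreased loglik by %.2e; stopping refinement", ll - ll1)
            break
        history.append(max(ll1, ll))
        if abs(ll1 - ll) < tol or param_delta < ptol:
            G, R, ll, beta, w, Pii = G1, R1, ll1, beta1, w1, Pii1
            converged = True
            break
        if not accelerate:
            G, R, ll, beta, w, Pii = G1, R1, ll1, beta1, w1, Pii1
            continue
        G2, R2 = _mt_update(lam, G1, R1, w1, Pii1, structure)
        ll2, beta2, w2, Pii2 = _mt_eval(Yt, Xt, lam, G2, R2)
        n_em += 1
        history.append(max(ll2, history[-1]))
        th0 = np.concatenate([G.ravel(), R.ravel()])
        th1 = np.concatenate([G1.ravel(), R1.ravel()])
        th2 = np.concatenate([G2.ravel(), R2.ravel()])
        r_ = th1 - th0
        v_ = th2 - th1 - r_
        vv = float(v_ @ v_)
        accepted = False
        if vv > 1e-30:
            alpha = -math.sqrt(float(r_ @ r_) / vv)
            if alpha < -1.0:
                thc = th0 - 2.0 * alpha * r_ + alpha * alpha * v_
                Gc = _bend_psd(thc[: T * T].reshape(T, T))
                Rc = _bend_psd(thc[T * T:].reshape(T, T))
                if structure == "diagonal":
                    Gc = np.diag(np.diag(Gc))
                try:
                    llc, betac, wc, Piic = _mt_eval(Yt, Xt, lam, Gc, Rc)
                except np.linalg.LinAlgError:
                    llc = -np.inf
                if llc >= ll2:
                    G, R, ll, beta, w, Pii = Gc, Rc, llc, betac, wc, Piic
                    history.append(llc)
                    accepted = True
        if not accepted:
            G, R, ll, beta, w, Pii = G2, R2, ll2, beta2, w2, Pii2
        if abs(history[-1] - history[-3]) < tol:
            converged = True
    if not converged:
        log.warning("MT EM-REML did not converge in %d iterations", n_em)
    g_ev = np.linalg.eigvalsh(0.5 * (G + G.T))
    at_boundary = bool(g_ev.min() <= 2e-6 * max(np.trace(G), 1e-12))
    if at_boundary:
        log.info("MT EM-REML: G estimate lies on the PSD boundary (bent)")
    Py = U @ w
    return TraitCovariances(
        trait_names=tuple(traits),
        G=0.5 * (G + G.T),
        R=0.5 * (R + R.T),
        structure=structure,
        loglik=float(ll),
        converged=converged,
        n_iter=n_em,
        beta=beta,
        kinship=K,
        obs_idx=obs_idx,
        Py=Py,
        n_obs=q,
        at_boundary=at_boundary,
    )


# ---------------------------------------------------------------------------
# BLUP and tests

def blup(fit) -> pd.DataFrame:
    """GEBVs for every individual in the fit's relationship matrix.

    Individuals without records are predicted through their K rows — the
    genomic-prediction use case.  Returns a DataFrame indexed by individual
    id with one column per trait.
    """
    if isinstance(fit, RepeatabilityFit):
        u = fit.sigma_u2 * (fit.kinship.K[:, fit.obs_idx] @ fit.w)
        return pd.DataFrame({fit.trait: u}, index=pd.Index(fit.kinship.ids, name="id"))
    if isinstance(fit, TraitCovariances):
        u = fit.kinship.K[:, fit.obs_idx] @ fit.Py @ fit.G
        return pd.DataFrame(u, columns=list(fit.trait_names), index=pd.Index(fit.kinship.ids, name="id"))
    raise TypeError(f"no BLUP rule for {type(fit).__name__}")


def blup_from_two_variance(fit: REMLFit, K_full: np.ndarray, obs_idx, trait: str = "trait") -> pd.DataFrame:
    """GEBVs from a profiled GBLUP fit, extended to all rows of ``K_full``."""
    name = next(k for k in fit.variances if k != "residual")
    u = fit.variances[name] * (K_full[:, np.asarray(obs_idx)] @ fit.w)
    return pd.DataFrame({trait: u})


def lrt(full: TraitCovariances, reduced: TraitCovariances):
    """Likelihood-ratio test of nested covariance structures.

    Returns ``(statistic, df, p)`` with df the difference in free
    parameters and p from the chi-square upper tail.
    """
    if full.trait_names != reduced.trait_names:
        raise ValueError("fits are not on the same traits")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise ValueError(
            f"full-model loglik below reduced ({full.loglik:.6f} < {reduced.loglik:.6f}): optimizer failure"
        )
    stat = max(stat, 0.0)
    df = full.n_free_params - reduced.n_free_params
    if df < 0:
        raise ValueError("reduced model is not nested in the full model")
    if df == 0:
        # identical parameterizations: the test is vacuous
        return float(stat), 0, 1.0 if stat <= 1e-8 else 0.0
    p = float(stats.chi2.sf(stat, df))
    return float(stat), int(df), p


def wald_f(fit: REMLFit, coefficient: str):
    """Wald F for one fixed coefficient with containment denominator df.

    ``F = (beta/SE)^2``; the denominator df is
    ``n - rank(X) - total random levels`` (containment approximation).
    """
    if coefficient not in fit.x_names:
        raise ValueError(f"coefficient {coefficient!r} not in the fixed design {fit.x_names}")
    j = fit.x_names.index(coefficient)
    b = float(fit.beta[j])
    var = float(fit.beta_cov[j, j])
    F = b * b / var if var > 0 else np.inf
    ddf = fit.n - fit.rank_x - sum(fit.random_levels.values())
    if ddf < 1:
        log.warning("containment ddf %d < 1; clipping to 1", ddf)
        ddf = 1
    p = float(stats.f.sf(F, 1, ddf))
    log.info("Wald F for %s: F=%.4f, ddf=%d (containment), p=%.4g", coefficient, F, ddf, p)
    return float(F), int(ddf), p
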