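"""Mixed-model phenotype pre-adjustment and low/high group splitting.

Phenotypes are corrected with a linear mixed model containing fixed factors
and covariates plus a random additive genetic animal effect whose covariance
is the genomic relationship matrix (VanRaden method 1).  REML estimation
profiles a one-dimensional likelihood in the variance ratio after rotating
the model by the eigenvectors of the relationship matrix, so each likelihood
evaluation is O(n).  The corrected phenotype is by default the pure residual
e-hat = y - Xb - u-hat (fixed-effect fit and BLUP of the random effects both
subtracted); ``residual_mode='fixed_only'`` subtracts the fixed part only.

Animals are then ranked by corrected phenotype and split into equal-size
low-phenotype (LP) and high-phenotype (HP) halves, dropping the single
median animal when n is odd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .plinkio import GenotypeMatrix

__all__ = [
    "LMMSpec",
    "LMMResult",
    "LMMError",
    "make_grm",
    "fit_lmm",
    "split_groups",
]

_RATIO_BOUNDS = (1e-6, 1e6)  # search bounds on the variance ratio
_RATIO_TOL = 1e-8


class LMMError(ValueError):
    pass


@dataclass
class LMMSpec:
    """Model specification: which phenotype-table columns play which role."""

    response: str = "phenotype"
    fixed_factors: Sequence[str] = ()
    covariates: Sequence[str] = ()
    random_iid: Optional[str] = None  # e.g. a herd column


@dataclass
class LMMResult:
    sigma_g: float
    sigma_e: float
    h2: float
    beta: pd.Series
    residuals: pd.Series  # corrected phenotypes, indexed by id
    sigma_iid: Optional[float] = None
    loglik_trace: list = field(default_factory=list)
    loglik: Optional[Callable[[float], float]] = None


def make_grm(geno) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    ``G = M M' / (2 sum p_k (1-p_k))`` with M the genotype matrix centered at
    twice the allele frequency.  Monomorphic markers carry no information and
    are skipped; all-monomorphic input is an error.
    """
    if isinstance(geno, GenotypeMatrix):
        X = geno.imputed()
    else:
        X = np.asarray(geno, dtype=np.float64)
    if X.shape[1] < 2:
        raise LMMError("need at least 2 markers for a relationship matrix")
    p = X.mean(axis=0) / 2.0
    poly = (X.std(axis=0) > 0) & (p > 0) & (p < 1)
    if not poly.any():
        raise LMMError("all markers monomorphic: relationship matrix undefined")
    M = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return (M @ M.T) / denom


def _design_matrix(pheno: pd.DataFrame, spec: LMMSpec):
    cols = [spec.response, *spec.fixed_factors, *spec.covariates]
    missing = [c for c in cols if c not in pheno.columns]
    if missing:
        raise LMMError(f"phenotype table lacks columns: {missing}")
    parts = [np.ones((len(pheno), 1))]
    names = ["intercept"]
    for f in spec.fixed_factors:
        levels = pheno[f].astype(str)
        counts = levels.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise LMMError(f"factor {f!r}: levels with <2 individuals: {small}")
        dummies = pd.get_dummies(levels, prefix=f, drop_first=True, dtype=float)
        parts.append(dummies.to_numpy())
        names.extend(dummies.columns.tolist())
    for c in spec.covariates:
        parts.append(pheno[c].to_numpy(float)[:, None])
        names.append(c)
    X = np.hstack(parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # greedy pass to name the aliased columns
        aliased, kept = [], []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(j)
            else:
                aliased.append(names[j])
        raise LMMError(f"singular fixed-effect design; aliased columns: {aliased}")
    return X, names


def _reml_nll_factory(s, yt, Xt):
    """Profiled REML negative log-likelihood in log(variance ratio)."""
    n, q = Xt.shape

    def nll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        v = lam * s + 1.0
        w = 1.0 / v
        XtW = Xt * w[:, None]
        A = XtW.T @ Xt
        beta = np.linalg.solve(A, XtW.T @ yt)
        r = yt - Xt @ beta
        rss = float(r @ (w * r))
        sigma_e = rss / (n - q)
        _, logdet_A = np.linalg.slogdet(A)
        return 0.5 * (
            (n - q) * np.log(sigma_e) + np.sum(np.log(v)) + logdet_A + (n - q)
        )

    return nll


def fit_lmm(
    pheno: pd.DataFrame,
    spec: LMMSpec,
    geno: Optional[GenotypeMatrix] = None,
    grm: Optional[np.ndarray] = None,
    residual_mode: str = "ehat",
) -> LMMResult:
    """REML fit of ``y = Xb + g + (iid) + e`` with Cov(g) = sigma_g * GRM.

    The GRM is computed from ``geno`` (or passed precomputed) and reordered
    to the phenotype rows by id.  With no second random term the likelihood
    is profiled in the single ratio sigma_g/sigma_e over the eigenbasis of
    the GRM; with ``spec.random_iid`` set, a two-ratio Nelder-Mead search on
    the dense covariance is used (intended for moderate n).
    """
    if residual_mode not in ("ehat", "fixed_only"):
        raise LMMError("residual_mode must be 'ehat' or 'fixed_only'")
    ids = pheno["id"].astype(str).to_numpy()
    if grm is None:
        if geno is None:
            raise LMMError("need either geno or a precomputed grm")
        grm = make_grm(geno)
        order = {str(i): k for k, i in enumerate(geno.iids)}
        try:
            rows = np.array([order[i] for i in ids])
        except KeyError as e:
            raise LMMError(f"phenotype id {e} missing from genotypes") from None
        grm = grm[np.ix_(rows, rows)]
    K = np.asarray(grm, dtype=np.float64)
    n = len(pheno)
    if K.shape != (n, n):
        raise LMMError(f"GRM shape {K.shape} does not match {n} phenotype rows")
    y = pheno[spec.response].to_numpy(np.float64)
    X, names = _design_matrix(pheno, spec)

    if spec.random_iid is not None:
        return _fit_two_component(pheno, spec, K, y, X, names, residual_mode)

    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    nll = _reml_nll_factory(s, yt, Xt)
    trace: list = []

    def traced(log_lam):
        val = nll(log_lam)
        trace.append((float(np.exp(log_lam)), -float(val)))
        return val

    lo, hi = np.log(_RATIO_BOUNDS[0]), np.log(_RATIO_BOUNDS[1])
    res = optimize.minimize_scalar(
        traced, bounds=(lo, hi), method="bounded",
        options={"xatol": np.log1p(_RATIO_TOL)},
    )
    if not res.success:
        err = LMMError(f"REML optimization did not converge: {res.message}")
        err.trace = trace
        raise err
    lam = float(np.exp(res.x))
    v = lam * s + 1.0
    w = 1.0 / v
    XtW = Xt * w[:, None]
    A = XtW.T @ Xt
    beta = np.linalg.solve(A, XtW.T @ yt)
    r = yt - Xt @ beta
    sigma_e = float(r @ (w * r)) / (n - X.shape[1])
    sigma_g = lam * sigma_e
    fixed_fit = X @ beta
    if residual_mode == "ehat":
        resid = U @ (w * r)  # sigma_e^2 V^-1 (y - Xb)
    else:
        resid = y - fixed_fit
    return LMMResult(
        sigma_g=sigma_g,
        sigma_e=sigma_e,
        h2=lam / (1.0 + lam),
        beta=pd.Series(beta, index=names),
        residuals=pd.Series(resid, index=ids),
        loglik_trace=trace,
        loglik=lambda lam_: -nll(np.log(lam_)),
    )


def _fit_two_component(pheno, spec, K, y, X, names, residual_mode):
    """Nested-profile REML with an extra i.i.d. random intercept."""
    col = spec.random_iid
    if col not in pheno.columns:
        raise LMMError(f"random_iid column {col!r} not in phenotype table")
    levels, inv = np.unique(pheno[col].astype(str), return_inverse=True)
    Z = np.zeros((len(pheno), len(levels)))
    Z[np.arange(len(pheno)), inv] = 1.0
    ZZt = Z @ Z.T
    n, q = X.shape
    eye = np.eye(n)
    trace: list = []

    def nll(params):
        lam, tau = np.exp(params)
        V = lam * K + tau * ZZt + eye
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e10
        logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        A = X.T @ Vi_X
        beta = np.linalg.solve(A, X.T @ Vi_y)
        r = y - X @ beta
        rss = float(r @ np.linalg.solve(V, r))
        sigma_e = rss / (n - q)
        _, logdet_A = np.linalg.slogdet(A)
        val = 0.5 * ((n - q) * np.log(sigma_e) + logdet_V + logdet_A + (n - q))
        trace.append((float(lam), float(tau), -float(val)))
        return val

    res = optimize.minimize(nll, x0=[0.0, -1.0], method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
    if not res.success:
        err = LMMError(f"two-component REML did not converge: {res.message}")
        err.trace = trace
        raise err
    lam, tau = np.exp(res.x)
    V = lam * K + tau * ZZt + eye
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    A = X.T @ Vi_X
    beta = np.linalg.solve(A, X.T @ Vi_y)
    r = y - X @ beta
    sigma_e = float(r @ np.linalg.solve(V, r)) / (n - q)
    ids = pheno["id"].astype(str).to_numpy()
    resid = np.linalg.solve(V, r) if residual_mode == "ehat" else r
    return LMMResult(
        sigma_g=lam * sigma_e,
        sigma_e=sigma_e,
        sigma_iid=tau * sigma_e,
        h2=lam / (1.0 + lam + tau),
        beta=pd.Series(beta, index=names),
        residuals=pd.Series(resid, index=ids),
        loglik_trace=trace,
    )


def split_groups(residuals) -> pd.DataFrame:
    """Split animals into equal LP/HP halves by corrected phenotype.

    ``residuals`` is a Series indexed by id (or a two-column id/residual
    frame).  Animals are sorted by (residual, id) — the id makes boundary
    ties deterministic — the lower half is LP, the upper half HP, and for odd
    n the single median animal is dropped.  Fewer than 4 animals is an error.
    """
    if isinstance(residuals, pd.DataFrame):
        residuals = residuals.set_index("id")["residual"]
    s = pd.Series(residuals)
    n = len(s)
    if n < 4:
        raise LMMError(f"need at least 4 individuals to split, got {n}")
    order = sorted(zip(s.to_numpy(), s.index.astype(str)), key=lambda t: (t[0], t[1]))
    half = n // 2
    if n % 2:
        order = order[:half] + order[half + 1 :]
    rows = [
        {"id": iid, "residual": val, "group": "LP" if i < half else "HP"}
        for i, (val, iid) in enumerate(order)
    ]
    return pd.DataFrame(rows)
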