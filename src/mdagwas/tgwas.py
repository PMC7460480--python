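"""Single-marker regression comparator with PC correction and BH-FDR.

Each SNP's allele count is regressed on the corrected phenotype by ordinary
least squares together with an intercept and the first k principal
components of the genotype matrix (population-structure correction; PCA on
column-centered, unit-variance genotypes is the classical-MDS-equivalent
axes).  Per-SNP two-sided t tests are then adjusted by the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .plinkio import GenotypeMatrix

__all__ = ["genotype_pcs", "single_marker_scan", "fdr_adjust", "run_tgwas"]


def genotype_pcs(geno, k: int = 10, scale: bool = True) -> np.ndarray:
    """First ``k`` principal-component score columns of the genotype matrix.

    Columns are ordered by decreasing explained variance and are mutually
    orthogonal.  If the matrix rank is below ``k`` the available components
    are returned with a warning.
    """
    X = geno.imputed() if isinstance(geno, GenotypeMatrix) else np.asarray(
        geno, dtype=np.float64
    )
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need more individuals ({n}) than components ({k})")
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    poly = sd > 0
    if scale:
        Xc = Xc[:, poly] / sd[poly]
    else:
        Xc = Xc[:, poly]
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    tol = S.max(initial=0.0) * max(Xc.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if rank < k:
        warnings.warn(
            f"genotype matrix rank {rank} < requested {k} components; "
            f"returning {rank}",
            stacklevel=2,
        )
        k = rank
    return U[:, :k] * S[:k]


def single_marker_scan(y, geno, covariates=None) -> pd.DataFrame:
    """Additive per-SNP OLS scan of ``y`` on allele count + covariates.

    ``covariates`` (e.g. PC scores) are augmented with an intercept; the
    full covariate matrix must have full column rank.  Monomorphic SNPs get
    effect 0 and p = 1.  Returns a per-marker frame with columns
    ``marker chrom bp beta se t p``.
    """
    if isinstance(geno, GenotypeMatrix):
        G = geno.imputed()
        markers = geno.markers
    else:
        G = np.asarray(geno, dtype=np.float64)
        markers = pd.DataFrame(
            {
                "marker": [f"m{j}" for j in range(G.shape[1])],
                "chrom": 0,
                "bp": np.arange(G.shape[1]) + 1,
            }
        )
    y = np.asarray(y, dtype=np.float64)
    n, m = G.shape
    C = np.ones((n, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=np.float64)
        if cov.ndim == 1:
            cov = cov[:, None]
        C = np.hstack([C, cov])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix (with intercept) is rank deficient")
    df = n - C.shape[1] - 1
    if df < 1:
        raise ValueError(f"too few individuals: residual df = {df}")
    Q, _ = np.linalg.qr(C)
    yr = y - Q @ (Q.T @ y)
    Gr = G - Q @ (Q.T @ G)
    xx = np.einsum("ij,ij->j", Gr, Gr)
    xy = Gr.T @ yr
    yy = float(yr @ yr)
    ok = xx > 1e-12 * np.maximum(np.einsum("ij,ij->j", G, G), 1.0)
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    tstat = np.zeros(m)
    pval = np.ones(m)
    beta[ok] = xy[ok] / xx[ok]
    rss = np.clip(yy - beta * xy, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        se[ok] = np.sqrt(rss[ok] / df / xx[ok])
        tstat[ok] = np.where(se[ok] > 0, beta[ok] / se[ok], np.inf * np.sign(beta[ok]))
    pval[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    out = markers[["marker", "chrom", "bp"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["t"] = tstat
    out["p"] = pval
    return out


def fdr_adjust(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up adjusted q-values and significance flags.

    Returns ``(qvalues, flags)`` with ``flags = qvalues <= q``.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    _, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, qvals <= q


def run_tgwas(
    geno: GenotypeMatrix,
    corrected: pd.DataFrame,
    n_pcs: int = 10,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Full comparator scan on a corrected-phenotype table (id, residual).

    PCs are computed on the analysis subsample itself.  Returns the scan
    frame with added ``q`` and ``sig`` columns.
    """
    ids = corrected["id"].astype(str)
    sub = geno.subset_individuals(ids)
    pcs = genotype_pcs(sub, k=n_pcs) if n_pcs > 0 else None
    scan = single_marker_scan(corrected["residual"].to_numpy(float), sub, pcs)
    scan["q"], scan["sig"] = fdr_adjust(scan["p"].to_numpy(), q=fdr)
    return scan
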