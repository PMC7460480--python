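"""Two-group canonical discriminant analysis and friends.

The core machinery of the multivariate association method: canonical
discriminant analysis (CDA) for two predefined groups, Mahalanobis distance
with Hotelling's T-squared inference, stepwise discriminant variable
selection (SDA) on Wilks' lambda, and centroid-cutoff discriminant
classification (DA).

With two groups there is a single canonical function
``CAN = d1*X1 + ... + dp*Xp``; its direction is the (pseudo-)inverse of the
pooled within-group covariance applied to the mean difference, normalized so
canonical scores have unit pooled within-group variance.  When the number of
variables reaches or exceeds the number of individuals the within matrix is
singular; the Moore-Penrose pseudo-inverse (optionally ridge-stabilized)
keeps every quantity defined, and Hotelling's F uses the rank actually
inverted as the effective dimension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CanonicalFunction",
    "SeparationTest",
    "DiscriminantModel",
    "DiscriminantError",
    "two_group_stats",
    "pooled_within_cov",
    "cda_fit",
    "mahalanobis_d2",
    "hotelling_test",
    "sda_select",
    "build_da_model",
    "da_classify",
]

_EIG_RTOL = 1e-10  # relative eigenvalue cutoff for the pseudo-inverse


class DiscriminantError(ValueError):
    pass


def _resolve_groups(labels, hp_label=None):
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise DiscriminantError(f"need exactly 2 groups, got {uniq}")
    if hp_label is None:
        # the conventional group names take precedence; otherwise the
        # lexicographically larger label plays the high-phenotype role
        hp_label = "HP" if "HP" in uniq else uniq[1]
    elif hp_label not in uniq:
        raise DiscriminantError(f"hp_label {hp_label!r} not among groups {uniq}")
    lp_label = uniq[0] if uniq[1] == hp_label else uniq[1]
    return labels == hp_label, lp_label, hp_label


def two_group_stats(X, labels, hp_label=None):
    """Group means, sizes and pooled within-group covariance.

    Returns ``(m_lp, m_hp, n_lp, n_hp, W, lp_label, hp_label)`` with
    ``W = [(n1-1) S1 + (n2-1) S2] / (n1 + n2 - 2)``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise DiscriminantError("X must be 2-D (individuals x variables)")
    hp_mask, lp_label, hp_label = _resolve_groups(labels, hp_label)
    X_hp, X_lp = X[hp_mask], X[~hp_mask]
    n_hp, n_lp = len(X_hp), len(X_lp)
    if n_hp < 2 or n_lp < 2:
        raise DiscriminantError("each group needs at least 2 members")
    m_hp = X_hp.mean(axis=0)
    m_lp = X_lp.mean(axis=0)
    C_hp = X_hp - m_hp
    C_lp = X_lp - m_lp
    W = (C_hp.T @ C_hp + C_lp.T @ C_lp) / (n_hp + n_lp - 2)
    return m_lp, m_hp, n_lp, n_hp, W, lp_label, hp_label


def pooled_within_cov(X, labels, hp_label=None) -> np.ndarray:
    """Pooled within-group covariance matrix of the two groups."""
    return two_group_stats(X, labels, hp_label)[4]


@dataclass
class CanonicalFunction:
    """The single canonical function of a two-group CDA."""

    raw_coef: np.ndarray  # d_i, unit pooled within-group score variance
    cnc: np.ndarray  # within-standardized coefficients d_i * sqrt(W_ii)
    centroid_lp: float
    centroid_hp: float
    n_lp: int
    n_hp: int
    lp_label: object
    hp_label: object
    d2: float  # Mahalanobis distance between group means
    rank: int  # rank of W used in the (pseudo-)inversion
    marker_ids: Optional[np.ndarray] = None

    def scores(self, X) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) @ self.raw_coef


@dataclass
class SeparationTest:
    d2: float
    t2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float


@dataclass
class DiscriminantModel:
    canonical: CanonicalFunction
    cutoff: float


def _pinv_psd(W: np.ndarray, ridge: float = 0.0):
    """Eigenvalue pseudo-inverse of a symmetric PSD matrix; returns the
    inverse operator applied lazily plus the numerical rank."""
    if ridge:
        W = W + ridge * np.eye(W.shape[0])
    vals, vecs = np.linalg.eigh(W)
    tol = max(vals.max(initial=0.0), 0.0) * _EIG_RTOL
    keep = vals > tol
    rank = int(keep.sum())
    inv_vals = np.where(keep, 1.0 / np.where(keep, vals, 1.0), 0.0)
    return vecs, inv_vals, rank


def cda_fit(
    X,
    labels,
    ridge: float = 0.0,
    hp_label=None,
    marker_ids: Optional[Sequence] = None,
) -> CanonicalFunction:
    """Fit the two-group canonical discriminant function.

    The raw direction is ``W^+ (m_hp - m_lp)`` scaled to unit pooled
    within-group score variance and oriented so the HP centroid exceeds the
    LP centroid.  CNCs are the within-standardized coefficients
    ``d_i * sqrt(W_ii)``.
    """
    m_lp, m_hp, n_lp, n_hp, W, lp_label, hp_label = two_group_stats(
        X, labels, hp_label
    )
    diff = m_hp - m_lp
    vecs, inv_vals, rank = _pinv_psd(W, ridge)
    d = vecs @ (inv_vals * (vecs.T @ diff))
    d2 = float(diff @ d)
    if not np.any(np.abs(d) > 0):
        raise DiscriminantError(
            "identical group means with zero within-group covariance: "
            "canonical direction undefined"
        )
    v = float(d @ W @ d)
    if v > 1e-300:
        d = d / np.sqrt(v)
    else:  # zero within-group variance along d: scale by Euclidean norm
        d = d / np.linalg.norm(d)
    c_lp = float(m_lp @ d)
    c_hp = float(m_hp @ d)
    if c_hp < c_lp:
        d = -d
        c_lp, c_hp = -c_lp, -c_hp
    cnc = d * np.sqrt(np.clip(np.diag(W), 0.0, None))
    return CanonicalFunction(
        raw_coef=d,
        cnc=cnc,
        centroid_lp=c_lp,
        centroid_hp=c_hp,
        n_lp=n_lp,
        n_hp=n_hp,
        lp_label=lp_label,
        hp_label=hp_label,
        d2=d2,
        rank=rank,
        marker_ids=None if marker_ids is None else np.asarray(marker_ids, dtype=object),
    )


def mahalanobis_d2(m1, m2, W, ridge: float = 0.0) -> float:
    """Squared Mahalanobis distance ``(m2-m1)' W^+ (m2-m1)``."""
    m1 = np.asarray(m1, dtype=np.float64)
    m2 = np.asarray(m2, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if m1.shape != m2.shape or W.shape != (m1.size, m1.size):
        raise DiscriminantError(
            f"dimension mismatch: means {m1.shape}/{m2.shape}, W {W.shape}"
        )
    diff = m2 - m1
    vecs, inv_vals, _ = _pinv_psd(W, ridge)
    return float(diff @ (vecs @ (inv_vals * (vecs.T @ diff))))


def hotelling_test(d2: float, n1: int, n2: int, p: int) -> SeparationTest:
    """Two-sample Hotelling T-squared test from a Mahalanobis distance.

    ``T2 = n1 n2 / (n1 + n2) * D2`` and
    ``F = T2 (n - p - 1) / ((n - 2) p)`` with ``(p, n - p - 1)`` degrees of
    freedom, where ``p`` is the effective dimension (the rank actually used).
    """
    n = n1 + n2
    df2 = n - p - 1
    if p < 1:
        raise DiscriminantError("effective dimension must be >= 1")
    if df2 < 1:
        raise DiscriminantError(
            f"n1+n2-p-1 = {df2} < 1: reduce the dimension (rank) before testing"
        )
    t2 = n1 * n2 / n * d2
    f_stat = t2 * df2 / ((n - 2) * p)
    p_value = float(stats.f.sf(f_stat, p, df2)) if d2 > 0 else 1.0
    return SeparationTest(
        d2=float(d2), t2=float(t2), f_stat=float(f_stat), df1=p, df2=df2,
        p_value=p_value,
    )


# ---------------------------------------------------------------------------
# stepwise discriminant analysis


def _lambda_ratio_f(d2_small, d2_big, c, df2):
    """Partial F for a one-variable change between nested subsets."""
    return df2 * c * (d2_big - d2_small) / (1.0 + c * d2_small)


def sda_select(
    X,
    labels,
    sle: float = 0.15,
    sls: float = 0.15,
    max_vars: Optional[int] = None,
    tol: float = 1e-8,
    hp_label=None,
) -> np.ndarray:
    """Forward-with-removal stepwise variable selection on Wilks' lambda.

    At each step the candidate with the best partial F given the entered set
    joins if its p-value is <= ``sle``; entered variables whose partial F
    p-value exceeds ``sls`` are then removed (worst first).  Candidates whose
    within-group variance after residualization on the entered set falls
    below ``tol`` of the original (near-exact collinearity) are ineligible.
    Selection stops when no entry or removal is possible, the error degrees
    of freedom are exhausted, or ``max_vars`` (default ``n1 + n2 - 2``) is
    reached.  Returns entered column indices in entry order; empty selection
    is a valid result.

    For two groups Wilks' lambda for a subset S is
    ``1 / (1 + c * D2_S)`` with ``c = n1 n2 / ((n1+n2)(n1+n2-2))``, so the
    procedure tracks the Mahalanobis distance of nested subsets
    incrementally (residualized mean differences within groups).
    """
    m_lp, m_hp, n_lp, n_hp, W, _, _ = two_group_stats(X, labels, hp_label)
    X = np.asarray(X, dtype=np.float64)
    hp_mask, _, _ = _resolve_groups(labels, hp_label)
    n, p = X.shape
    c = n_lp * n_hp / (n * (n - 2))
    if max_vars is None:
        max_vars = n - 2
    max_vars = min(max_vars, p)

    # group-centered data: within-group scatter and regressions
    Xc = X.copy()
    Xc[hp_mask] -= m_hp
    Xc[~hp_mask] -= m_lp
    diff = m_hp - m_lp
    w_orig = np.clip(np.diag(W).copy(), 0.0, None)

    entered: list[int] = []
    Winv = np.empty((0, 0))
    Xres = Xc.copy()
    dres = diff.copy()
    eligible = w_orig > 0
    d2 = 0.0
    seen_states: set[frozenset] = set()

    def rebuild_residuals():
        nonlocal Xres, dres
        Xres = Xc.copy()
        dres = diff.copy()
        for e in entered:
            denom = Xres[:, e] @ Xres[:, e]
            if denom <= 0:
                continue
            b = (Xres.T @ Xres[:, e]) / denom
            dres = dres - b * dres[e]
            Xres = Xres - np.outer(Xres[:, e], b)

    while True:
        k = len(entered)
        df2 = n - 2 - k
        did_something = False

        if k < max_vars and df2 >= 1:
            wres = (Xres * Xres).sum(axis=0) / (n - 2)
            cand = eligible.copy()
            cand[entered] = False
            cand &= wres > tol * np.where(w_orig > 0, w_orig, 1.0)
            if cand.any():
                with np.errstate(divide="ignore", invalid="ignore"):
                    inc = np.where(cand, dres * dres / np.where(cand, wres, 1.0), -np.inf)
                j = int(np.argmax(inc))
                f_j = _lambda_ratio_f(d2, d2 + inc[j], c, df2)
                p_j = float(stats.f.sf(f_j, 1, df2))
                if p_j <= sle:
                    # block-update the inverse of W over the entered set
                    if k == 0:
                        Winv = np.array([[1.0 / W[j, j]]])
                    else:
                        b = W[np.ix_(entered, [j])][:, 0]
                        u = Winv @ b
                        s = W[j, j] - b @ u
                        if s <= tol * max(W[j, j], 1.0):
                            eligible[j] = False
                            continue
                        Winv = np.block(
                            [
                                [Winv + np.outer(u, u) / s, -u[:, None] / s],
                                [-u[None, :] / s, np.array([[1.0 / s]])],
                            ]
                        )
                    entered.append(j)
                    d2 = d2 + inc[j]
                    # residualize everything on the newly entered column
                    denom = Xres[:, j] @ Xres[:, j]
                    b = (Xres.T @ Xres[:, j]) / denom
                    dres = dres - b * dres[j]
                    Xres = Xres - np.outer(Xres[:, j], b)
                    did_something = True

        # removal phase
        while len(entered) > 0:
            k = len(entered)
            dE = diff[entered]
            a = Winv @ dE
            d2_full = float(dE @ a)
            diag = np.diag(Winv)
            d2_minus = d2_full - a * a / diag
            df2_rem = n - 1 - k
            if df2_rem < 1:
                break
            f_rem = _lambda_ratio_f(d2_minus, d2_full, c, df2_rem)
            p_rem = stats.f.sf(f_rem, 1, df2_rem)
            worst = int(np.argmax(p_rem))
            if p_rem[worst] <= sls:
                d2 = d2_full
                break
            j = entered.pop(worst)
            keep = [i for i in range(k) if i != worst]
            Winv = (
                Winv[np.ix_(keep, keep)]
                - np.outer(Winv[keep, worst], Winv[worst, keep]) / Winv[worst, worst]
            )
            d2 = float(d2_minus[worst])
            rebuild_residuals()
            did_something = True

        state = frozenset(entered)
        if state in seen_states or not did_something:
            break
        seen_states.add(state)

    return np.array(entered, dtype=np.intp)


# ---------------------------------------------------------------------------
# discriminant classification


def build_da_model(canonical: CanonicalFunction) -> DiscriminantModel:
    """Cutoff = group-size-weighted mean of the two centroids."""
    n = canonical.n_lp + canonical.n_hp
    cutoff = (
        canonical.n_lp * canonical.centroid_lp + canonical.n_hp * canonical.centroid_hp
    ) / n
    return DiscriminantModel(canonical=canonical, cutoff=cutoff)


def da_classify(model: DiscriminantModel, X, true_labels=None):
    """Assign each row of ``X`` by its canonical score against the cutoff.

    Scores below the cutoff go to the group with the lower centroid (LP);
    scores at or above it go to HP.  Returns ``(labels, accuracy)`` where
    accuracy is the fraction of ``true_labels`` recovered (None if no truth
    given).
    """
    can = model.canonical
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != can.raw_coef.size:
        raise DiscriminantError(
            f"X has {X.shape[1]} variables, model expects {can.raw_coef.size}"
        )
    scores = can.scores(X)
    labels = np.where(scores < model.cutoff, can.lp_label, can.hp_label)
    accuracy = None
    if true_labels is not None:
        accuracy = float(np.mean(labels == np.asarray(true_labels)))
    return labels, accuracy
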