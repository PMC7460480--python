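"""The four-step multivariate discriminant association pipeline.

Given SNP genotypes and an LP/HP grouping of mixed-model-corrected
phenotypes:

1. fit a canonical discriminant analysis per chromosome and retain markers
   whose |CNC| strictly exceeds the chromosome's mean + 1 SD of |CNC|;
2. pool the retained markers and reduce them to a linearly independent
   subset by stepwise discriminant analysis (at most n - 2 markers);
3. fit the genome-wide CDA on that subset; its Hotelling test and the
   discriminant-classification training accuracy validate the separation;
4. prune recursively: refit the CDA, drop the marker(s) with the smallest
   |CNC|, and stop just before the Hotelling p-value reaches ``alpha`` or
   perfect classification is lost.  The surviving minimal set is the
   associated-marker set; a "top" subset keeps those with |CNC| at or above
   an arbitrary threshold (0.25 by default).

CNCs are re-estimated after every removal (the pruning is genuinely
recursive, not a one-shot ranking), and one marker is removed per iteration
by default — the most conservative batch size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import discrim
from .discrim import (
    CanonicalFunction,
    DiscriminantError,
    SeparationTest,
    build_da_model,
    cda_fit,
    da_classify,
    hotelling_test,
)
from .plinkio import GenotypeMatrix

__all__ = [
    "MGwasParams",
    "StageResult",
    "MGwasResult",
    "MGwasError",
    "select_per_chromosome",
    "reduce_sda",
    "validate_separation",
    "prune_minimal",
    "top_discriminant",
    "run_mgwas",
]

logger = logging.getLogger("mdagwas.mgwas")


class MGwasError(RuntimeError):
    pass


@dataclass
class MGwasParams:
    alpha: float = 0.001  # Hotelling significance kept throughout pruning
    cnc_top: float = 0.25  # |CNC| threshold of the "top discriminant" subset
    sle: float = 0.15  # stepwise entry significance level
    sls: float = 0.15  # stepwise stay significance level
    batch: int = 1  # markers removed per pruning iteration
    ridge: float = 0.0


@dataclass
class StageResult:
    stage: str
    marker_ids: np.ndarray
    cnc: Optional[pd.Series] = None  # |CNC| is the ranking quantity
    test: Optional[SeparationTest] = None
    accuracy: Optional[float] = None


@dataclass
class MGwasResult:
    stages: dict
    params: MGwasParams

    def stage_ids(self, name: str) -> np.ndarray:
        return self.stages[name].marker_ids

    def summary(self) -> dict:
        out = {}
        for name, st in self.stages.items():
            entry = {"n_markers": int(len(st.marker_ids))}
            if st.test is not None:
                entry.update(
                    d2=st.test.d2, t2=st.test.t2, f=st.test.f_stat,
                    df1=st.test.df1, df2=st.test.df2, p_value=st.test.p_value,
                )
            if st.accuracy is not None:
                entry["accuracy"] = st.accuracy
            out[name] = entry
        return out


def _aligned(geno: GenotypeMatrix, groups: pd.DataFrame):
    sub = geno.subset_individuals(groups["id"].astype(str))
    X = sub.imputed()
    labels = groups["group"].to_numpy()
    return sub, X, labels


def _polymorphic(X: np.ndarray) -> np.ndarray:
    return X.std(axis=0) > 0


def cnc_retention_mask(abs_cnc) -> np.ndarray:
    """Step-1 retention rule: |CNC| strictly above mean + 1 sample SD.

    A single value is retained by convention (its SD is undefined); when all
    values are equal the SD is zero and the strict inequality retains
    nothing.
    """
    a = np.asarray(abs_cnc, dtype=np.float64)
    if a.size == 1:
        return np.ones(1, dtype=bool)
    return a > a.mean() + a.std(ddof=1)


def select_per_chromosome(
    geno: GenotypeMatrix, groups: pd.DataFrame, params: MGwasParams = MGwasParams()
) -> dict:
    """Step 1: per-chromosome CDA and the mean + 1 SD rule on |CNC|.

    Markers monomorphic in the analysed sample are dropped first (their
    canonical coefficient is undefined).  A chromosome with a single marker
    retains it by convention (the SD of one value is undefined); the SD is
    the sample SD (ddof=1) over the chromosome's markers and the inequality
    is strict, so a chromosome whose |CNC|s are all equal retains nothing.
    Returns {chrom: array of retained marker ids}.
    """
    sub, X, labels = _aligned(geno, groups)
    poly = _polymorphic(X)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("dropping %d monomorphic markers before step 1", n_dropped)
    retained: dict = {}
    for chrom, mk in sub.markers.groupby("chrom", sort=True):
        cols = mk.index.to_numpy()
        cols = cols[poly[cols]]
        if len(cols) == 0:
            logger.warning("chromosome %s: no polymorphic markers", chrom)
            retained[chrom] = np.array([], dtype=object)
            continue
        ids = sub.markers["marker"].to_numpy(object)[cols]
        if len(cols) == 1:
            retained[chrom] = ids
            continue
        can = cda_fit(X[:, cols], labels, ridge=params.ridge)
        retained[chrom] = ids[cnc_retention_mask(np.abs(can.cnc))]
    return retained


def reduce_sda(
    geno: GenotypeMatrix,
    groups: pd.DataFrame,
    retained_ids,
    params: MGwasParams = MGwasParams(),
) -> np.ndarray:
    """Step 2: stepwise reduction of the pooled retained markers to a
    linearly independent discriminating subset (size <= n - 2)."""
    retained_ids = np.asarray(list(retained_ids), dtype=object)
    if len(retained_ids) == 0:
        return retained_ids
    sub, X, labels = _aligned(geno.subset_markers(retained_ids), groups)
    cols = discrim.sda_select(
        X, labels, sle=params.sle, sls=params.sls, hp_label="HP"
    )
    return sub.markers["marker"].to_numpy(object)[cols]


def validate_separation(
    geno: GenotypeMatrix,
    groups: pd.DataFrame,
    marker_ids,
    params: MGwasParams = MGwasParams(),
):
    """Step 3: genome-wide CDA on a marker set -> Hotelling test + DA
    training accuracy.  Effective dimension is the rank of the within
    matrix actually inverted."""
    marker_ids = np.asarray(list(marker_ids), dtype=object)
    if len(marker_ids) == 0:
        raise MGwasError("cannot validate an empty marker set")
    sub, X, labels = _aligned(geno.subset_markers(marker_ids), groups)
    can = cda_fit(X, labels, ridge=params.ridge, hp_label="HP",
                  marker_ids=sub.markers["marker"].to_numpy(object))
    test = hotelling_test(can.d2, can.n_lp, can.n_hp, can.rank)
    _, acc = da_classify(build_da_model(can), X, labels)
    return test, acc, can


def _centered(X, labels):
    hp = labels == "HP"
    Xc = X.copy()
    m_hp = X[hp].mean(axis=0)
    m_lp = X[~hp].mean(axis=0)
    Xc[hp] -= m_hp
    Xc[~hp] -= m_lp
    return Xc, m_lp, m_hp, int((~hp).sum()), int(hp.sum())


def prune_minimal(
    geno: GenotypeMatrix,
    groups: pd.DataFrame,
    marker_ids,
    params: MGwasParams = MGwasParams(),
):
    """Step 4: recursive pruning of low-|CNC| markers.

    Repeatedly refits the CDA on the current set, removes the ``batch``
    markers with the smallest |CNC| and revalidates; when the Hotelling
    p-value reaches ``alpha`` or an animal is misassigned, the removal is
    undone and pruning stops.  Returns
    ``(minimal ids, canonical function, test, accuracy)``.

    When the number of selected markers approaches the number of animals the
    Hotelling F has almost no error degrees of freedom, so the *input* set
    may not yet test significant even though it separates the groups
    perfectly.  Pruning then first descends — deleting low-|CNC| markers
    strictly improves the test by freeing degrees of freedom — until both
    criteria hold, and only then searches for the minimal satisfying set.
    An input from which the criteria are never reached is an error.

    Markers that are collinear with the rest of the set within floating
    precision carry no discriminant information and are dropped up front
    (pivoted-QR rank filter); the within-group inverse is maintained by
    rank-one downdates with periodic refresh, so a full prune costs O(k^3)
    rather than O(k^4).
    """
    from scipy import linalg as sla

    marker_ids = np.asarray(list(marker_ids), dtype=object)
    sub, X, labels = _aligned(geno.subset_markers(marker_ids), groups)
    ids = sub.markers["marker"].to_numpy(object)
    n, k0 = X.shape
    Xc, m_lp, m_hp, n_lp, n_hp = _centered(X, labels)
    W_full = (Xc.T @ Xc) / (n - 2)
    diff_full = m_hp - m_lp
    w_diag = np.clip(np.diag(W_full), 0.0, None)

    # numerical-rank filter: keep a maximal well-conditioned subset
    _, R, piv = sla.qr(Xc, mode="economic", pivoting=True)
    rdiag = np.abs(np.diag(R))
    rtol = rdiag.max(initial=0.0) * max(Xc.shape) * np.finfo(float).eps
    rank = int((rdiag > rtol).sum())
    if rank < k0:
        logger.info("dropping %d collinear markers before pruning", k0 - rank)
    cur = sorted(piv[:rank].tolist())

    def fresh_inverse(idx):
        Wc = W_full[np.ix_(idx, idx)]
        try:
            cf = sla.cho_factor(Wc)
            return sla.cho_solve(cf, np.eye(len(idx)))
        except np.linalg.LinAlgError:
            return np.linalg.pinv(Wc, rcond=1e-12)

    Winv = fresh_inverse(cur)

    def evaluate(cur_idx, Winv_cur):
        idx = np.asarray(cur_idx)
        dE = diff_full[idx]
        a = Winv_cur @ dE
        d2 = float(dE @ a)
        if d2 <= 0:
            return None
        d = a / np.sqrt(d2)  # unit within-variance since d'Wd = d'dE = d2
        c_lp = float(m_lp[idx] @ d)
        c_hp = float(m_hp[idx] @ d)
        if c_hp < c_lp:
            d, c_lp, c_hp = -d, -c_hp, -c_lp
        test = hotelling_test(d2, n_lp, n_hp, len(idx))
        cutoff = (n_lp * c_lp + n_hp * c_hp) / n
        scores = X[:, idx] @ d
        pred = np.where(scores < cutoff, "LP", "HP")
        acc = float(np.mean(pred == labels))
        cnc = d * np.sqrt(w_diag[idx])
        return d, cnc, test, acc, (c_lp, c_hp)

    state = evaluate(cur, Winv)
    if state is None:
        raise MGwasError("degenerate separation on the input set")
    d, cnc, test, acc, cents = state
    satisfied = test.p_value < params.alpha and acc >= 1.0
    if not satisfied and acc < 1.0:
        raise MGwasError(
            f"input set does not separate the groups perfectly "
            f"(accuracy={acc:.3f}); pruning cannot proceed"
        )

    since_refresh = 0
    while len(cur) > params.batch:
        order = np.argsort(np.abs(cnc), kind="stable")
        drop_local = order[: params.batch]
        trial = [m for i, m in enumerate(cur) if i not in set(drop_local.tolist())]
        Winv_trial = Winv
        for dl in sorted(drop_local.tolist(), reverse=True):
            kk = Winv_trial.shape[0]
            keep = [i for i in range(kk) if i != dl]
            Winv_trial = (
                Winv_trial[np.ix_(keep, keep)]
                - np.outer(Winv_trial[keep, dl], Winv_trial[dl, keep])
                / Winv_trial[dl, dl]
            )
        since_refresh += 1
        if since_refresh >= 32:
            Winv_trial = fresh_inverse(trial)
            since_refresh = 0
        try:
            trial_state = evaluate(trial, Winv_trial)
        except DiscriminantError:
            if satisfied:
                break
            raise MGwasError("degrees of freedom exhausted before the "
                             "pruning criteria were ever satisfied")
        if trial_state is None:
            break
        t_d, t_cnc, t_test, t_acc, t_cents = trial_state
        t_ok = t_test.p_value < params.alpha and t_acc >= 1.0
        if satisfied and not t_ok:
            break  # minimal satisfying set reached: undo and stop
        cur, Winv = trial, Winv_trial
        d, cnc, test, acc, cents = t_d, t_cnc, t_test, t_acc, t_cents
        satisfied = satisfied or t_ok
        if not satisfied and t_acc < 1.0:
            raise MGwasError(
                "perfect classification lost before the Hotelling criterion "
                "was ever met; no minimal set exists for this input"
            )

    if not satisfied:
        raise MGwasError(
            f"pruning never reached the criteria (final p={test.p_value:.3g}, "
            f"accuracy={acc:.3f})"
        )

    idx = np.asarray(cur)
    can = CanonicalFunction(
        raw_coef=d,
        cnc=cnc,
        centroid_lp=cents[0],
        centroid_hp=cents[1],
        n_lp=n_lp,
        n_hp=n_hp,
        lp_label="LP",
        hp_label="HP",
        d2=test.d2,
        rank=len(idx),
        marker_ids=ids[idx],
    )
    return ids[idx], can, test, acc


def top_discriminant(canonical: CanonicalFunction, cnc_threshold: float = 0.25):
    """Markers of the minimal set with |CNC| at or above the threshold
    (inclusive), ranked by |CNC| descending."""
    if canonical.marker_ids is None:
        raise MGwasError("canonical function carries no marker ids")
    a = np.abs(canonical.cnc)
    keep = np.flatnonzero(a >= cnc_threshold)
    keep = keep[np.argsort(-a[keep], kind="stable")]
    return canonical.marker_ids[keep], pd.Series(
        canonical.cnc[keep], index=canonical.marker_ids[keep]
    )


def run_mgwas(
    geno: GenotypeMatrix, groups: pd.DataFrame, params: MGwasParams = MGwasParams()
) -> MGwasResult:
    """Run steps 1-4 and return the per-stage marker sets and statistics.

    Deterministic given its inputs; any stage failure is re-raised with the
    stage name attached.
    """
    stages: dict = {}

    retained = select_per_chromosome(geno, groups, params)
    union = np.concatenate([v for v in retained.values()]) if retained else np.array([])
    stages["per_chromosome"] = StageResult("per_chromosome", union)
    logger.info("step 1: retained %d markers across chromosomes", len(union))
    if len(union) == 0:
        raise MGwasError("step 1 (per-chromosome CDA) retained no markers")

    try:
        sda_ids = reduce_sda(geno, groups, union, params)
    except Exception as e:
        raise MGwasError(f"step 2 (stepwise reduction) failed: {e}") from e
    logger.info("step 2: %d linearly independent markers", len(sda_ids))
    if len(sda_ids) == 0:
        raise MGwasError("step 2 (stepwise reduction) selected no markers")

    try:
        test, acc, can = validate_separation(geno, groups, sda_ids, params)
    except Exception as e:
        raise MGwasError(f"step 3 (separation validation) failed: {e}") from e
    stages["sda_independent"] = StageResult(
        "sda_independent", np.asarray(sda_ids, dtype=object),
        cnc=pd.Series(can.cnc, index=can.marker_ids), test=test, accuracy=acc,
    )
    logger.info("step 3: p=%.3g accuracy=%.3f", test.p_value, acc)

    try:
        min_ids, min_can, min_test, min_acc = prune_minimal(
            geno, groups, sda_ids, params
        )
    except MGwasError as e:
        raise MGwasError(f"step 4 (recursive pruning) failed: {e}") from e
    stages["minimal"] = StageResult(
        "minimal", min_ids, cnc=pd.Series(min_can.cnc, index=min_ids),
        test=min_test, accuracy=min_acc,
    )
    logger.info("step 4: minimal set of %d markers (p=%.3g)", len(min_ids),
                min_test.p_value)

    top_ids, top_cnc = top_discriminant(min_can, params.cnc_top)
    stages["top"] = StageResult("top", top_ids, cnc=top_cnc,
                                test=min_test, accuracy=min_acc)
    return MGwasResult(stages=stages, params=params)


def stages_table(result: MGwasResult, geno: GenotypeMatrix) -> pd.DataFrame:
    """Tidy per-marker table (`marker chrom bp cnc stage`) across stages."""
    mk = geno.markers.set_index("marker")
    rows = []
    for name, st in result.stages.items():
        for m in st.marker_ids:
            cnc = float(st.cnc[m]) if st.cnc is not None and m in st.cnc else np.nan
            rows.append(
                {
                    "marker": m,
                    "chrom": mk.loc[m, "chrom"],
                    "bp": int(mk.loc[m, "bp"]),
                    "cnc": cnc,
                    "stage": name,
                }
            )
    return pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cnc", "stage"])
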