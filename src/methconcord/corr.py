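"""Correlation machinery.

Across-subject (Pearson on per-probe means), within-subject per-CpG Spearman
with exact small-n permutation p-values, critical-rho inversion, BH q-values,
per-subject correlations with the cross-pair coupling statistic, classical
MDS, and ancestry PCs from SNP-overlapping probes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .types import MultiTissueDataset, pair_label

logger = logging.getLogger(__name__)

DEFAULT_MIN_N = 5
#: largest pairwise-complete n routed to the exhaustive permutation null
EXACT_MAX_N = 8

REASON_OK = ""
REASON_INSUFFICIENT_N = "insufficient_n"
REASON_ZERO_VARIANCE = "zero_variance"


# ---------------------------------------------------------------------------
# Spearman engine
# ---------------------------------------------------------------------------

def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=1, method="average")


def _row_pearson(ra: np.ndarray, rb: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson correlation; second return flags zero-variance rows."""
    a = ra - ra.mean(axis=1, keepdims=True)
    b = rb - rb.mean(axis=1, keepdims=True)
    sa = np.sqrt((a * a).sum(axis=1))
    sb = np.sqrt((b * b).sum(axis=1))
    degenerate = (sa == 0) | (sb == 0)
    denom = np.where(degenerate, 1.0, sa * sb)
    rho = (a * b).sum(axis=1) / denom
    rho[degenerate] = np.nan
    return np.clip(rho, -1.0, 1.0), degenerate


@lru_cache(maxsize=8)
def _exact_null(n: int) -> np.ndarray:
    """Sorted |rho| values of the exhaustive n! Spearman permutation null
    (no ties: both rank vectors are permutations of 1..n)."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    ranks = base[perms]                      # (n!, n)
    c = base - base.mean()
    d = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((c * c).sum()) * np.sqrt((d * d).sum(axis=1))
    rho = (d @ c) / denom
    return np.sort(np.abs(rho))


def exact_permutation_p(rho: float, n: int) -> float:
    """Two-sided exact Spearman p: fraction of the n! permutations whose
    |rho| is at least |rho| (within a small numeric tolerance)."""
    null = _exact_null(n)
    target = abs(rho) - 1e-9
    idx = np.searchsorted(null, target, side="left")
    return float((null.size - idx) / null.size)


def t_approximation_p(rho: np.ndarray, n) -> np.ndarray:
    """Two-sided p via t = r*sqrt((n-2)/(1-r^2)), df = n-2."""
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - rho * rho
        t = np.abs(rho) * np.sqrt(np.where(denom > 0, (n - 2) / denom, np.inf))
    p = 2.0 * stats.t.sf(t, np.maximum(n - 2, 1e-300))
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.minimum(p, 1.0)


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def within_subject_cpg_correlation(betaA: pd.DataFrame, betaB: pd.DataFrame,
                                   min_n: int = DEFAULT_MIN_N,
                                   tissue_pair: Optional[str] = None,
                                   ) -> pd.DataFrame:
    """Per-CpG Spearman correlation across subjects between two tissues.

    Pairwise-complete subjects per probe; probes with fewer than ``min_n``
    usable subjects, or zero variance in either tissue, get an undefined rho
    with a reason code.  p-values use the exhaustive permutation null for
    n <= 8 without ties and the t-approximation (df = n-2) otherwise; q is
    the BH adjustment over all defined p of this table.
    """
    probes = betaA.index.intersection(betaB.index)
    subjects = [s for s in betaA.columns if s in set(betaB.columns)]
    A = betaA.loc[probes, subjects].to_numpy(dtype=float)
    B = betaB.loc[probes, subjects].to_numpy(dtype=float)
    n_probes = len(probes)

    rho = np.full(n_probes, np.nan)
    p = np.full(n_probes, np.nan)
    reason = np.full(n_probes, REASON_OK, dtype=object)

    finite = np.isfinite(A) & np.isfinite(B)
    n_used = finite.sum(axis=1)
    too_few = n_used < min_n
    reason[too_few] = REASON_INSUFFICIENT_N

    complete = finite.all(axis=1) & ~too_few
    if complete.any():
        idx = np.flatnonzero(complete)
        ra = _rank_rows(A[idx])
        rb = _rank_rows(B[idx])
        r, degen = _row_pearson(ra, rb)
        rho[idx] = r
        reason[idx[degen]] = REASON_ZERO_VARIANCE
        ok = idx[~degen]
        n_here = A.shape[1]
        if n_here <= EXACT_MAX_N:
            for i in ok:
                if _has_ties(A[i]) or _has_ties(B[i]):
                    p[i] = t_approximation_p(rho[i], n_here)
                else:
                    p[i] = exact_permutation_p(rho[i], n_here)
        else:
            p[ok] = t_approximation_p(rho[ok], n_here)

    for i in np.flatnonzero(~complete & ~too_few):
        mask = finite[i]
        a, b = A[i, mask], B[i, mask]
        if np.unique(a).size < 2 or np.unique(b).size < 2:
            reason[i] = REASON_ZERO_VARIANCE
            continue
        ra = stats.rankdata(a, method="average")
        rb = stats.rankdata(b, method="average")
        r, _ = _row_pearson(ra[None, :], rb[None, :])
        rho[i] = r[0]
        ni = int(mask.sum())
        if ni <= EXACT_MAX_N and not _has_ties(a) and not _has_ties(b):
            p[i] = exact_permutation_p(rho[i], ni)
        else:
            p[i] = float(t_approximation_p(rho[i], ni))

    q = bh_adjust(p)
    out = pd.DataFrame({
        "probe_id": probes.astype(str),
        "tissue_pair": tissue_pair if tissue_pair is not None else "",
        "rho": rho,
        "p": p,
        "q": q,
        "n_used": n_used,
        "reason_code": reason,
    })
    return out


# ---------------------------------------------------------------------------
# Significance helpers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CriticalRho:
    exact: float
    rounded: float
    n: int
    alpha: float


def critical_rho(n: int, alpha: float = 0.05) -> CriticalRho:
    """Smallest |rho| nominally significant (two-sided) at sample size n.

    ``exact`` inverts the t-approximation p-value at alpha by bisection;
    ``rounded`` is the smallest two-decimal value whose p is strictly below
    alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    f = lambda r: float(t_approximation_p(np.array(r), n)) - alpha
    exact = brentq(f, 1e-12, 1 - 1e-12, xtol=1e-12)
    rounded = next(c / 100 for c in range(0, 101)
                   if float(t_approximation_p(np.array(c / 100), n)) < alpha)
    return CriticalRho(exact=float(exact), rounded=float(rounded), n=n, alpha=alpha)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.  NaN p propagate as NaN
    and are excluded from m.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    defined = np.isfinite(p)
    pd_ = p[defined]
    m = pd_.size
    if m == 0:
        return q
    order = np.argsort(pd_, kind="mergesort")
    ranked = pd_[order] * m / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.minimum(qs, 1.0)
    out = np.empty(m)
    out[order] = qs
    q[defined] = out
    return q


@dataclass
class CorrelationSummary:
    tissue_pair: str
    n_defined: int
    frac_nominal: float
    frac_moderate: float
    frac_moderate_negative: float
    rho_mean: float
    rho_median: float
    n_bh_significant: int
    min_rho_bh: float


def summarize(records: pd.DataFrame, q_threshold: float = 0.05,
              p_threshold: float = 0.05, rho_threshold: float = 0.5,
              ) -> CorrelationSummary:
    """Headline fractions over the probes with a defined rho."""
    if records.empty:
        raise ValueError("no correlation records to summarize")
    defined = records.loc[np.isfinite(records["rho"].to_numpy(dtype=float))]
    rho = defined["rho"].to_numpy(dtype=float)
    p = defined["p"].to_numpy(dtype=float)
    q = defined["q"].to_numpy(dtype=float)
    survivors = np.abs(rho[np.isfinite(q) & (q < q_threshold)])
    pairs = records["tissue_pair"].unique()
    return CorrelationSummary(
        tissue_pair=pairs[0] if len(pairs) == 1 else "mixed",
        n_defined=len(defined),
        frac_nominal=float(np.mean(p < p_threshold)) if len(defined) else np.nan,
        frac_moderate=float(np.mean(rho > rho_threshold)) if len(defined) else np.nan,
        frac_moderate_negative=float(np.mean(rho < -rho_threshold)) if len(defined) else np.nan,
        rho_mean=float(np.mean(rho)) if len(defined) else np.nan,
        rho_median=float(np.median(rho)) if len(defined) else np.nan,
        n_bh_significant=int(survivors.size),
        min_rho_bh=float(survivors.min()) if survivors.size else np.nan,
    )


# ---------------------------------------------------------------------------
# Across-subject / per-subject correlations
# ---------------------------------------------------------------------------

@dataclass
class AcrossSubjectSummary:
    tissue_pair: str
    r: float
    n_probes: int


def across_subject_correlation(betaA: pd.DataFrame, betaB: pd.DataFrame,
                               probe_set: Optional[Iterable[str]] = None,
                               tissue_pair: str = "",
                               ) -> AcrossSubjectSummary:
    """Pearson r between the two tissues' per-probe cross-subject means."""
    probes = betaA.index.intersection(betaB.index)
    if probe_set is not None:
        probes = probes.intersection(pd.Index(probe_set))
    if len(probes) < 2:
        raise ValueError("need at least 2 probes in common")
    ma = np.nanmean(betaA.loc[probes].to_numpy(dtype=float), axis=1)
    mb = np.nanmean(betaB.loc[probes].to_numpy(dtype=float), axis=1)
    keep = np.isfinite(ma) & np.isfinite(mb)
    ma, mb = ma[keep], mb[keep]
    if ma.size < 2 or np.std(ma) == 0 or np.std(mb) == 0:
        raise ValueError("undefined result: zero-variance mean vector")
    r = float(np.corrcoef(ma, mb)[0, 1])
    return AcrossSubjectSummary(tissue_pair=tissue_pair, r=r, n_probes=int(ma.size))


def per_subject_correlation(dataset: MultiTissueDataset,
                            probe_set: Optional[Iterable[str]] = None,
                            pairs: Optional[Sequence[Tuple[str, str]]] = None,
                            ) -> pd.DataFrame:
    """Per-subject Pearson correlation between tissue beta vectors.

    Rows are subjects, columns canonical tissue-pair labels.
    """
    tissues = dataset.tissues
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(tissues) for b in tissues[i + 1:]]
    probes = dataset.probes
    for t in tissues:
        probes = probes.intersection(dataset.betas[t].index)
    if probe_set is not None:
        probes = probes.intersection(pd.Index(probe_set))
    if len(probes) < 2:
        raise ValueError("need at least 2 probes")

    out = pd.DataFrame(index=pd.Index(dataset.subjects, name="subject_id"))
    for a, b in pairs:
        label = pair_label(a, b)
        va = dataset.betas[a].loc[probes].to_numpy(dtype=float)
        vb = dataset.betas[b].loc[probes].to_numpy(dtype=float)
        vals = []
        for j, subj in enumerate(dataset.subjects):
            x, y = va[:, j], vb[:, j]
            keep = np.isfinite(x) & np.isfinite(y)
            if keep.sum() < 2 or np.std(x[keep]) == 0 or np.std(y[keep]) == 0:
                logger.warning("subject %s skipped for pair %s", subj, label)
                vals.append(np.nan)
            else:
                vals.append(float(np.corrcoef(x[keep], y[keep])[0, 1]))
        out[label] = vals
    return out


def coupling(per_subject: pd.DataFrame, pair_x: str, pair_y: str,
             ) -> Tuple[float, float]:
    """Pearson correlation over subjects between two per-subject correlation
    columns (e.g. brain-buccal coupled with blood-buccal), with its p-value."""
    x = per_subject[pair_x].to_numpy(dtype=float)
    y = per_subject[pair_y].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

def stack_samples(dataset: MultiTissueDataset) -> pd.DataFrame:
    """All samples (tissue x subject) as rows over complete-case probes."""
    probes = dataset.probes
    for t in dataset.tissues:
        beta = dataset.betas[t]
        probes = probes.intersection(beta.index[~beta.isna().any(axis=1)])
    rows, index = [], []
    for t in dataset.tissues:
        block = dataset.betas[t].loc[probes]
        for subj in block.columns:
            rows.append(block[subj].to_numpy(dtype=float))
            index.append((t, subj))
    return pd.DataFrame(rows,
                        index=pd.MultiIndex.from_tuples(index, names=["tissue", "subject_id"]))


def mds_embedding(samples: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of the sample x feature matrix.

    Double-centers the squared Euclidean distance matrix and returns the
    top-k eigenvectors scaled by sqrt(eigenvalue); deterministic up to sign.
    """
    X = samples.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    sq = (X * X).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.clip(D2, 0.0, None, out=D2)
    J = np.eye(n) - 1.0 / n
    Bmat = -0.5 * J @ D2 @ J
    w, v = np.linalg.eigh(Bmat)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > max(w.max(), 0.0) * 1e-12
    n_pos = int(pos.sum())
    kk = min(k, n_pos)
    if kk < k:
        logger.warning("only %d positive eigenvalues; returning %d dims", n_pos, kk)
    coords = v[:, :kk] * np.sqrt(w[:kk])
    return pd.DataFrame(coords, index=samples.index,
                        columns=[f"dim{i + 1}" for i in range(kk)])


def ancestry_pcs(beta: pd.DataFrame, annotation: pd.DataFrame,
                 max_dist: int = 0, k: int = 3) -> pd.DataFrame:
    """Subject PC scores from SNP-overlapping probes.

    Probes within ``max_dist`` bp of a SNP are selected, centered per probe,
    and the top-k left singular vectors of the subject x probe matrix are
    scaled by their singular values.  Deterministic up to sign.
    """
    dist = pd.to_numeric(annotation["snp_distance_bp"], errors="coerce")
    keep = annotation.loc[dist.le(max_dist).fillna(False), "probe_id"].astype(str)
    probes = beta.index.intersection(pd.Index(keep))
    if len(probes) == 0:
        raise ValueError(f"no probes within {max_dist} bp of a SNP")
    n_subj = beta.shape[1]
    if n_subj < k + 1:
        raise ValueError(f"need at least k+1={k + 1} subjects, got {n_subj}")
    M = beta.loc[probes].to_numpy(dtype=float).T        # subjects x probes
    M = M - np.nanmean(M, axis=0, keepdims=True)
    M = np.nan_to_num(M, nan=0.0)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    kk = min(k, s.size)
    scores = U[:, :kk] * s[:kk]
    return pd.DataFrame(scores, index=pd.Index(beta.columns, name="subject_id"),
                        columns=[f"PC{i + 1}" for i in range(kk)])
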