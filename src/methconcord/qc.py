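"""Probe-level quality filters: SNP proximity, greedy-cut, probe context."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-rule removal bookkeeping; per-rule counts may overlap."""

    n_input_probes: int = 0
    removed_snp_proximity: int = 0
    removed_detection: int = 0
    removed_context: int = 0
    n_removed_unique: int = 0
    n_surviving: int = 0
    removed_samples: List[str] = field(default_factory=list)
    greedycut_order: List[Tuple[str, str]] = field(default_factory=list)

    def reconcile(self) -> bool:
        return self.n_removed_unique + self.n_surviving == self.n_input_probes


def filter_snp_proximity(annotation: pd.DataFrame, max_dist: int = 5) -> Set[str]:
    """Probes whose nearest SNP lies within ``max_dist`` bp (inclusive).

    Probes with a missing distance are kept and counted in a warning.
    """
    if max_dist < 0:
        raise ValueError(f"max_dist must be non-negative, got {max_dist}")
    if annotation.empty:
        return set()
    dist = pd.to_numeric(annotation["snp_distance_bp"], errors="coerce")
    n_missing = int(dist.isna().sum())
    if n_missing:
        logger.warning("%d probes lack an SNP distance annotation; kept", n_missing)
    hit = annotation.loc[dist.le(max_dist).fillna(False), "probe_id"]
    return set(hit.astype(str))


def filter_context(annotation: pd.DataFrame) -> Set[str]:
    """Probes not interrogating CpG methylation (context != 'cpg')."""
    if annotation.empty:
        return set()
    bad = annotation.loc[annotation["context"].astype(str) != "cpg", "probe_id"]
    return set(bad.astype(str))


def greedycut(detp: pd.DataFrame, threshold: float = 0.01,
              ) -> Tuple[List[str], List[str], FilterReport]:
    """Iteratively drop the worst probe/sample until no detection p exceeds
    ``threshold``.

    Each round removes the row or column with the highest failure fraction.
    Ties prefer removing a probe over a sample (samples are precious at this
    cohort size); among tied probes/samples the lexicographically smallest id
    goes first.  Terminates in at most rows+columns iterations.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    fail = (detp.to_numpy() > threshold)
    rows = list(detp.index.astype(str))
    cols = list(detp.columns.astype(str))
    row_alive = np.ones(len(rows), dtype=bool)
    col_alive = np.ones(len(cols), dtype=bool)
    removed_probes: List[str] = []
    removed_samples: List[str] = []
    order: List[Tuple[str, str]] = []

    while row_alive.any() and col_alive.any():
        sub = fail[np.ix_(row_alive, col_alive)]
        if not sub.any():
            break
        row_frac = sub.mean(axis=1)
        col_frac = sub.mean(axis=0)
        live_rows = np.flatnonzero(row_alive)
        live_cols = np.flatnonzero(col_alive)
        best_row_frac = row_frac.max()
        best_col_frac = col_frac.max()
        if best_row_frac >= best_col_frac:
            cand = [rows[live_rows[i]] for i in np.flatnonzero(row_frac == best_row_frac)]
            victim = min(cand)
            row_alive[rows.index(victim)] = False
            removed_probes.append(victim)
            order.append(("probe", victim))
        else:
            cand = [cols[live_cols[i]] for i in np.flatnonzero(col_frac == best_col_frac)]
            victim = min(cand)
            col_alive[cols.index(victim)] = False
            removed_samples.append(victim)
            order.append(("sample", victim))

    if not row_alive.any() or not col_alive.any():
        logger.warning("greedy-cut removed the entire matrix")

    report = FilterReport(
        n_input_probes=len(rows),
        removed_detection=len(removed_probes),
        n_removed_unique=len(removed_probes),
        n_surviving=len(rows) - len(removed_probes),
        removed_samples=removed_samples,
        greedycut_order=order,
    )
    return removed_probes, removed_samples, report


def apply_filters(beta: pd.DataFrame,
                  annotation: Optional[pd.DataFrame] = None,
                  detp: Optional[pd.DataFrame] = None,
                  max_dist: int = 5,
                  threshold: float = 0.01,
                  ) -> Tuple[pd.DataFrame, FilterReport]:
    """Run all three filter rules against one beta matrix and reconcile."""
    snp_removed: Set[str] = set()
    ctx_removed: Set[str] = set()
    det_removed: Set[str] = set()
    removed_samples: List[str] = []
    order: List[Tuple[str, str]] = []
    if annotation is not None:
        snp_removed = filter_snp_proximity(annotation, max_dist=max_dist)
        ctx_removed = filter_context(annotation)
    if detp is not None:
        det_probes, removed_samples, gc_report = greedycut(detp, threshold=threshold)
        det_removed = set(det_probes)
        order = gc_report.greedycut_order

    probe_ids = set(beta.index.astype(str))
    all_removed = (snp_removed | ctx_removed | det_removed) & probe_ids
    surviving = beta.index[~beta.index.astype(str).isin(all_removed)]
    out = beta.loc[surviving]
    if removed_samples:
        out = out.drop(columns=[s for s in removed_samples if s in out.columns])

    report = FilterReport(
        n_input_probes=len(beta.index),
        removed_snp_proximity=len(snp_removed & probe_ids),
        removed_detection=len(det_removed & probe_ids),
        removed_context=len(ctx_removed & probe_ids),
        n_removed_unique=len(all_removed),
        n_surviving=len(surviving),
        removed_samples=removed_samples,
        greedycut_order=order,
    )
    assert report.reconcile()
    return out, report
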