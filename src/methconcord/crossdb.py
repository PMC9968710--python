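"""Cross-database comparison of per-CpG correlation tables.

Two correlation tables (probe_id, tissue_pair, rho) are inner-joined; a
probe is *stable* for a pair when the absolute difference of its two rho
values is strictly below the threshold (default 0.2).  Probes with an
undefined rho in either table are excluded from both the join and the
rho-of-rho correlation.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_DELTA_THRESHOLD = 0.2
MQTL_P_CUTOFF = 1e-14


def align_and_compare(table_a: pd.DataFrame, table_b: pd.DataFrame,
                      threshold: float = DEFAULT_DELTA_THRESHOLD,
                      ) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Join two correlation tables and classify per-probe stability.

    Returns the record table (probe_id, tissue_pair, rho_a, rho_b, delta,
    stable) and, per tissue pair, the Pearson r between the two rho columns.
    """
    def _clean(t: pd.DataFrame, tag: str) -> pd.DataFrame:
        t = t.loc[np.isfinite(pd.to_numeric(t["rho"], errors="coerce"))]
        dropped = len(table_a if tag == "a" else table_b) - len(t)
        if dropped:
            logger.info("dropped %d undefined-rho rows from table %s", dropped, tag)
        return t[["probe_id", "tissue_pair", "rho"]].rename(columns={"rho": f"rho_{tag}"})

    a = _clean(table_a, "a")
    b = _clean(table_b, "b")
    merged = a.merge(b, on=["probe_id", "tissue_pair"], how="inner")
    if merged.empty:
        raise ValueError("no probes shared between the two tables")
    merged["delta"] = (merged["rho_a"] - merged["rho_b"]).abs()
    merged["stable"] = merged["delta"] < threshold

    rho_of_rho: Dict[str, float] = {}
    for pair, grp in merged.groupby("tissue_pair", sort=True):
        if len(grp) < 2:
            raise ValueError(f"fewer than 2 shared probes for pair {pair!r}")
        x = grp["rho_a"].to_numpy(dtype=float)
        y = grp["rho_b"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rho_of_rho[pair] = np.nan
        else:
            rho_of_rho[pair] = float(np.corrcoef(x, y)[0, 1])
    return merged.reset_index(drop=True), rho_of_rho


def venn_counts(records: pd.DataFrame) -> Dict[FrozenSet[str], int]:
    """3-set Venn region counts of per-pair stable probe sets.

    Keys are frozensets of tissue-pair labels naming an *exact* region (a
    probe counted under {A, B} is stable in A and B but not the third pair);
    region counts sum to the number of probes stable in at least one pair.
    """
    pairs = sorted(records["tissue_pair"].unique())
    stable_sets = {
        p: set(records.loc[(records["tissue_pair"] == p) & records["stable"],
                           "probe_id"].astype(str))
        for p in pairs
    }
    out: Dict[FrozenSet[str], int] = {}
    for r in range(1, len(pairs) + 1):
        for combo in combinations(pairs, r):
            inside = set.intersection(*(stable_sets[p] for p in combo))
            outside = set().union(*(stable_sets[p] for p in pairs if p not in combo)) \
                if len(combo) < len(pairs) else set()
            out[frozenset(combo)] = len(inside - outside)
    return out


def triple_intersection(records: pd.DataFrame) -> int:
    """Probes stable in every tissue pair present in the records."""
    pairs = records["tissue_pair"].unique()
    sets = [set(records.loc[(records["tissue_pair"] == p) & records["stable"],
                            "probe_id"].astype(str)) for p in pairs]
    return len(set.intersection(*sets)) if sets else 0


def annotate_mqtl(records: pd.DataFrame, mqtl_list: pd.DataFrame,
                  p_cutoff: float = MQTL_P_CUTOFF) -> pd.DataFrame:
    """Add an mqtl flag: probe is in the list (after the p cutoff, when a
    p column is present)."""
    lst = mqtl_list
    if "p" in lst.columns:
        p = pd.to_numeric(lst["p"], errors="coerce")
        lst = lst.loc[p < p_cutoff]
    ids = set(lst["probe_id"].astype(str))
    out = records.copy()
    out["mqtl"] = out["probe_id"].astype(str).isin(ids)
    return out
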