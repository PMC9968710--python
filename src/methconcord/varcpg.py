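"""Variable-CpG classification by the trimmed-range rule.

A probe is *variable* when, after dropping values strictly outside the
[10th, 90th] percentile band (linear-interpolation quantiles), the retained
values still span at least 0.05 beta units.  The threshold is inclusive.
"""

from __future__ import annotations

from typing import Dict, Iterable, List

import numpy as np
import pandas as pd

DEFAULT_TRIM = 10.0
DEFAULT_RANGE_THRESHOLD = 0.05
MIN_VALUES = 3


def classify_variable(beta: pd.DataFrame, trim: float = DEFAULT_TRIM,
                      range_threshold: float = DEFAULT_RANGE_THRESHOLD,
                      ) -> pd.DataFrame:
    """Per-probe trimmed range and variability flag.

    Returns a frame with columns probe_id, trimmed_range, variable, defined;
    probes with fewer than 3 non-missing values are undefined (flag False,
    range NaN).
    """
    if not 0 <= trim < 50:
        raise ValueError(f"trim percentile must lie in [0, 50), got {trim}")
    B = beta.to_numpy(dtype=float)
    n_valid = np.isfinite(B).sum(axis=1)
    defined = n_valid >= MIN_VALUES

    lo = np.full(B.shape[0], np.nan)
    hi = np.full(B.shape[0], np.nan)
    if defined.any():
        with np.errstate(invalid="ignore"):
            qs = np.nanquantile(B[defined], [trim / 100.0, 1 - trim / 100.0],
                                axis=1, method="linear")
        lo[defined], hi[defined] = qs[0], qs[1]

    span = np.full(B.shape[0], np.nan)
    if defined.any():
        with np.errstate(invalid="ignore"):
            keep = (B >= lo[:, None]) & (B <= hi[:, None])
        masked = np.where(keep, B, np.nan)
        rows = np.flatnonzero(defined)
        span[rows] = (np.nanmax(masked[rows], axis=1)
                      - np.nanmin(masked[rows], axis=1))
    with np.errstate(invalid="ignore"):
        variable = defined & (span >= range_threshold)

    return pd.DataFrame({
        "probe_id": beta.index.astype(str),
        "trimmed_range": span,
        "variable": variable,
        "defined": defined,
    })


def intersect_variable(flags_by_tissue: Dict[str, pd.DataFrame]) -> List[str]:
    """Probe ids flagged variable in every tissue (exact set intersection)."""
    sets = [set(f.loc[f["variable"].astype(bool), "probe_id"].astype(str))
            for f in flags_by_tissue.values()]
    if not sets:
        return []
    common = set.intersection(*sets)
    return sorted(common)
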