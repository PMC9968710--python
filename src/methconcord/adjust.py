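"""Residualize beta values on cell-composition covariates, per tissue.

The adjusted value is the per-probe OLS residual plus the probe mean
(re-centered so values stay on the beta scale), clipped to [0, 1].  Blood
uses five of the six cell fractions -- dropping Neutro breaks the sum-to-one
collinearity -- brain uses the neuron fraction, saliva/buccal the epithelial
fraction.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import ADJUST_COVARIATES, AdjustedBetaMatrix

logger = logging.getLogger(__name__)

MIN_COMPLETE_SUBJECTS = 5


class CollinearCovariatesError(ValueError):
    """Covariate matrix is rank deficient; names the offending columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "covariate matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns))


def _check_rank(X: np.ndarray, names: List[str]) -> None:
    """Raise if [1 | X] is rank deficient, identifying collinear columns."""
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return
    # greedily find columns that do not increase the rank
    collinear = []
    kept = np.ones((len(X), 1))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            collinear.append(name)
        else:
            kept = cand
    raise CollinearCovariatesError(collinear or names)


def covariates_for_tissue(props: pd.DataFrame, tissue: str,
                          covariates: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Select the covariate columns the tissue rule prescribes."""
    if covariates is None:
        if tissue not in ADJUST_COVARIATES:
            raise ValueError(f"no adjustment rule for tissue {tissue!r}")
        covariates = ADJUST_COVARIATES[tissue]
    missing = [c for c in covariates if c not in props.columns]
    if missing:
        raise ValueError(
            f"cell-proportion table for {tissue!r} lacks columns: {missing}")
    return props[list(covariates)]


def residualize(beta: pd.DataFrame, props: pd.DataFrame, tissue: str,
                covariates: Optional[Sequence[str]] = None,
                min_n: int = MIN_COMPLETE_SUBJECTS,
                clip: bool = True) -> AdjustedBetaMatrix:
    """Per-probe OLS of beta on the tissue's cell covariates.

    Output = residual + probe mean, clipped to [0, 1].  Probes with missing
    values are fitted on pairwise-complete subjects; probes with fewer than
    ``min_n`` complete subjects pass through unadjusted and are flagged.
    """
    cov = covariates_for_tissue(props, tissue, covariates)
    common = [s for s in beta.columns if s in cov.index]
    if len(common) < len(beta.columns):
        raise ValueError("cell proportions missing for some subjects: "
                         f"{sorted(set(beta.columns) - set(common))}")
    X = cov.loc[list(beta.columns)].to_numpy(dtype=float)
    names = list(cov.columns)
    # a zero-variance covariate carries nothing to remove: the intercept
    # absorbs it, so drop it instead of tripping the rank check
    varying = np.ptp(X, axis=0) > 0
    if not varying.all():
        dropped = [n for n, v in zip(names, varying) if not v]
        logger.warning("constant covariates dropped: %s", ", ".join(dropped))
        X = X[:, varying]
        names = [n for n, v in zip(names, varying) if v]
    if names:
        _check_rank(X, names)
    if not names:
        out = beta.to_numpy(dtype=float).copy()
        if clip:
            out = np.clip(out, 0.0, 1.0)
        return AdjustedBetaMatrix(beta=pd.DataFrame(out, index=beta.index,
                                                    columns=beta.columns),
                                  covariates=[], tissue=tissue)

    B = beta.to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(X)), X])
    out = np.empty_like(B)
    skipped: List[str] = []

    complete = ~np.isnan(B).any(axis=1)
    if complete.any():
        Bc = B[complete]
        coef, *_ = np.linalg.lstsq(design, Bc.T, rcond=None)
        resid = Bc - (design @ coef).T
        out[complete] = resid + Bc.mean(axis=1, keepdims=True)

    for i in np.flatnonzero(~complete):
        row = B[i]
        mask = ~np.isnan(row)
        if mask.sum() < min_n:
            out[i] = row
            skipped.append(str(beta.index[i]))
            continue
        d = design[mask]
        if np.linalg.matrix_rank(d) < d.shape[1]:
            out[i] = row
            skipped.append(str(beta.index[i]))
            continue
        coef, *_ = np.linalg.lstsq(d, row[mask], rcond=None)
        fitted = d @ coef
        adj = np.full_like(row, np.nan)
        adj[mask] = row[mask] - fitted + row[mask].mean()
        out[i] = adj

    if skipped:
        logger.warning("%d probes passed through unadjusted (too few complete "
                       "subjects)", len(skipped))
    if clip:
        out = np.clip(out, 0.0, 1.0)
    adjusted = pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return AdjustedBetaMatrix(beta=adjusted, covariates=names, tissue=tissue,
                              skipped_probes=skipped)
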