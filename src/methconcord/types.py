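"""Core data containers shared across the pipeline.

Beta matrices are plain :class:`pandas.DataFrame` objects with probe ids on
the index and subject ids on the columns, values in [0, 1] (NaN = missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

TISSUES = ("brain", "blood", "saliva", "buccal")

BLOOD_CELL_TYPES = ("B", "NK", "CD4T", "CD8T", "Mono", "Neutro")
#: blood covariates for adjustment: Neutro is dropped to avoid collinearity
#: with the sum-to-one constraint.
BLOOD_ADJUST_CELL_TYPES = ("B", "NK", "CD4T", "CD8T", "Mono")
BRAIN_CELL_TYPES = ("neuron", "non_neuron")
EPITHELIAL_CELL_TYPES = ("epithelial", "immune")

CELL_TYPES_BY_TISSUE = {
    "brain": BRAIN_CELL_TYPES,
    "blood": BLOOD_CELL_TYPES,
    "saliva": EPITHELIAL_CELL_TYPES,
    "buccal": EPITHELIAL_CELL_TYPES,
}

#: covariate columns actually used when residualizing each tissue
ADJUST_COVARIATES = {
    "brain": ("neuron",),
    "blood": BLOOD_ADJUST_CELL_TYPES,
    "saliva": ("epithelial",),
    "buccal": ("epithelial",),
}


def pair_label(tissue_a: str, tissue_b: str) -> str:
    """Canonical tissue-pair label (alphabetical, hyphen-joined)."""
    if tissue_a == tissue_b:
        raise ValueError(f"tissue pair requires two distinct tissues, got {tissue_a!r} twice")
    return "-".join(sorted((tissue_a, tissue_b)))


def brain_peripheral_pairs(tissues=TISSUES) -> List[str]:
    """Canonical labels for every brain-vs-peripheral pair present."""
    return [pair_label("brain", t) for t in tissues if t != "brain"]


@dataclass
class MultiTissueDataset:
    """One beta matrix per tissue plus per-tissue cell proportion tables.

    All beta matrices share an identical, identically-ordered subject axis.
    """

    betas: Dict[str, pd.DataFrame]
    cell_proportions: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        subjects = None
        for tissue, beta in self.betas.items():
            if subjects is None:
                subjects = list(beta.columns)
            elif list(beta.columns) != subjects:
                raise ValueError(
                    f"subject columns of tissue {tissue!r} do not match the other tissues"
                )

    @property
    def tissues(self) -> List[str]:
        return list(self.betas)

    @property
    def subjects(self) -> List[str]:
        first = next(iter(self.betas.values()))
        return list(first.columns)

    @property
    def probes(self) -> pd.Index:
        return next(iter(self.betas.values())).index

    def subset_probes(self, probe_ids) -> "MultiTissueDataset":
        keep = pd.Index(probe_ids)
        return MultiTissueDataset(
            betas={t: b.loc[b.index.intersection(keep)] for t, b in self.betas.items()},
            cell_proportions=dict(self.cell_proportions),
        )


@dataclass
class AdjustedBetaMatrix:
    """Residualized beta matrix plus provenance of the adjustment."""

    beta: pd.DataFrame
    covariates: List[str]
    tissue: str
    adjusted: bool = True
    #: probes passed through unadjusted (too few complete subjects)
    skipped_probes: List[str] = field(default_factory=list)
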