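"""Three-state per-gene pathway projection.

The tabular analogue of a colored KEGG pathway map: every measured member of
a pathway is classified from its differential log2 fold change as UP
(elevated), DOWN (reduced) or INDIFFERENT, using a symmetric |log2FC|
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

UP = "UP"
DOWN = "DOWN"
INDIFFERENT = "INDIFFERENT"


@dataclass(frozen=True)
class PathwayProjection:
    pathway: str
    contrast_label: str
    threshold: float
    entries: pd.DataFrame  # columns gene, log2fc, state

    @property
    def n_up(self) -> int:
        return int((self.entries["state"] == UP).sum())

    @property
    def n_down(self) -> int:
        return int((self.entries["state"] == DOWN).sum())

    @property
    def n_indifferent(self) -> int:
        return int((self.entries["state"] == INDIFFERENT).sum())

    def to_frame(self) -> pd.DataFrame:
        return self.entries.copy()


def classify(log2fc: float, threshold: float) -> str:
    if not np.isfinite(log2fc):
        return INDIFFERENT
    if log2fc >= threshold:
        return UP
    if log2fc <= -threshold:
        return DOWN
    return INDIFFERENT


def project_pathway(
    diff: pd.DataFrame,
    pathway_name: str,
    members,
    threshold: float = 0.25,
    contrast_label: str = "",
) -> PathwayProjection:
    """Classify each measured member of ``members`` from the differential
    table's log2fc column. Genes with an undefined log2FC are INDIFFERENT."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    measured = diff.set_index("gene")["log2fc"]
    rows = []
    for gene in members:
        if gene not in measured.index:
            continue
        lfc = float(measured[gene])
        rows.append(
            dict(gene=gene, log2fc=lfc if np.isfinite(lfc) else math.nan,
                 state=classify(lfc, threshold))
        )
    if not rows:
        raise ValueError(f"pathway {pathway_name!r} has no measured member")
    return PathwayProjection(
        pathway=pathway_name,
        contrast_label=contrast_label,
        threshold=threshold,
        entries=pd.DataFrame(rows),
    )
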