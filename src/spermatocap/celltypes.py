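"""Marker-panel cell typing and group composition testing.

Each cell is scored against every cell-type marker panel with the shared
average-z gene-set score; the cell takes the argmax label unless the margin
between the top two panel scores falls below ``min_margin`` (then it is
"unassigned"). This is a deliberate cell-level replacement for
cluster-then-annotate workflows: it removes the dependence on a stochastic
embedding while keeping the marker-consistency contract testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneSet, NormalizedMatrix, TestResult, chisq_test, gene_set_zscore
from .datasets import SOMATIC_TYPES, STAGE_ORDER

UNASSIGNED = "unassigned"


@dataclass
class MarkerPanelSet:
    panels: dict[str, GeneSet]
    stage_order: tuple[str, ...] = STAGE_ORDER
    somatic_labels: tuple[str, ...] = SOMATIC_TYPES

    def __post_init__(self) -> None:
        if len(set(self.stage_order)) != len(self.stage_order):
            raise ValueError("stage_order labels not unique")
        for label, panel in self.panels.items():
            if len(panel) == 0:
                raise ValueError(f"empty marker panel for {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.panels)


def assign_types(
    norm: NormalizedMatrix,
    panels: MarkerPanelSet,
    min_margin: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every cell by its best-scoring marker panel.

    Returns ``(assignments, score_table)``: per-cell label, top score and
    top-two margin, plus the full cell x panel score table. Cells whose
    margin is below ``min_margin`` are labeled ``unassigned``.
    """
    scores = {}
    for label, panel in panels.panels.items():
        try:
            s, _ = gene_set_zscore(norm, panel)
        except ValueError as exc:
            raise ValueError(f"marker panel {label!r}: {exc}") from exc
        scores[label] = s
    table = pd.DataFrame(scores)
    vals = table.to_numpy()
    order = np.argsort(vals, axis=1)
    top = vals[np.arange(len(table)), order[:, -1]]
    second = vals[np.arange(len(table)), order[:, -2]]
    margin = top - second
    labels = np.asarray(table.columns)[order[:, -1]].astype(object)
    labels[margin < min_margin] = UNASSIGNED
    out = pd.DataFrame(
        {"label": labels, "top_score": top, "margin": margin}, index=table.index
    )
    return out, table


def composition_table(
    groups: pd.Series, labels: pd.Series, cell_types: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Group x cell-type count table (drops unassigned cells)."""
    keep = labels != UNASSIGNED
    tab = pd.crosstab(groups[keep], labels[keep])
    if cell_types is not None:
        tab = tab.reindex(columns=[t for t in cell_types if t in tab.columns], fill_value=0)
    return tab


def composition_test(table: pd.DataFrame) -> TestResult:
    """Chi-square test of group x cell-type composition."""
    return chisq_test(table.to_numpy())
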