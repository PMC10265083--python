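"""Per-cell-type differential expression and the cross-class frequency screen.

For every (disease class, cell type) the same cell type of the reference
group is the comparator. A gene is tested only if it is expressed (value >
0) in at least ``min_pct`` of cells on at least one side AND its mean
difference on the log2(TPM/10+1) scale reaches ``logfc_threshold`` in
absolute value — the legacy ``thresh.use = 2`` gate interpreted on the
analysis scale. Gate-passing genes get a two-sided Wilcoxon rank-sum test
with Bonferroni adjustment over the genes tested within that comparison.

The frequency screen then asks, per gene and direction: in how many classes
is the gene differentially expressed in EVERY germ-cell stage of that class?
Stages absent by arrest (diplotene and later in pachytene-arrested classes)
are excluded from the class's stage list.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import NormalizedMatrix, wilcoxon_test
from .datasets import STAGE_ORDER

logger = logging.getLogger(__name__)

DEG_COLUMNS = (
    "gene", "cell_type", "class_label", "direction", "effect",
    "pct1", "pct2", "p_value", "p_adjusted",
)


def germ_types_for_classes(
    classes: Sequence[str],
    arrested: Mapping[str, str] | None = None,
) -> dict[str, list[str]]:
    """Germ-stage list per class: all nine stages, truncated at the arrest
    stage for arrested classes.

    ``arrested`` maps class label -> last germ stage present (default:
    pachytene for ClassII/III/IV, full range otherwise).
    """
    if arrested is None:
        arrested = {"ClassII": "P", "ClassIII": "P", "ClassIV": "P"}
    out = {}
    for cls in classes:
        last = arrested.get(cls, STAGE_ORDER[-1])
        out[cls] = list(STAGE_ORDER[: STAGE_ORDER.index(last) + 1])
    return out


def observed_germ_types(
    cell_types: pd.Series,
    groups: pd.Series,
    classes: Sequence[str],
    reference: str = "NC",
    min_cells: int = 3,
) -> dict[str, list[str]]:
    """Germ-stage list per class restricted to evaluable stages.

    A stage enters a class's list only if both the class and the reference
    group have at least ``min_cells`` cells of it — stages missing by arrest
    (or too sparse to test) cannot carry a differential call and would make
    the all-stage quantifier vacuously unsatisfiable.
    """
    out: dict[str, list[str]] = {}
    for cls in classes:
        stages = []
        for stage in STAGE_ORDER:
            n_cls = int(((groups == cls) & (cell_types == stage)).sum())
            n_ref = int(((groups == reference) & (cell_types == stage)).sum())
            if n_cls >= min_cells and n_ref >= min_cells:
                stages.append(stage)
        if not stages:
            raise ValueError(f"class {cls!r} has no evaluable germ stage")
        out[cls] = stages
    return out


def deg_per_celltype(
    norm: NormalizedMatrix,
    cell_types: pd.Series,
    groups: pd.Series,
    reference: str = "NC",
    classes: Sequence[str] | None = None,
    logfc_threshold: float = 2.0,
    min_pct: float = 0.25,
    alpha: float = 0.05,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Wilcoxon DEGs for each (class, cell type) against the reference group.

    ``cell_types`` and ``groups`` are per-cell series indexed by cell id.
    Returns one row per significant (Bonferroni-adjusted p < alpha) gene with
    direction, effect (class mean - reference mean), expressed fractions and
    p-values.
    """
    cell_types = cell_types.reindex(norm.cell_ids)
    groups = groups.reindex(norm.cell_ids)
    if classes is None:
        classes = [g for g in pd.unique(groups.dropna()) if g != reference]
    records: list[dict] = []
    for cls in classes:
        for ct in pd.unique(cell_types.dropna()):
            m1 = ((groups == cls) & (cell_types == ct)).to_numpy()
            m2 = ((groups == reference) & (cell_types == ct)).to_numpy()
            if m1.sum() < min_cells or m2.sum() < min_cells:
                logger.info("skipping %s/%s: <%d cells on one side", cls, ct, min_cells)
                continue
            v1 = norm.values[:, m1]
            v2 = norm.values[:, m2]
            pct1 = (v1 > 0).mean(axis=1)
            pct2 = (v2 > 0).mean(axis=1)
            diff = v1.mean(axis=1) - v2.mean(axis=1)
            expressed = (pct1 > 0) | (pct2 > 0)
            gate = (
                expressed
                & (np.maximum(pct1, pct2) >= min_pct)
                & (np.abs(diff) >= logfc_threshold)
            )
            tested = np.where(gate)[0]
            n_tested = len(tested)
            for gi in tested:
                res = wilcoxon_test(v1[gi], v2[gi])
                p_adj = min(1.0, res.p_value * n_tested)
                # alpha >= 1 disables the significance gate entirely, so every
                # tested gene is reported
                if p_adj < alpha or alpha >= 1.0:
                    records.append({
                        "gene": norm.gene_symbols[gi],
                        "cell_type": ct,
                        "class_label": cls,
                        "direction": "up" if diff[gi] > 0 else "down",
                        "effect": float(diff[gi]),
                        "pct1": float(pct1[gi]),
                        "pct2": float(pct2[gi]),
                        "p_value": res.p_value,
                        "p_adjusted": p_adj,
                    })
    return pd.DataFrame(records, columns=list(DEG_COLUMNS))


def frequency_screen(
    records: pd.DataFrame,
    germ_types_by_class: Mapping[str, Sequence[str]],
    direction: str = "down",
) -> pd.DataFrame:
    """Count, per gene, the classes where it is a DEG in every listed stage.

    A gene qualifies in a class iff it has a record with the requested
    direction for EVERY germ type listed for that class. The report carries
    the per-class qualification flags and is sorted by frequency (desc),
    then symbol.
    """
    for cls, types in germ_types_by_class.items():
        if len(types) == 0:
            raise ValueError(f"class {cls!r} has an empty cell-type list")
    sub = records[records["direction"] == direction]
    genes = sorted(sub["gene"].unique())
    flags = {}
    for cls, types in germ_types_by_class.items():
        cls_rec = sub[sub["class_label"] == cls]
        covered = cls_rec.groupby("gene")["cell_type"].agg(set)
        need = set(types)
        flags[cls] = {g: need.issubset(covered.get(g, set())) for g in genes}
    report = pd.DataFrame(
        {
            "gene": genes,
            **{f"in_{cls}": [flags[cls][g] for g in genes] for cls in germ_types_by_class},
        }
    )
    report["frequency"] = report[[f"in_{c}" for c in germ_types_by_class]].sum(axis=1)
    report = report.sort_values(
        ["frequency", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    cols = ["gene", "frequency"] + [f"in_{c}" for c in germ_types_by_class]
    return report[cols]


def celltype_subset_screen(
    records: pd.DataFrame,
    cell_types: Sequence[str],
    classes: Sequence[str],
    direction: str = "down",
) -> pd.DataFrame:
    """Frequency screen over a fixed cell-type subset for every class.

    E.g. ``cell_types=["SSC"]`` reproduces the stem-cell-focused screen.
    """
    if len(cell_types) == 0:
        raise ValueError("cell-type subset is empty")
    mapping = {cls: list(cell_types) for cls in classes}
    return frequency_screen(records, mapping, direction=direction)
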