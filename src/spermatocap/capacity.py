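"""Spermatogenesis-capacity scoring, group ranking and trend-gene discovery.

The capacity score of a spermatogenic cell is the average z-score of a
curated spermatogenesis gene set over the pooled germ cells (the average-Z
"spermatogenesis score"). Groups are ranked by the median per-cell score;
the rank (best = 1) serves as the group's severity rank.

Trend genes are discovered at the donor level to avoid pseudoreplication:
for each gene the Spearman correlation between the per-donor germ-cell mean
expression and the donor's group severity rank is computed, with
Benjamini-Hochberg control over genes. Significant trend genes are grouped
into m modules by seeded k-means on their standardized per-group mean
profiles; modules are renumbered so Module 1 has the most positive mean rho
(expression rising as capacity falls) and Module m the most negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .core import GeneSet, NormalizedMatrix, TestResult, gene_set_zscore, wilcoxon_test


@dataclass
class CapacityResult:
    scores: pd.Series  # per germ cell
    group_of_cell: pd.Series  # group label per scored cell
    summaries: pd.DataFrame  # per-group median / IQR / n
    n_genes_used: int
    ranking: tuple[str, ...] = ()  # best -> worst, set by rank_groups
    severity_rank: dict[str, int] = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None
    ties: tuple[tuple[str, str], ...] = ()


def spermatogenesis_score(
    norm: NormalizedMatrix,
    gene_set: GeneSet,
    germ_cells: list[str] | np.ndarray,
) -> CapacityResult:
    """Average-Z capacity score per germ cell, pooled across groups."""
    scores, n_used = gene_set_zscore(norm, gene_set, germ_cells)
    groups = norm.cell_meta.loc[scores.index, "group"]
    summaries = scores.groupby(groups).agg(
        median="median",
        iqr=lambda s: float(np.subtract(*np.percentile(s, [75, 25]))),
        n="size",
    )
    return CapacityResult(
        scores=scores, group_of_cell=groups, summaries=summaries, n_genes_used=n_used
    )


def rank_groups(result: CapacityResult) -> CapacityResult:
    """Rank groups by descending median score; report pairwise Wilcoxon tests.

    Ties in medians still yield a total order (alphabetical within the tie)
    and are noted in ``ties``.
    """
    med = result.summaries["median"]
    if len(med) < 2:
        raise ValueError("need at least two groups to rank")
    if (result.summaries["n"] < 2).any():
        raise ValueError("each group needs at least 2 scored cells")
    order = med.sort_values(ascending=False, kind="mergesort")
    # alphabetical tie-break for determinism
    ranking = tuple(
        order.reset_index()
        .sort_values(["median", order.index.name or "index"],
                     ascending=[False, True], kind="mergesort")
        .iloc[:, 0]
    )
    ties = tuple(
        (a, b)
        for i, a in enumerate(ranking)
        for b in ranking[i + 1:]
        if med[a] == med[b]
    )
    rows = []
    for i, a in enumerate(ranking):
        for b in ranking[i + 1:]:
            res: TestResult = wilcoxon_test(
                result.scores[result.group_of_cell == a],
                result.scores[result.group_of_cell == b],
            )
            rows.append({"group1": a, "group2": b,
                         "statistic": res.statistic, "p_value": res.p_value,
                         "effect": res.effect})
    result.ranking = ranking
    result.severity_rank = {g: i + 1 for i, g in enumerate(ranking)}
    result.pairwise = pd.DataFrame(rows)
    result.ties = ties
    return result


def donor_germ_means(
    norm: NormalizedMatrix, germ_cells: list[str] | np.ndarray
) -> pd.DataFrame:
    """Gene x donor table of mean normalized expression over germ cells."""
    idx = norm.cell_positions(list(germ_cells))
    donors = norm.cell_meta.iloc[idx]["donor"].to_numpy()
    cols = {}
    for donor in pd.unique(donors):
        cols[donor] = norm.values[:, idx[donors == donor]].mean(axis=1)
    return pd.DataFrame(cols, index=pd.Index(norm.gene_symbols, name="gene"))


def trend_correlations(
    norm: NormalizedMatrix,
    result: CapacityResult,
    germ_cells: list[str] | np.ndarray,
) -> pd.DataFrame:
    """Spearman trend of per-donor germ-cell means against severity rank.

    Requires a ranked :class:`CapacityResult` (severity ranks set). Genes
    constant across donors are excluded. Returns gene / rho / p_value /
    p_adjusted (BH).
    """
    if not result.severity_rank:
        raise ValueError("rank_groups must be applied before trend_correlations")
    means = donor_germ_means(norm, germ_cells)
    donor_group = (
        norm.cell_meta.loc[list(germ_cells)]
        .groupby("donor")["group"].first()
        .reindex(means.columns)
    )
    ranks = donor_group.map(result.severity_rank).to_numpy(dtype=float)
    if len(np.unique(ranks)) < 3 or len(ranks) < 4:
        raise ValueError("need >=4 donors spanning >=3 severity ranks")
    rows = []
    X = means.to_numpy()
    for gi, gene in enumerate(means.index):
        y = X[gi]
        if np.ptp(y) == 0:
            continue
        rho, p = stats.spearmanr(y, ranks)
        if np.isnan(rho):
            continue
        rows.append({"gene": gene, "rho": float(rho), "p_value": float(p)})
    trends = pd.DataFrame(rows)
    trends["p_adjusted"] = multipletests(trends["p_value"], method="fdr_bh")[1]
    return trends


def group_mean_profiles(
    norm: NormalizedMatrix,
    germ_cells: list[str] | np.ndarray,
    group_order: tuple[str, ...],
) -> pd.DataFrame:
    """Gene x group table of mean germ-cell expression, columns in the given
    (severity) order."""
    idx = norm.cell_positions(list(germ_cells))
    groups = norm.cell_meta.iloc[idx]["group"].to_numpy()
    cols = {g: norm.values[:, idx[groups == g]].mean(axis=1) for g in group_order}
    return pd.DataFrame(cols, index=pd.Index(norm.gene_symbols, name="gene"))


def trend_modules(
    trends: pd.DataFrame,
    group_profiles: pd.DataFrame,
    m: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster trend genes into m modules by their standardized group profile.

    Profiles (rows of ``group_profiles`` restricted to the trend genes) are
    standardized to zero mean / unit variance over the severity-ordered
    groups, then clustered with seeded k-means (25 restarts). Modules are
    renumbered by decreasing mean rho: Module 1 rises as capacity falls,
    Module m falls.
    """
    genes = [g for g in trends["gene"] if g in group_profiles.index]
    prof = group_profiles.loc[genes].to_numpy(dtype=float)
    sd = prof.std(axis=1)
    keep = sd > 0
    profz = (prof[keep] - prof[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    if len(np.unique(profz, axis=0)) < m:
        raise ValueError(f"fewer than m={m} distinct standardized profiles")
    km = KMeans(n_clusters=m, n_init=25, random_state=seed)
    raw = km.fit_predict(profz)
    kept_genes = np.asarray(genes, dtype=object)[keep]
    out = trends.copy()
    out["module"] = pd.NA
    rho_of = trends.set_index("gene")["rho"]
    mean_rho = {c: rho_of.reindex(kept_genes[raw == c]).mean() for c in range(m)}
    renumber = {c: i + 1 for i, c in enumerate(
        sorted(mean_rho, key=lambda c: -mean_rho[c]))}
    module_of = {g: renumber[c] for g, c in zip(kept_genes, raw)}
    out["module"] = out["gene"].map(module_of).astype("Int64")
    return out


def external_overlap(
    modules: pd.DataFrame,
    external_lists: pd.DataFrame,
    module_direction: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Intersect trend modules with external disease DEG lists.

    ``external_lists`` has columns (list_name, gene, direction). Each module
    is compared with the matching direction of each list (Module 1 with
    "up", the last module with "down" by default); pass ``module_direction``
    to override. No inference, set arithmetic only.
    """
    mods = modules.dropna(subset=["module"])
    module_ids = sorted(int(x) for x in mods["module"].unique())
    if module_direction is None:
        module_direction = {}
        if module_ids:
            module_direction[module_ids[0]] = "up"
            module_direction[module_ids[-1]] = "down"
    rows = []
    for mid, direction in module_direction.items():
        mod_genes = set(mods.loc[mods["module"] == mid, "gene"].str.upper())
        for list_name, sub in external_lists.groupby("list_name"):
            ext = set(sub.loc[sub["direction"] == direction, "gene"].str.upper())
            inter = sorted(mod_genes & ext)
            rows.append({
                "module": mid, "list_name": list_name, "direction": direction,
                "n_overlap": len(inter), "genes": ",".join(inter),
            })
    return pd.DataFrame(rows)
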