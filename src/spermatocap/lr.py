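"""Permutation-based ligand-receptor interaction inference between cell types.

For a candidate pair and an ordered (sender type, receiver type) the
statistic is the arithmetic mean of the ligand's mean normalized expression
in the sender cells and the receptor's mean in the receiver cells. A pair is
considered at all only if the ligand is expressed (value > 0) in strictly
more than ``min_pct`` of sender cells and the receptor in strictly more than
``min_pct`` of receiver cells; an absent gene means no interaction.

The null shuffles the cell-type labels of ALL cells jointly (one permutation
reused for every pair within an iteration, preserving marginal type sizes)
and the p-value is the fraction of permuted statistics >= the observed one,
so p = 0 is possible; a +1/(n+1) smoothed variant is available for
downstream FDR use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LR_RESULT_COLUMNS = (
    "pair_id", "ligand", "receptor", "sender_type", "receiver_type",
    "pct_ligand", "pct_receptor", "statistic", "p_value", "significant",
    "low_confidence",
)


@dataclass
class InteractionNetwork:
    """Directed significant-interaction counts between cell types."""

    counts: pd.DataFrame  # sender x receiver
    edge_pairs: dict[tuple[str, str], tuple[str, ...]]

    def node_strength(self) -> pd.Series:
        """Total incident significant-interaction count per type."""
        return self.counts.sum(axis=1) + self.counts.sum(axis=0)


def lr_statistic(
    norm,
    ligand: str,
    receptor: str,
    sender_cells: np.ndarray,
    receiver_cells: np.ndarray,
    min_pct: float = 0.10,
) -> tuple[float, float, float] | None:
    """(statistic, pct_ligand, pct_receptor), or None when gated out."""
    lig_idx = norm.gene_positions([ligand])
    rec_idx = norm.gene_positions([receptor])
    if len(lig_idx) == 0 or len(rec_idx) == 0:
        return None
    s_idx = norm.cell_positions(list(sender_cells))
    r_idx = norm.cell_positions(list(receiver_cells))
    if len(s_idx) == 0 or len(r_idx) == 0:
        raise ValueError("empty sender or receiver cell subset")
    lig = norm.values[lig_idx[0], s_idx]
    rec = norm.values[rec_idx[0], r_idx]
    pct_l = float((lig > 0).mean())
    pct_r = float((rec > 0).mean())
    if not (pct_l > min_pct and pct_r > min_pct):
        return None
    return float((lig.mean() + rec.mean()) / 2.0), pct_l, pct_r


def _type_means(values: np.ndarray, codes: np.ndarray, n_types: int) -> np.ndarray:
    """Gene x type mean matrix given integer type codes per cell."""
    sums = np.zeros((values.shape[0], n_types))
    counts = np.bincount(codes, minlength=n_types).astype(float)
    for t in range(n_types):
        mask = codes == t
        if mask.any():
            sums[:, t] = values[:, mask].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return sums / counts[None, :]


def permutation_test(
    norm,
    pairs: pd.DataFrame,
    type_labels: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_pct: float = 0.10,
    seed: int = 0,
    smoothed: bool = False,
    sender_receiver: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Permutation p-values for every (pair, sender type, receiver type).

    ``pairs`` has columns (pair_id, ligand, receptor); ``type_labels`` maps
    cell id -> type. By default all ordered type pairs are tested; pass
    ``sender_receiver`` to restrict. Deterministic given ``seed``. Types
    with fewer than 3 cells have their rows flagged ``low_confidence``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    type_labels = type_labels.reindex(norm.cell_ids).dropna()
    cell_idx = norm.cell_positions(list(type_labels.index))
    types = sorted(type_labels.unique())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    t_code = {t: i for i, t in enumerate(types)}
    codes = type_labels.map(t_code).to_numpy(dtype=np.int64)
    type_sizes = np.bincount(codes, minlength=len(types))

    genes = sorted(set(pairs["ligand"]) | set(pairs["receptor"]))
    gene_idx = {g: i for i, g in enumerate(genes)}
    pos = {g: p for g, p in zip(genes, [norm.gene_positions([g]) for g in genes])}
    present = {g: len(p) > 0 for g, p in pos.items()}
    rowpos = [pos[g][0] if present[g] else 0 for g in genes]
    values = norm.values[np.ix_(rowpos, cell_idx)]

    obs_means = _type_means(values, codes, len(types))
    pct = _type_means((values > 0).astype(float), codes, len(types))

    if sender_receiver is None:
        sender_receiver = [(s, r) for s in types for r in types]

    combos = []
    for _, row in pairs.iterrows():
        li = gene_idx[row["ligand"]]
        ri = gene_idx[row["receptor"]]
        for s, r in sender_receiver:
            combos.append((row["pair_id"], row["ligand"], row["receptor"], s, r, li, ri))

    li_arr = np.asarray([c[5] for c in combos])
    ri_arr = np.asarray([c[6] for c in combos])
    s_arr = np.asarray([t_code[c[3]] for c in combos])
    r_arr = np.asarray([t_code[c[4]] for c in combos])

    obs_stat = (obs_means[li_arr, s_arr] + obs_means[ri_arr, r_arr]) / 2.0
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(combos), dtype=np.int64)
    for _ in range(n_perm):
        perm_codes = rng.permutation(codes)
        pm = _type_means(values, perm_codes, len(types))
        null = (pm[li_arr, s_arr] + pm[ri_arr, r_arr]) / 2.0
        exceed += null >= obs_stat
    if smoothed:
        pvals = (exceed + 1.0) / (n_perm + 1.0)
    else:
        pvals = exceed / float(n_perm)

    rows = []
    for k, (pair_id, lig, rec, s, r, li, ri) in enumerate(combos):
        both = present[lig] and present[rec]
        pct_l = float(pct[li, t_code[s]]) if present[lig] else 0.0
        pct_r = float(pct[ri, t_code[r]]) if present[rec] else 0.0
        gates = both and pct_l > min_pct and pct_r > min_pct
        rows.append({
            "pair_id": pair_id, "ligand": lig, "receptor": rec,
            "sender_type": s, "receiver_type": r,
            "pct_ligand": pct_l, "pct_receptor": pct_r,
            "statistic": float(obs_stat[k]) if both else np.nan,
            "p_value": float(pvals[k]) if both else np.nan,
            "significant": bool(gates and pvals[k] < alpha),
            "low_confidence": bool(
                type_sizes[t_code[s]] < 3 or type_sizes[t_code[r]] < 3),
        })
    return pd.DataFrame(rows, columns=list(LR_RESULT_COLUMNS))


def build_network(results: pd.DataFrame, types: list[str] | None = None) -> InteractionNetwork:
    """Count significant interactions per directed (sender, receiver) edge."""
    if types is None:
        types = sorted(
            set(results["sender_type"]) | set(results["receiver_type"]))
    counts = pd.DataFrame(0, index=pd.Index(types, name="sender"),
                          columns=pd.Index(types, name="receiver"))
    edge_pairs: dict[tuple[str, str], tuple[str, ...]] = {}
    sig = results[results["significant"]]
    for (s, r), sub in sig.groupby(["sender_type", "receiver_type"]):
        counts.loc[s, r] = len(sub)
        edge_pairs[(s, r)] = tuple(sorted(sub["pair_id"]))
    return InteractionNetwork(counts=counts, edge_pairs=edge_pairs)


def delta_network(
    disease: InteractionNetwork, reference: InteractionNetwork
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed per-edge count difference (disease - reference) plus the
    gained/lost pair lists per edge. Missing types are treated as zero."""
    types = sorted(set(disease.counts.index) | set(reference.counts.index))
    d = disease.counts.reindex(index=types, columns=types, fill_value=0)
    r = reference.counts.reindex(index=types, columns=types, fill_value=0)
    delta = d - r
    rows = []
    for s in types:
        for t in types:
            dp = set(disease.edge_pairs.get((s, t), ()))
            rp = set(reference.edge_pairs.get((s, t), ()))
            if dp or rp:
                rows.append({
                    "sender": s, "receiver": t,
                    "delta": int(delta.loc[s, t]),
                    "gained": ",".join(sorted(dp - rp)),
                    "lost": ",".join(sorted(rp - dp)),
                })
    return delta, pd.DataFrame(rows, columns=["sender", "receiver", "delta", "gained", "lost"])
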