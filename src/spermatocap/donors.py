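"""Donor-level pseudobulk aggregation and arrest-class discovery.

Donors are stratified by average-linkage hierarchical clustering of their
pseudobulk expression profiles, using 1 - Pearson correlation over the most
variable genes as the distance. The cluster containing the majority of the
reference (control) donors is labeled ``ClassI``; the remaining clusters get
provisional labels in dendrogram leaf order and are meant to be relabeled by
downstream capacity ranking, since the expression dendrogram alone carries no
severity ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .core import NormalizedMatrix


@dataclass
class DonorProfile:
    donor_id: str
    pseudobulk: np.ndarray  # per-gene mean of normalized values
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"donor {self.donor_id}: n_cells must be >= 1")


@dataclass
class ClassAssignment:
    labels: dict[str, str]  # donor -> class label
    linkage: np.ndarray  # scipy linkage record (heights, members)
    k: int
    donor_order: tuple[str, ...]  # order in which donors index the linkage


def pseudobulk(norm: NormalizedMatrix) -> list[DonorProfile]:
    """One profile per donor: per-gene mean of normalized values."""
    if "donor" not in norm.cell_meta.columns or norm.cell_meta["donor"].isna().any():
        missing = (
            list(norm.cell_ids[: 5])
            if "donor" not in norm.cell_meta.columns
            else list(norm.cell_meta.index[norm.cell_meta["donor"].isna()][:5])
        )
        raise ValueError(f"cells without donor label, e.g. {missing}")
    donors = norm.cell_meta["donor"].to_numpy()
    profiles = []
    for donor in pd.unique(donors):
        mask = donors == donor
        profiles.append(
            DonorProfile(
                donor_id=str(donor),
                pseudobulk=norm.values[:, mask].mean(axis=1),
                n_cells=int(mask.sum()),
            )
        )
    return profiles


def cluster_donors(
    profiles: list[DonorProfile],
    k: int = 5,
    reference_donors: set[str] | None = None,
    n_variable_genes: int = 2000,
) -> ClassAssignment:
    """Cut an average-linkage correlation dendrogram of donors into k classes.

    Distance is 1 - Pearson correlation over the top ``n_variable_genes`` by
    pseudobulk variance. Donors are sorted by id before clustering so the
    result does not depend on input order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(profiles) < k:
        raise ValueError(f"k={k} exceeds the {len(profiles)} donors")
    profiles = sorted(profiles, key=lambda p: p.donor_id)
    donor_ids = tuple(p.donor_id for p in profiles)
    X = np.vstack([p.pseudobulk for p in profiles])  # donors x genes
    var = X.var(axis=0)
    top = np.sort(np.argsort(var)[::-1][: min(n_variable_genes, X.shape[1])])
    Xv = X[:, top]
    corr = np.corrcoef(Xv)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    Z = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    flat = sch.fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(flat)) != k:
        raise ValueError(f"could not cut the dendrogram into exactly {k} groups")

    reference_donors = set(reference_donors or ())
    ref_counts = pd.Series(
        [flat[i] for i, d in enumerate(donor_ids) if d in reference_donors]
    )
    ref_cluster = int(ref_counts.value_counts().index[0]) if len(ref_counts) else None

    # provisional labels: ClassI for the reference cluster, then dendrogram
    # leaf order for the rest
    leaf_order = sch.leaves_list(Z)
    label_of: dict[int, str] = {}
    if ref_cluster is not None:
        label_of[ref_cluster] = "ClassI"
    nxt = 2
    for leaf in leaf_order:
        c = int(flat[leaf])
        if c not in label_of:
            label_of[c] = f"Cluster{nxt}"
            nxt += 1
    labels = {d: label_of[int(flat[i])] for i, d in enumerate(donor_ids)}
    return ClassAssignment(labels=labels, linkage=Z, k=k, donor_order=donor_ids)
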