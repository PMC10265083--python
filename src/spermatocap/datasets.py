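"""Loaders for bundled gene sets, marker panels and the ligand-receptor table.

All bundled files are plain two/three-column TSV and are meant to be
user-replaceable: point the same loaders at your own files to swap in, e.g.,
the exact cycle gene lists or GO export used in a particular study.

Bundled defaults:

* ``cycle_g1s.tsv`` / ``cycle_g2m.tsv`` — the canonical single-cell phase
  programs (43 G1/S and 54 G2/M genes, the Tirosh-derived lists shipped with
  standard single-cell toolkits).
* ``spermatogenesis_default.tsv`` — a curated default of 50 well-established
  spermatogenesis genes. This is a synthetic stand-in assembled for this
  package, not any study's GO export; replace it with your own list for real
  analyses.
* ``marker_panels.tsv`` — per-cell-type marker panels over the 12 testis
  cell types, built from widely used literature markers.
* ``lr_pairs.tsv`` — a small simple (one ligand, one receptor) pair table.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .core import GeneSet

STAGE_ORDER = ("SSC", "Diff.ing SPG", "Diff.ed SPG", "L", "Z", "P", "D", "SPC7", "RS")
SOMATIC_TYPES = ("ST", "MIX", "tMphi")
ALL_TYPES = STAGE_ORDER + SOMATIC_TYPES


def _data_path(name: str) -> Path:
    return Path(resources.files("spermatocap.data") / name)


def load_gene_set_tsv(path: str | Path, role: str = "custom") -> GeneSet:
    """Read a two-column (set_name, gene_symbol) TSV into a GeneSet.

    The file must contain exactly one set name.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["set_name", "gene"])
    names = df["set_name"].unique()
    if len(names) != 1:
        raise ValueError(f"{path}: expected one set name, found {list(names)}")
    return GeneSet(name=str(names[0]), role=role, genes=tuple(df["gene"]))


def load_cycle_sets(
    g1s_path: str | Path | None = None, g2m_path: str | Path | None = None
) -> tuple[GeneSet, GeneSet]:
    """Load the G1/S and G2/M phase gene sets (bundled defaults: 43 + 54)."""
    g1s = load_gene_set_tsv(g1s_path or _data_path("cycle_g1s.tsv"), role="g1s")
    g2m = load_gene_set_tsv(g2m_path or _data_path("cycle_g2m.tsv"), role="g2m")
    return g1s, g2m


def load_spermatogenesis_set(path: str | Path | None = None) -> GeneSet:
    """Load the spermatogenesis gene set used for capacity scoring.

    The bundled default is a curated synthetic stand-in (see module
    docstring); supply ``path`` to use your own list.
    """
    return load_gene_set_tsv(
        path or _data_path("spermatogenesis_default.tsv"), role="spermatogenesis"
    )


def load_marker_panels(path: str | Path | None = None) -> dict[str, GeneSet]:
    """Read (cell_type, gene) TSV into one marker-panel GeneSet per type."""
    df = pd.read_csv(
        path or _data_path("marker_panels.tsv"),
        sep="\t", header=None, names=["cell_type", "gene"],
    )
    panels = {}
    for cell_type, sub in df.groupby("cell_type", sort=False):
        panels[str(cell_type)] = GeneSet(
            name=str(cell_type), role="marker_panel", genes=tuple(sub["gene"])
        )
    return panels


def load_lr_pairs(path: str | Path | None = None) -> pd.DataFrame:
    """Read the (pair_id, ligand, receptor) table."""
    df = pd.read_csv(
        path or _data_path("lr_pairs.tsv"),
        sep="\t", header=None, names=["pair_id", "ligand", "receptor"],
    )
    if df["pair_id"].duplicated().any():
        raise ValueError("duplicate pair_id in ligand-receptor table")
    if (df[["ligand", "receptor"]] == "").any().any():
        raise ValueError("empty ligand or receptor symbol")
    for col in ("ligand", "receptor"):
        df[col] = df[col].str.upper()
    return df
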