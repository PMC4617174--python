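"""Packaged example data.

Small plain-text fixtures shipped with the package: the 13-gene cloned-gene
feature table, a per-ancestral-gene copy table of the family in the
triplicated *B. rapa* genome, a 9-species tree annotated with polyploidy
events, and a member x species presence matrix.

The copy table and presence matrix are *synthetic reconstructions*: their
totals reproduce the published family-level numbers (10 ancestral genes, 15
retained copies, a 60/30/10 one/two/three-copy split, LF-dominant subgenome
counts, and the narrated gain order of members relative to the gamma,
alpha/beta and Brassica-triplication events), but the per-gene assignments
behind those totals are not published and were filled in consistently.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .catalog import GeneRecord, read_gene_table
from .footprint import SpeciesTree
from .io import read_presence_matrix, read_synteny_table

__all__ = [
    "load_gene_table",
    "load_copy_table",
    "load_species_tree",
    "load_presence_matrix",
    "FAMILY_GROUPS",
]

_DATA = files("famevol.data")

#: Conventional phylogenetic groups of the kinase family.
FAMILY_GROUPS: dict[str, tuple[str, ...]] = {
    "I": ("SnRK2.1", "SnRK2.4", "SnRK2.5", "SnRK2.9", "SnRK2.10"),
    "II": ("SnRK2.7", "SnRK2.8"),
    "III": ("SnRK2.2", "SnRK2.3", "SnRK2.6"),
}


def load_gene_table() -> list[GeneRecord]:
    """The 13 cloned family members with their tabulated features."""
    return read_gene_table(str(_DATA / "table1.tsv"))


def load_copy_table() -> pd.DataFrame:
    """Synteny table of retained homoeologs per ancestral family gene."""
    return read_synteny_table(str(_DATA / "bra_snrk2_copies_synthetic.tsv"))


def load_species_tree() -> SpeciesTree:
    """9-species tree with gamma/alpha/beta/salicoid/WGT branch events."""
    return SpeciesTree.from_newick(str(_DATA / "species_tree.nwk"))


def load_presence_matrix() -> pd.DataFrame:
    """Member x species copy counts across the 9 species."""
    return read_presence_matrix(str(_DATA / "snrk2_presence_synthetic.tsv"))
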