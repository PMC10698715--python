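"""Earliest-appearance branch of an exon on a species tree.

Given a rooted species tree and an exon-by-species presence/absence matrix,
each exon is assigned the most recent common ancestor of all species that
carry it (single-gain, Dollo-style assumption: one origin, losses within
the carrier clade permitted and ignored).  ``unknown`` entries are ignored.
"""

from __future__ import annotations

import dendropy
import pandas as pd

from .errors import NoOriginError, ParameterError, ParseError

__all__ = [
    "load_species_tree",
    "load_presence_matrix",
    "origin_branch",
    "origin_table",
    "toy_chordate_tree",
    "toy_chordate_matrix",
]

#: values interpreted as present / absent / unknown in a presence matrix
_PRESENT = {"1", 1, True, "present"}
_ABSENT = {"0", 0, False, "absent"}


def load_species_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted newick tree (a path or a newick string)."""
    data = newick
    if "(" not in newick:  # assume path
        with open(newick) as fh:
            data = fh.read()
    try:
        tree = dendropy.Tree.get(data=data, schema="newick",
                                 suppress_internal_node_taxa=False)
    except Exception as exc:
        raise ParseError(f"could not parse newick tree: {exc}") from exc
    tree.is_rooted = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        raise ParseError("species tree has duplicate tip labels")
    return tree


def load_presence_matrix(path_or_buf) -> pd.DataFrame:
    """Exon x species matrix from TSV (values 0/1/NA), exon ids as index."""
    df = pd.read_csv(path_or_buf, sep="\t", index_col=0, dtype=str)
    return df


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label if node.taxon else ""
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


def origin_branch(matrix: pd.DataFrame, tree: dendropy.Tree, exon_id: str) -> str:
    """Clade label of the MRCA of every species scored present for the exon.

    Species scored unknown (NA) are ignored; an exon present in a single
    species maps to that tip; an exon present everywhere maps to the root.
    """
    if exon_id not in matrix.index:
        raise ParameterError(f"unknown exon {exon_id!r}")
    tips = {lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon}
    row = matrix.loc[exon_id]
    carriers = []
    for species, value in row.items():
        if pd.isna(value) or str(value).strip().upper() in {"NA", "UNKNOWN", ""}:
            continue
        if species not in tips:
            raise ParameterError(f"species {species!r} not in the tree")
        if value in _PRESENT or str(value).strip() == "1":
            carriers.append(species)
    if not carriers:
        raise NoOriginError(f"exon {exon_id!r} is present in no species")
    if len(carriers) == 1:
        node = tree.find_node_with_taxon_label(carriers[0])
    else:
        node = tree.mrca(taxon_labels=carriers)
    return _node_label(node)


def origin_table(matrix: pd.DataFrame, tree: dendropy.Tree) -> pd.DataFrame:
    """Origin branch for every exon in the matrix."""
    rows = [{"exon_id": e, "origin": origin_branch(matrix, tree, e)}
            for e in matrix.index]
    return pd.DataFrame(rows, columns=["exon_id", "origin"])


# ---------------------------------------------------------------------------
# toy chordate fixture: nested clades chordates > amniotes > placental
# mammals > Hominidae, enough to reproduce the published origin assignments
# qualitatively
# ---------------------------------------------------------------------------

TOY_CHORDATE_NEWICK = (
    "(amphioxus,(zebrafish,(xenopus,((chicken,anole)Sauropsida,"
    "(opossum,(dog,((mouse,rat)Rodentia,(macaque,(gibbon,(orangutan,"
    "(gorilla,(human,chimpanzee)Hominini)Homininae)Hominidae)Hominoidea)"
    "Catarrhini)Euarchontoglires)Placentalia)Theria)Amniota)"
    "Tetrapoda)Vertebrata)Chordata;"
)

_AMNIOTES = ["chicken", "anole", "opossum", "dog", "mouse", "rat", "macaque",
             "gibbon", "orangutan", "gorilla", "human", "chimpanzee"]
_PLACENTALS = _AMNIOTES[3:]
_GREAT_APES = ["orangutan", "gorilla", "human", "chimpanzee"]


def toy_chordate_tree() -> dendropy.Tree:
    return load_species_tree(TOY_CHORDATE_NEWICK)


def toy_chordate_matrix() -> pd.DataFrame:
    """Presence/absence of the independently spliced exons across chordates.

    Encodes the qualitative pattern behind the published origin mapping:
    the PDZ-terminal exon in all chordates, the signal-peptide exon from
    amniotes on, the two juxtamembrane exons in placental mammals, and the
    great-ape-specific intracellular exon only in Hominidae.
    """
    species = ["amphioxus", "zebrafish", "xenopus"] + _AMNIOTES
    rows = {
        "exon_22_pdz": {s: "1" for s in species},
        "exon_6_signal": {s: ("1" if s in _AMNIOTES else "0") for s in species},
        "exon_18": {s: ("1" if s in _PLACENTALS else "0") for s in species},
        "exon_19b": {s: ("1" if s in _PLACENTALS else "0") for s in species},
        "exon_19a_human": {s: ("1" if s in _GREAT_APES else "0") for s in species},
    }
    df = pd.DataFrame(rows).T
    df.index.name = "exon_id"
    return df
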