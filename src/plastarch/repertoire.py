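"""Gene repertoire comparison and Dollo parsimony on a fixed species tree.

Under the Dollo model a character (a gene, or the inverted repeat) arises
once and can only be lost.  Given a rooted species tree and a
presence/absence vector over its leaves, the most parsimonious
reconstruction places the gain at a single node (the root for ancestral
characters, otherwise the last common ancestor of the present leaves) and a
loss on the edge above every maximal all-absent subtree under the gain.
That edge set is the unique minimum; its size is the loss count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .catalog import Catalog, default_catalog
from .genome_io import ChloroGenome

__all__ = [
    "build_presence_matrix",
    "presence_states",
    "core_genes",
    "DolloReconstruction",
    "dollo_map",
    "ir_loss_events",
    "dollo_table",
]

PRESENT, PSEUDOGENE, ABSENT = "present", "pseudogene", "absent"


def build_presence_matrix(
    genomes: list[ChloroGenome] | dict[str, ChloroGenome],
    catalog: Catalog | None = None,
) -> pd.DataFrame:
    """Conserved genes x taxa matrix with cells present/pseudogene/absent.

    Gene names are base names: IR duplicates, duplicated tRNAs and gene
    parts (ycf3a/ycf3b) collapse onto one row.  A locus annotated both
    intact and as pseudogene counts as present.
    """
    if isinstance(genomes, dict):
        genomes = list(genomes.values())
    if catalog is None:
        catalog = default_catalog()
    states: dict[str, dict[str, str]] = {}
    for g in genomes:
        col: dict[str, str] = {}
        for f in g.features:
            if not f.conserved:
                continue
            state = PSEUDOGENE if f.pseudo else PRESENT
            prev = col.get(f.base_name)
            if prev == PRESENT:
                continue
            col[f.base_name] = state if prev is None or state == PRESENT else prev
        states[g.id] = col
    all_genes = sorted({gene for col in states.values() for gene in col})
    data = {
        gid: [col.get(gene, ABSENT) for gene in all_genes]
        for gid, col in states.items()
    }
    return pd.DataFrame(data, index=pd.Index(all_genes, name="gene"))


def presence_states(
    matrix: pd.DataFrame, pseudogene_as_present: bool = False
) -> pd.DataFrame:
    """Booleanize a presence matrix (pseudogenes default to absent)."""
    if pseudogene_as_present:
        return matrix.isin([PRESENT, PSEUDOGENE])
    return matrix == PRESENT


def core_genes(
    matrix: pd.DataFrame,
    taxa_subset: list[str] | None = None,
    pseudogene_as_present: bool = False,
) -> list[str]:
    """Genes present in every listed taxon, sorted."""
    taxa = list(matrix.columns) if taxa_subset is None else list(taxa_subset)
    unknown = [t for t in taxa if t not in matrix.columns]
    if unknown:
        raise KeyError(f"unknown taxa: {unknown}")
    boolm = presence_states(matrix, pseudogene_as_present)
    return sorted(boolm.index[boolm[taxa].all(axis=1)])


# ---------------------------------------------------------------------------
# Dollo reconstruction


@dataclass
class DolloReconstruction:
    """Single-gain / minimal-loss mapping of one binary character."""

    character: str
    gain_clade: frozenset[str]  # leaf labels under the gain node
    loss_clades: list[frozenset[str]] = field(default_factory=list)
    states: dict[int, bool] = field(default_factory=dict)  # id(node) -> state

    @property
    def loss_count(self) -> int:
        return len(self.loss_clades)


def _leafset(node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def dollo_map(
    tree: dendropy.Tree,
    presence: dict[str, bool],
    gain_policy: str = "lca_of_present",
    character: str = "",
) -> DolloReconstruction:
    """Most parsimonious single-gain loss mapping on a rooted tree.

    ``presence`` is keyed by leaf label.  ``gain_policy`` is ``root`` for
    characters ancestral to the whole tree (e.g. genes present in the
    outgroups) or ``lca_of_present``.  Losses are the edges above maximal
    all-absent subtrees under the gain; on a polytomy each lost child
    subtree counts as its own event.
    """
    if gain_policy not in ("root", "lca_of_present"):
        raise ValueError(f"unknown gain_policy {gain_policy!r}")
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in presence]
    if missing:
        raise KeyError(f"{character or 'character'}: no state for leaves {missing}")
    present = {l for l in leaves if presence[l]}

    root = tree.seed_node
    if not present and gain_policy == "lca_of_present":
        raise ValueError(f"{character or 'character'} never present")

    if gain_policy == "root" or not present or len(present) == len(leaves):
        gain = root
    else:
        gain = tree.mrca(taxon_labels=sorted(present))

    # all-absent status per node, computed bottom-up under the gain node
    absent_all: dict[int, bool] = {}
    for node in gain.postorder_iter():
        if node.is_leaf():
            absent_all[id(node)] = node.taxon.label not in present
        else:
            absent_all[id(node)] = all(absent_all[id(c)] for c in node.child_nodes())

    loss_clades: list[frozenset[str]] = []
    states: dict[int, bool] = {}

    def walk(node, lost: bool):
        if not lost and absent_all[id(node)]:
            loss_clades.append(_leafset(node))
            lost = True
        states[id(node)] = not lost
        for c in node.child_nodes():
            walk(c, lost)

    # losses live on edges strictly under the gain node: even when every
    # leaf below the gain is absent, each lost child subtree is its own event
    states[id(gain)] = True
    for child in gain.child_nodes():
        walk(child, False)
    if gain.is_leaf():
        states[id(gain)] = gain.taxon.label in present
    # nodes outside the gain clade never had the character
    for node in tree.preorder_node_iter():
        states.setdefault(id(node), False)

    loss_clades.sort(key=lambda s: (len(s), sorted(s)))
    return DolloReconstruction(
        character=character, gain_clade=_leafset(gain),
        loss_clades=loss_clades, states=states)


def ir_loss_events(
    tree: dendropy.Tree, ir_presence: dict[str, bool]
) -> DolloReconstruction:
    """Loss events of the inverted repeat, treated as an ancestral character."""
    return dollo_map(tree, ir_presence, gain_policy="root", character="IR")


def dollo_table(
    tree: dendropy.Tree,
    matrix: pd.DataFrame,
    outgroup_ids: list[str] | None = None,
    pseudogene_as_present: bool = False,
) -> pd.DataFrame:
    """Per-gene loss counts for every non-universal gene in a matrix.

    Genes present in at least one outgroup use a root gain (ancestral);
    the rest use the LCA of the present leaves.
    """
    outgroup_ids = outgroup_ids or []
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    boolm = presence_states(matrix, pseudogene_as_present)
    cols = [c for c in boolm.columns if c in leaves]
    rows = []
    for gene in boolm.index:
        vector = {t: bool(boolm.at[gene, t]) for t in cols}
        if not any(vector.values()):
            continue
        ancestral = any(boolm.at[gene, o] for o in outgroup_ids if o in boolm.columns)
        policy = "root" if ancestral else "lca_of_present"
        rec = dollo_map(tree, vector, gain_policy=policy, character=gene)
        rows.append({
            "gene": gene,
            "gain_policy": policy,
            "n_present": sum(vector.values()),
            "loss_count": rec.loss_count,
            "losses": "; ".join(",".join(sorted(c)) for c in rec.loss_clades),
        })
    return pd.DataFrame(rows).set_index("gene")
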