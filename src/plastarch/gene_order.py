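"""Signed gene-order comparison between circular genomes.

The gene order of a circular genome is the cyclic sequence of gene symbols,
each signed by coding strand.  Reading the circle the other way reverses the
order and flips every sign, so adjacencies (gene pairs) and colinear blocks
must be invariant under that symmetry: a block matches either directly or as
a globally reversed, sign-flipped run.

Because every shared gene occurs exactly once in the reduced orders, blocks
are exactly the maximal circular runs of adjacencies of one genome that are
preserved in the other, which is how they are computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

from .architecture import QuadripartiteStructure, round_half_up
from .genome_io import ChloroGenome, GeneFeature

__all__ = [
    "SignedGeneOrder",
    "AdjacencyPair",
    "extract_signed_order",
    "adjacency_pairs",
    "colinear_blocks",
    "SyntenyBlock",
    "synteny_stats",
    "build_pair_matrix",
    "select_ancestral_pairs",
]


class SignedGene(NamedTuple):
    name: str
    sign: int


@dataclass
class SignedGeneOrder:
    """Circular ordered list of signed gene symbols for one genome."""

    genome_id: str
    elements: list[SignedGene]
    features: list[GeneFeature] = field(default_factory=list)
    n_genes: int | None = None  # unique conserved gene names in the genome

    def __len__(self) -> int:
        return len(self.elements)

    def names(self) -> list[str]:
        return [e.name for e in self.elements]


def extract_signed_order(
    genome: ChloroGenome,
    collapse: QuadripartiteStructure | None = None,
) -> SignedGeneOrder:
    """Signed order of conserved genes by ascending circular midpoint.

    When ``collapse`` is given, features whose midpoint falls in the IRb
    copy are dropped, so the inverted repeat contributes each resident gene
    once (maps draw the IR once per comparison).
    """
    feats = [f for f in genome.features if f.conserved]
    if not feats:
        raise ValueError(f"{genome.id}: no conserved features")
    if collapse is not None:
        feats = [
            f for f in feats
            if collapse.region_of(f.midpoint(genome.length)) != "IRb"
        ]
    feats.sort(key=lambda f: (f.midpoint(genome.length), f.name))
    elements = [SignedGene(f.name, f.strand) for f in feats]
    return SignedGeneOrder(
        genome_id=genome.id, elements=elements, features=feats,
        n_genes=genome.n_genes)


class AdjacencyPair(NamedTuple):
    """Canonical signed gene pair, invariant under reverse reading.

    key((a,sa),(b,sb)) == key((b,-sb),(a,-sa)).
    """

    a: str
    sa: int
    b: str
    sb: int

    @classmethod
    def make(cls, a: str, sa: int, b: str, sb: int) -> "AdjacencyPair":
        fwd = (a, sa, b, sb)
        rev = (b, -sb, a, -sa)
        return cls(*min(fwd, rev))

    def __str__(self) -> str:
        def fmt(g, s):
            return ("+" if s == 1 else "-") + g
        return f"{fmt(self.a, self.sa)}|{fmt(self.b, self.sb)}"

    @property
    def genes(self) -> tuple[str, str]:
        return (self.a, self.b)


def adjacency_pairs(order: SignedGeneOrder | Iterable[SignedGene]) -> set[AdjacencyPair]:
    """All circular adjacencies of a signed order, canonicalized."""
    elements = order.elements if isinstance(order, SignedGeneOrder) else list(order)
    n = len(elements)
    if n < 2:
        return set()
    pairs = set()
    for i in range(n):
        (a, sa), (b, sb) = elements[i], elements[(i + 1) % n]
        pairs.add(AdjacencyPair.make(a, sa, b, sb))
    return pairs


# ---------------------------------------------------------------------------
# Colinear blocks


@dataclass
class SyntenyBlock:
    """A maximal run of shared genes colinear between two genomes."""

    genes: list[str]
    signs1: list[int]
    orientation: str  # "same" | "inverted"
    span1: tuple[int, int]  # (start index, length) in reduced order1
    span2: tuple[int, int]  # (start index, length) in reduced order2

    def __len__(self) -> int:
        return len(self.genes)


def _reduce_to_shared(order1: SignedGeneOrder, order2: SignedGeneOrder):
    """Keep genes occurring exactly once in each order, preserving order."""
    def counts(order):
        c: dict[str, int] = {}
        for e in order.elements:
            c[e.name] = c.get(e.name, 0) + 1
        return c

    c1, c2 = counts(order1), counts(order2)
    shared = {g for g in c1 if g in c2}
    usable = {g for g in shared if c1[g] == 1 and c2[g] == 1}
    skipped = sorted(shared - usable)
    if skipped:
        warnings.warn(
            f"{order1.genome_id} vs {order2.genome_id}: duplicated genes "
            f"excluded from block matching: {', '.join(skipped)}")
    r1 = [e for e in order1.elements if e.name in usable]
    r2 = [e for e in order2.elements if e.name in usable]
    return r1, r2


def colinear_blocks(
    order1: SignedGeneOrder,
    order2: SignedGeneOrder,
    min_len: int = 2,
    max_gap: int = 0,
) -> list[SyntenyBlock]:
    """Maximal colinear blocks between two circular signed gene orders.

    Orders are first reduced to genes present exactly once in each genome
    (duplicates are skipped with a warning).  Blocks are maximal common
    circular runs, matching directly or as reverse complement, may wrap the
    origin, and are discarded below ``min_len`` genes.  ``max_gap`` allows
    that many intervening genes in genome 2 between consecutive block
    members of genome 1 (0 = strict adjacency).
    """
    if not order1.elements or not order2.elements:
        raise ValueError("both orders must be non-empty")
    r1, r2 = _reduce_to_shared(order1, order2)
    if not r1:
        warnings.warn(
            f"{order1.genome_id} vs {order2.genome_id}: no shared single-copy genes")
        return []
    n, m = len(r1), len(r2)
    pos2 = {e.name: (i, e.sign) for i, e in enumerate(r2)}

    def preserved(i: int) -> bool:
        """Is the adjacency r1[i] -> r1[i+1] preserved in r2 (within gap)?"""
        x, y = r1[i], r1[(i + 1) % n]
        ix, tx = pos2[x.name]
        iy, ty = pos2[y.name]
        step = 1 + max_gap
        d_fwd = (iy - ix) % m
        d_rev = (ix - iy) % m
        direct = tx == x.sign and ty == y.sign and 1 <= d_fwd <= step
        inverted = tx == -x.sign and ty == -y.sign and 1 <= d_rev <= step
        return direct or inverted

    if n == 1:
        blocks = [_make_block(r1, 0, 1, pos2, m)]
    else:
        pres = [preserved(i) for i in range(n)]
        if all(pres):
            blocks = [_make_block(r1, 0, n, pos2, m)]
        else:
            blocks = []
            # walk runs starting after each break
            starts = [(i + 1) % n for i in range(n) if not pres[i]]
            for s in sorted(starts):
                length = 1
                while pres[(s + length - 1) % n]:
                    length += 1
                blocks.append(_make_block(r1, s, length, pos2, m))
    blocks = [b for b in blocks if len(b) >= min_len]
    blocks.sort(key=lambda b: b.span1[0])
    return blocks


def _make_block(r1, start: int, length: int, pos2, m: int) -> SyntenyBlock:
    n = len(r1)
    members = [r1[(start + t) % n] for t in range(length)]
    genes = [e.name for e in members]
    signs1 = [e.sign for e in members]
    first = members[0]
    orientation = "same" if pos2[first.name][1] == first.sign else "inverted"
    idx2 = [pos2[g][0] for g in genes]
    if length == 1:
        span2 = (idx2[0], 1)
    elif orientation == "same":
        span2 = (idx2[0], (idx2[-1] - idx2[0]) % m + 1)
    else:
        span2 = (idx2[-1], (idx2[0] - idx2[-1]) % m + 1)
    return SyntenyBlock(genes=genes, signs1=signs1, orientation=orientation,
                        span1=(start, length), span2=span2)


def synteny_stats(
    blocks: list[SyntenyBlock],
    order1: SignedGeneOrder,
    order2: SignedGeneOrder,
) -> dict:
    """Block-level synteny summary between two genomes.

    Percentages use each genome's unique conserved gene count as the
    denominator and are rounded half-up to integers.
    """
    gene_set: set[str] = set()
    for b in blocks:
        gene_set.update(b.genes)
    n1 = order1.n_genes or len({e.name for e in order1.elements})
    n2 = order2.n_genes or len({e.name for e in order2.elements})
    largest = max(blocks, key=len, default=None)
    if largest is not None:
        largest = next(b for b in blocks if len(b) == len(largest))
    return {
        "n_blocks": len(blocks),
        "n_block_genes": len(gene_set),
        "pct_of_g1": int(round_half_up(100.0 * len(gene_set) / n1, 0)) if n1 else 0,
        "pct_of_g2": int(round_half_up(100.0 * len(gene_set) / n2, 0)) if n2 else 0,
        "largest_block": list(largest.genes) if largest else [],
    }


# ---------------------------------------------------------------------------
# Ancestral gene-pair selection across a study panel


def build_pair_matrix(orders: dict[str, SignedGeneOrder]) -> pd.DataFrame:
    """Boolean pair x genome presence matrix over all observed adjacencies.

    Indexed by the canonical pair string; the AdjacencyPair objects live in
    the ``pair_obj`` column.
    """
    adj = {gid: adjacency_pairs(o) for gid, o in orders.items()}
    all_pairs = sorted({p for s in adj.values() for p in s}, key=str)
    data = {gid: [p in adj[gid] for p in all_pairs] for gid in sorted(orders)}
    df = pd.DataFrame(data, index=pd.Index([str(p) for p in all_pairs], name="pair"))
    df.insert(0, "pair_obj", all_pairs)
    return df


def select_ancestral_pairs(
    matrix: pd.DataFrame,
    lineage_map: dict[str, str],
    outgroup_ids: list[str],
    repertoires: dict[str, set[str]],
) -> pd.DataFrame:
    """Flag ancestral gene pairs in a pair-presence matrix.

    Rule A: the pair is present in at least two ingroup genomes from
    distinct lineages and in at least one outgroup.  Rule B: a member gene
    of the pair is missing from at least two ingroup lineages or from both
    outgroups, and the pair is present in at least one ingroup lineage
    (outgroup presence not required).  Cells where a member gene is absent
    from a genome's repertoire are tagged "absent_gene_loss" as opposed to
    "absent_rearranged".
    """
    genome_cols = [c for c in matrix.columns if c != "pair_obj"]
    ingroup = [g for g in genome_cols if g not in outgroup_ids]
    unmapped = [g for g in ingroup if g not in lineage_map]
    if unmapped:
        raise KeyError(f"genomes not in lineage_map: {unmapped}")
    missing_rep = [g for g in genome_cols if g not in repertoires]
    if missing_rep:
        raise KeyError(f"genomes without repertoires: {missing_rep}")
    lineages = sorted(set(lineage_map[g] for g in ingroup))

    rows = []
    for key, row in matrix.iterrows():
        pair: AdjacencyPair = row["pair_obj"]
        present = {g for g in genome_cols if row[g]}
        genes = pair.genes
        in_lineages = {lineage_map[g] for g in present if g in lineage_map}
        out_present = [g for g in outgroup_ids if g in present]

        rule_a = len(in_lineages) >= 2 and len(out_present) >= 1

        # lineages from which some member gene is entirely missing
        gene_absent_lineages = set()
        for lin in lineages:
            members = [g for g in ingroup if lineage_map[g] == lin]
            for gene in genes:
                if all(gene not in repertoires[g] for g in members):
                    gene_absent_lineages.add(lin)
                    break
        gene_absent_both_outgroups = any(
            all(gene not in repertoires[o] for o in outgroup_ids)
            for gene in genes) if outgroup_ids else False
        rule_b = (
            (len(gene_absent_lineages) >= 2 or gene_absent_both_outgroups)
            and len(in_lineages) >= 1
        )

        status = {}
        for g in genome_cols:
            if g in present:
                status[g] = "present"
            elif any(gene not in repertoires[g] for gene in genes):
                status[g] = "absent_gene_loss"
            else:
                status[g] = "absent_rearranged"

        rows.append({
            "pair": key,
            "selected": rule_a or rule_b,
            "rule": "A" if rule_a else ("B" if rule_b else ""),
            **status,
        })
    return pd.DataFrame(rows).set_index("pair")
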