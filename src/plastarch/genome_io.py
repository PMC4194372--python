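"""Annotated-genome, gene-order-TSV and species-tree input/output.

Coordinates are 0-based half-open on the circular genome; a feature that
wraps the origin is stored as two spans ``[s, L) + [0, e)``.  GenBank
1-based closed locations are converted on read (Biopython already exposes
them 0-based half-open).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import dendropy
from Bio import SeqIO

from .catalog import Catalog, default_catalog, normalize_name, split_part_suffix

__all__ = [
    "GeneFeature",
    "ChloroGenome",
    "read_genome_record",
    "write_gene_order_tsv",
    "read_gene_order_tsv",
    "read_tree",
    "GenomeParseError",
]


class GenomeParseError(ValueError):
    """Raised for malformed genome records or gene-order files."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene occurrence on a circular genome.

    ``intervals`` is an ordered tuple of ``[start, end)`` spans; a feature
    wrapping the origin carries two spans.  ``conserved`` marks membership
    of the conserved-gene catalog (free-standing ORFs are parsed but not
    conserved).  ``part`` labels fragments of trans-spliced/split genes
    (ycf3a / ycf3b); such fragments share a ``base_name``.
    """

    name: str
    category: str
    strand: int
    intervals: tuple[tuple[int, int], ...]
    conserved: bool = False
    part: str | None = None
    pseudo: bool = False

    def __post_init__(self):
        if not self.name:
            raise ValueError("feature name must be non-empty")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")
        if not self.intervals:
            raise ValueError(f"{self.name}: intervals must be non-empty")

    @property
    def base_name(self) -> str:
        base, part = split_part_suffix(self.name)
        return base if part is not None else self.name

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def extent(self, genome_length: int) -> tuple[int, int]:
        """Circular extent (begin, span) covering first start to last end."""
        begin = self.intervals[0][0]
        end = self.intervals[-1][1]
        span = end - begin if end > begin else end + genome_length - begin
        return begin, span

    def midpoint(self, genome_length: int) -> float:
        begin, span = self.extent(genome_length)
        return (begin + span / 2.0) % genome_length


@dataclass
class ChloroGenome:
    """An annotated circular chloroplast genome."""

    id: str
    length: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self):
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != {self.length}"
            )
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < self.length and 0 < e <= self.length):
                    raise ValueError(f"{self.id}/{f.name}: span ({s},{e}) outside genome")

    def require_sequence(self) -> str:
        if self.sequence is None:
            raise GenomeParseError(f"{self.id}: sequence absent")
        return self.sequence

    def sorted_features(self, conserved_only: bool = False) -> list[GeneFeature]:
        feats = [f for f in self.features if f.conserved or not conserved_only]
        return sorted(feats, key=lambda f: (f.midpoint(self.length), f.name))

    def gene_names(self, conserved_only: bool = True) -> set[str]:
        """Unique base names (IR duplicates and gene parts collapse)."""
        return {
            f.base_name
            for f in self.features
            if f.conserved or not conserved_only
        }

    @property
    def n_genes(self) -> int:
        return len(self.gene_names())


# ---------------------------------------------------------------------------
# GenBank flatfile reading

_FEATURE_TYPES = ("gene", "CDS", "tRNA", "rRNA", "ncRNA", "misc_RNA")


def _location_spans(feat, length: int) -> tuple[tuple[int, int], ...]:
    spans = []
    for part in feat.location.parts:
        s, e = int(part.start), int(part.end)
        if not (0 <= s < e <= length):
            raise GenomeParseError(f"unparseable location for {feat}")
        spans.append((s, e))
    spans.sort()
    # merge an origin-wrapping pair into wrap order: [s,L) then [0,e)
    if len(spans) >= 2 and spans[0][0] == 0 and spans[-1][1] == length:
        spans = spans[1:] + spans[:1]
    return tuple(spans)


def _raw_name(feat) -> str | None:
    q = feat.qualifiers
    for key in ("gene", "standard_name", "locus_tag", "product"):
        if key in q and q[key]:
            return q[key][0]
    return None


def read_genome_record(path, catalog: Catalog | None = None) -> ChloroGenome:
    """Read a GenBank flatfile into a :class:`ChloroGenome`.

    One :class:`GeneFeature` per annotated gene occurrence: gene/CDS/RNA
    records for the same locus (same normalized name, overlapping circular
    extents) merge into one feature covering exons and introns, while IR
    duplicates (disjoint extents) stay separate occurrences.
    """
    if catalog is None:
        catalog = default_catalog()
    record = SeqIO.read(str(path), "genbank")
    length = len(record.seq)
    if length == 0:
        raise GenomeParseError(f"{path}: zero-length record")
    sequence = str(record.seq).upper() if len(record.seq) else None

    candidates = []  # (name, category, conserved, strand, spans, pseudo)
    for feat in record.features:
        if feat.type not in _FEATURE_TYPES:
            continue
        raw = _raw_name(feat)
        if raw is None:
            continue
        name, category, conserved = normalize_name(raw, catalog)
        spans = _location_spans(feat, length)
        strand = -1 if feat.location.strand == -1 else 1
        pseudo = "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers
        candidates.append((name, category, conserved, strand, spans, pseudo))

    features = _merge_candidates(candidates, length)
    features.sort(key=lambda f: (f.midpoint(length), f.name))
    return ChloroGenome(id=record.id or record.name, length=length,
                        features=features, sequence=sequence)


def _circ_overlap(a: tuple[int, int], b: tuple[int, int], length: int) -> bool:
    def unroll(ext):
        begin, span = ext
        return [(begin, begin + span)] if begin + span <= length else [
            (begin, length), (0, begin + span - length)]
    for s1, e1 in unroll(a):
        for s2, e2 in unroll(b):
            if s1 < e2 and s2 < e1:
                return True
    return False


def _extent_of(spans, length: int) -> tuple[int, int]:
    begin = spans[0][0]
    end = spans[-1][1]
    span = end - begin if end > begin else end + length - begin
    return begin, span


def _merge_candidates(candidates, length: int) -> list[GeneFeature]:
    by_name: dict[str, list] = {}
    for cand in candidates:
        by_name.setdefault(cand[0], []).append(cand)

    features: list[GeneFeature] = []
    for name, group in by_name.items():
        clusters: list[list] = []
        for cand in group:
            ext = _extent_of(cand[4], length)
            placed = False
            for cl in clusters:
                if any(_circ_overlap(ext, other_ext, length) for other_ext, _ in cl):
                    cl.append((ext, cand))
                    placed = True
                    break
            if not placed:
                clusters.append([(ext, cand)])
        for cl in clusters:
            features.append(_merge_cluster(name, cl, length))
    return features


def _merge_cluster(name, cluster, length: int) -> GeneFeature:
    # Union extent over all records of this locus: exons + introns.  Offsets
    # are taken relative to the first record's begin; members starting just
    # before it (circularly) get negative offsets.
    exts = [ext for ext, _ in cluster]
    cands = [cand for _, cand in cluster]
    ref = exts[0][0]
    lo, hi = 0, exts[0][1]
    for b, span in exts[1:]:
        rel = (b - ref) % length
        if rel > length // 2:
            rel -= length
        lo = min(lo, rel)
        hi = max(hi, rel + span)
    begin = (ref + lo) % length
    end = begin + (hi - lo)
    if end <= length:
        spans = ((begin, end),)
    else:
        spans = ((begin, length), (0, end - length))
    _, category, conserved, strand, _, _ = cands[0]
    pseudo = any(c[5] for c in cands)
    base, part = split_part_suffix(name)
    return GeneFeature(name=name, category=category, strand=strand,
                       intervals=spans, conserved=conserved,
                       part=part if base != name else None, pseudo=pseudo)


# ---------------------------------------------------------------------------
# Gene-order TSV dialect
#
#   #id <id> length <bp>
#   name <TAB> strand(+/-) <TAB> start-end[,start-end] <TAB> conserved(0/1)
#
# Rows are written in genome order (ascending circular midpoint).


def write_gene_order_tsv(genome: ChloroGenome, path) -> None:
    lines = [f"#id {genome.id} length {genome.length}"]
    for f in genome.sorted_features():
        spans = ",".join(f"{s}-{e}" for s, e in f.intervals)
        strand = "+" if f.strand == 1 else "-"
        lines.append(f"{f.name}\t{strand}\t{spans}\t{int(f.conserved)}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gene_order_tsv(path) -> ChloroGenome:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#id "):
        raise GenomeParseError(f"{path}:1: missing '#id <id> length <bp>' header")
    head = lines[0].split()
    try:
        gid = head[1]
        length = int(head[3])
        assert head[2] == "length"
    except (IndexError, ValueError, AssertionError):
        raise GenomeParseError(f"{path}:1: malformed header {lines[0]!r}") from None

    features = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise GenomeParseError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
        name, strand_s, spans_s, cons_s = fields
        try:
            strand = {"+": 1, "-": -1}[strand_s]
            spans = tuple(
                (int(a), int(b))
                for a, b in (p.split("-") for p in spans_s.split(","))
            )
            conserved = bool(int(cons_s))
        except (KeyError, ValueError) as exc:
            raise GenomeParseError(f"{path}:{lineno}: {exc}") from None
        from .catalog import infer_category
        base, part = split_part_suffix(name)
        features.append(GeneFeature(
            name=name, category=infer_category(name), strand=strand,
            intervals=spans, conserved=conserved,
            part=part if base != name else None))
    return ChloroGenome(id=gid, length=length, features=features)


# ---------------------------------------------------------------------------
# Species trees


def read_tree(path) -> dendropy.Tree:
    """Read a rooted newick species tree; polytomies are preserved."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise GenomeParseError(f"duplicate leaf labels: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise GenomeParseError(f"duplicate leaf labels: {dupes}")
    tree.is_rooted = True
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree
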