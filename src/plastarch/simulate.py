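"""Synthetic chloroplast-like genomes evolved along a species tree.

The generator emulates the study system at the resolution the pipeline
works at: circular genomes of roughly 60-200 kb carrying ~85-130 named
conserved genes on both strands, an optional exact inverted repeat housing
the rRNA operon, spacer DNA tuned to a target intergenic fraction and a
target A+T content.  Evolution along a rooted tree applies, per branch,
gene losses, loss of one IR copy, and segmental inversions whose
breakpoints never split a feature.  Every event is logged with exact
coordinates so leaves can be reproduced by replay.

Nucleotides are i.i.d. with the configured A+T bias; there is no codon
structure, substitution process or intron model — the pipeline never
translates, so none of those features are needed for its tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .architecture import revcomp
from .catalog import default_catalog
from .genome_io import ChloroGenome, GeneFeature

__all__ = [
    "IRConfig",
    "SimulationConfig",
    "SimulatedClade",
    "simulate_ancestor",
    "evolve",
    "replay_events",
]

# fixed biological lengths (bp) for structural RNA genes
_RRNA_LEN = {"rrs": 1480, "rrl": 2890, "rrf": 120}


@dataclass(frozen=True)
class IRConfig:
    length: int = 12_000
    rrn_genes: tuple[str, ...] = ("rrs", "trnI-gau", "trnA-ugc", "rrl", "rrf")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults: mid-range genome size and gene count,
    A+T and intergenic fractions typical of compact prasinophyte plastomes,
    a handful of rearrangements and losses per branch."""

    n_genes: int = 110
    genome_bp: int = 100_000
    at_pct: float = 62.0
    intergenic_target_pct: float = 15.0
    ir: IRConfig | None = IRConfig()
    n_inversions: int = 3
    n_losses: int = 2
    p_ir_loss: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0 or self.n_inversions < 0 or self.n_losses < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.p_ir_loss <= 1.0:
            raise ValueError("p_ir_loss must be in [0, 1]")
        if self.ir is not None and self.ir.length >= self.genome_bp / 2:
            raise ValueError("ir.length must be < genome_bp / 2")


@dataclass
class SimulatedClade:
    """A simulated ancestor evolved to the leaves of a tree."""

    tree: dendropy.Tree
    ancestor: ChloroGenome
    genomes: dict[str, ChloroGenome]
    events: list[dict] = field(default_factory=list)
    ir_present: dict[str, bool] = field(default_factory=dict)

    def true_presence(self) -> dict[str, set[str]]:
        """Per-leaf conserved base-name sets implied by the genomes."""
        return {gid: g.gene_names() for gid, g in self.genomes.items()}


def _random_seq(rng: np.random.Generator, length: int, at_pct: float) -> str:
    p_at = at_pct / 200.0
    p_gc = (100.0 - at_pct) / 200.0
    bases = rng.choice(np.array(list("ATGC")), size=length,
                       p=[p_at, p_at, p_gc, p_gc])
    return "".join(bases)


def _gene_length(rng: np.random.Generator, name: str, category: str) -> int:
    if category == "rRNA":
        return _RRNA_LEN.get(name, 1500)
    if category == "tRNA":
        return int(rng.integers(72, 91))
    return int(rng.integers(300, 1800))


def simulate_ancestor(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> ChloroGenome:
    """Build the ancestral circular genome described by *config*."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    catalog = default_catalog()
    if config.n_genes == 0:
        length = max(config.genome_bp, 1)
        return ChloroGenome(id="ancestor", length=length,
                            sequence=_random_seq(rng, length, config.at_pct))

    pool = [g for g in catalog.names() if catalog.genes[g] != "other"]
    ir_genes = list(config.ir.rrn_genes) if config.ir else []
    for g in ir_genes:
        if g in pool:
            pool.remove(g)
    n_sc = config.n_genes - len(ir_genes)
    if n_sc < 0:
        raise ValueError("n_genes smaller than the IR rRNA operon")
    sc_names = sorted(rng.choice(pool, size=min(n_sc, len(pool)),
                                 replace=False).tolist())
    sc_names = [sc_names[i] for i in rng.permutation(len(sc_names))]

    lengths = {g: _gene_length(rng, g, catalog.category(g)) for g in sc_names + ir_genes}

    # Solve spacer budget for the intergenic target.
    p = config.intergenic_target_pct
    ir_gap = 50  # fixed spacer between IR-resident genes
    ir_genic = sum(lengths[g] for g in ir_genes)
    if config.ir:
        min_ir = ir_genic + ir_gap * (len(ir_genes) + 1)
        ir_len = max(config.ir.length, min_ir)
        ir_filler = ir_len - ir_genic
    else:
        ir_len = ir_filler = 0
    total = config.genome_bp
    spacer_sc = p / 100.0 * total - 2 * ir_filler
    n_gaps = max(n_sc + 2, 1)
    spacer_sc = max(spacer_sc, 2.0 * n_gaps)
    # scale protein lengths so everything sums close to genome_bp
    sc_target = total - 2 * ir_len - spacer_sc
    sc_now = sum(lengths[g] for g in sc_names)
    scalable = [g for g in sc_names if catalog.category(g) == "protein"]
    fixed = sc_now - sum(lengths[g] for g in scalable)
    if scalable and sc_target > fixed:
        factor = (sc_target - fixed) / max(sum(lengths[g] for g in scalable), 1)
        for g in scalable:
            lengths[g] = max(150, int(round(lengths[g] * factor)))

    # split SC genes: ~15% to the small single-copy region
    n_ssc = max(1, int(round(0.15 * len(sc_names)))) if config.ir else 0
    ssc_names = sc_names[:n_ssc]
    lsc_names = sc_names[n_ssc:]

    gaps = rng.dirichlet(np.ones(n_gaps)) * (spacer_sc - 2 * n_gaps) + 2
    gaps = [int(round(x)) for x in gaps]
    gap_iter = iter(gaps + [2] * 8)

    segments: list[tuple[str | None, int, str]] = []  # (feature name|None, strand, seq)

    def add_spacer(n_bp: int):
        segments.append((None, 0, _random_seq(rng, n_bp, config.at_pct)))

    def add_gene(name: str, strand: int | None = None):
        s = int(strand if strand is not None else rng.choice([1, -1]))
        segments.append((name, s, _random_seq(rng, lengths[name], config.at_pct)))

    for g in lsc_names:
        add_spacer(next(gap_iter))
        add_gene(g)
    add_spacer(next(gap_iter))

    ir_segments: list[tuple[str | None, int, str]] = []
    if config.ir:
        ir_segments.append((None, 0, _random_seq(rng, ir_gap, config.at_pct)))
        for g in ir_genes:
            ir_segments.append((g, 1, _random_seq(rng, lengths[g], config.at_pct)))
            ir_segments.append((None, 0, _random_seq(rng, ir_gap, config.at_pct)))
        rest = ir_len - sum(len(s) for _, _, s in ir_segments)
        if rest > 0:
            ir_segments.append((None, 0, _random_seq(rng, rest, config.at_pct)))
        segments.extend(ir_segments)  # IRa
        for g in ssc_names:
            add_spacer(next(gap_iter))
            add_gene(g)
        add_spacer(next(gap_iter))
        # IRb: reverse-complement mirror of IRa
        for name, strand, seq in reversed(ir_segments):
            segments.append((name, -strand, revcomp(seq)))

    # assemble
    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for name, strand, seq in segments:
        if name is not None:
            features.append(GeneFeature(
                name=name, category=catalog.category(name),
                strand=strand, intervals=((pos, pos + len(seq)),),
                conserved=True))
        seq_parts.append(seq)
        pos += len(seq)
    sequence = "".join(seq_parts)

    if config.ir:
        # pin the IR boundaries: flanking bases must not extend the repeat
        sequence, features = _pin_ir_boundaries(sequence, segments, ir_segments)

    return ChloroGenome(id="ancestor", length=len(sequence),
                        features=features, sequence=sequence)


def _pin_ir_boundaries(sequence: str, segments, ir_segments) -> tuple[str, list]:
    """Mutate the spacer bases flanking IRa/IRb so seed-extension of the
    planted repeat stops exactly at the planted boundaries."""
    ir_total = sum(len(s) for _, _, s in ir_segments)
    offset = 0
    ira_start = None
    for seg in segments:
        if seg is ir_segments[0]:
            ira_start = offset
            break
        offset += len(seg[2])
    ira = (ira_start, ira_start + ir_total)
    # the mirror copy is laid out last, so it ends the sequence
    irb = (len(sequence) - ir_total, len(sequence))

    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    s = list(sequence)
    n = len(s)

    def fix(p: int, q: int):
        # ensure s[p] != comp(s[q])
        if comp[s[p]] == s[q]:
            s[p] = "A" if comp["A"] != s[q] else "C"

    fix((ira[0] - 1) % n, irb[1] % n)
    fix(ira[1] % n, (irb[0] - 1) % n)

    # rebuild features unchanged (coordinates unaffected)
    catalog = default_catalog()
    features = []
    pos = 0
    for name, strand, seq in segments:
        if name is not None:
            features.append(GeneFeature(
                name=name, category=catalog.category(name),
                strand=strand, intervals=((pos, pos + len(seq)),),
                conserved=True))
        pos += len(seq)
    return "".join(s), features


# ---------------------------------------------------------------------------
# Editing primitives (shared by evolve and replay)


def _delete_span(genome: ChloroGenome, start: int, end: int) -> ChloroGenome:
    """Remove [start, end) from sequence and shift features; features inside
    the span are dropped, features straddling it are not allowed."""
    assert 0 <= start < end <= genome.length
    size = end - start
    feats = []
    for f in genome.features:
        (s, e), = f.intervals
        if s >= start and e <= end:
            continue
        if s < end and e > start:
            raise ValueError(f"{f.name} straddles deletion [{start},{end})")
        if s >= end:
            f = replace(f, intervals=((s - size, e - size),))
        feats.append(f)
    seq = None
    if genome.sequence is not None:
        seq = genome.sequence[:start] + genome.sequence[end:]
    return ChloroGenome(id=genome.id, length=genome.length - size,
                        features=feats, sequence=seq)


def _invert_span(genome: ChloroGenome, start: int, end: int) -> ChloroGenome:
    """Reverse-complement [start, end); features inside are reflected and
    strand-flipped, features straddling the breakpoints are not allowed."""
    assert 0 <= start < end <= genome.length
    feats = []
    for f in genome.features:
        (s, e), = f.intervals
        if s >= start and e <= end:
            ns, ne = start + (end - e), start + (end - s)
            f = replace(f, intervals=((ns, ne),), strand=-f.strand)
        elif s < end and e > start:
            raise ValueError(f"{f.name} straddles inversion [{start},{end})")
        feats.append(f)
    seq = None
    if genome.sequence is not None:
        seq = (genome.sequence[:start]
               + revcomp(genome.sequence[start:end])
               + genome.sequence[end:])
    feats.sort(key=lambda f: f.intervals[0][0])
    return ChloroGenome(id=genome.id, length=genome.length,
                        features=feats, sequence=seq)


def _apply_event(genome: ChloroGenome, event: dict) -> ChloroGenome:
    kind = event["event"]
    if kind == "gene_loss":
        for s, e in sorted(event["spans"], reverse=True):
            genome = _delete_span(genome, s, e)
        return genome
    if kind == "ir_loss":
        s, e = event["span"]
        return _delete_span(genome, s, e)
    if kind == "inversion":
        return _invert_span(genome, event["start"], event["end"])
    raise ValueError(f"unknown event {kind!r}")


# ---------------------------------------------------------------------------


def _label_nodes(tree: dendropy.Tree) -> None:
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            node.label = f"N{k}"
        k += 1


def _node_label(node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def _ir_spans(genome: ChloroGenome, min_len: int = 1000):
    from .architecture import detect_inverted_repeat

    seq = genome.sequence
    quad = detect_inverted_repeat(seq, min_len=min_len) if seq else None
    return quad


def _in_any(pos: int, spans) -> bool:
    return any(s <= pos < e for s, e in spans)


def _eligible_loss_genes(genome: ChloroGenome, ir_span) -> list[str]:
    """Unique conserved base names that can be lost: not rRNA-operon genes
    and with no occurrence inside an IR copy."""
    bad = set()
    names: dict[str, list[GeneFeature]] = {}
    for f in genome.features:
        if not f.conserved:
            continue
        names.setdefault(f.base_name, []).append(f)
        if f.category == "rRNA":
            bad.add(f.base_name)
        if ir_span is not None:
            (s, e), = f.intervals
            for span in ir_span:
                if span and span[0] <= s and e <= span[1]:
                    bad.add(f.base_name)
    return sorted(n for n in names if n not in bad)


def evolve(ancestor: ChloroGenome, tree: dendropy.Tree,
           config: SimulationConfig,
           rng: np.random.Generator | None = None) -> SimulatedClade:
    """Evolve *ancestor* along *tree*; per branch: gene losses, possible IR
    loss, then inversions.  Returns leaves plus the full event log."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    tree = tree.clone(depth=1)
    _label_nodes(tree)

    events: list[dict] = []
    leaf_genomes: dict[str, ChloroGenome] = {}
    ir_present: dict[str, bool] = {}

    # track IR spans explicitly: (ira, irb) in current coordinates or None
    root_quad = _current_ir(ancestor, config)

    def descend(node, genome: ChloroGenome, quad):
        for child in node.child_nodes():
            g, q = genome, quad
            label = _node_label(child)

            for _ in range(config.n_losses):
                eligible = _eligible_loss_genes(g, q)
                if not eligible:
                    raise ValueError(f"branch {label}: no genes left to lose")
                gene = eligible[int(rng.integers(len(eligible)))]
                spans = [f.intervals[0] for f in g.features if f.base_name == gene]
                ev = {"branch": label, "event": "gene_loss", "gene": gene,
                      "spans": [list(sp) for sp in spans]}
                g = _apply_event(g, ev)
                q = _shift_quad(q, spans)
                events.append(ev)

            if q is not None and rng.random() < config.p_ir_loss:
                ira, irb = q
                ev = {"branch": label, "event": "ir_loss", "span": list(irb)}
                g = _apply_event(g, ev)
                q = None
                events.append(ev)

            for _ in range(config.n_inversions):
                pick = _pick_inversion(g, q, rng)
                if pick is None:
                    break
                x, y = pick
                ev = {"branch": label, "event": "inversion", "start": x, "end": y}
                g = _apply_event(g, ev)
                q = _reflect_quad(q, x, y)
                events.append(ev)

            if child.is_leaf():
                leaf = ChloroGenome(id=label, length=g.length,
                                    features=list(g.features), sequence=g.sequence)
                leaf_genomes[label] = leaf
                ir_present[label] = q is not None
            else:
                descend(child, g, q)

    root_genome = ChloroGenome(id="ancestor", length=ancestor.length,
                               features=list(ancestor.features),
                               sequence=ancestor.sequence)
    descend(tree.seed_node, root_genome, root_quad)
    return SimulatedClade(tree=tree, ancestor=ancestor, genomes=leaf_genomes,
                          events=events, ir_present=ir_present)


def _current_ir(genome: ChloroGenome, config: SimulationConfig):
    if config.ir is None or genome.sequence is None:
        return None
    quad = _ir_spans(genome, min_len=min(1000, config.ir.length))
    if quad is None:
        return None
    n = genome.length
    ira = (quad.ira[0] % n, ((quad.ira[1] - 1) % n) + 1)
    irb = (quad.irb[0] % n, ((quad.irb[1] - 1) % n) + 1)
    return (ira, irb)


def _shift_quad(quad, deleted_spans):
    if quad is None:
        return None
    spans = sorted(deleted_spans, reverse=True)
    ira, irb = quad
    for s, e in spans:
        size = e - s
        ira = tuple(v - size if v >= e else v for v in ira)
        irb = tuple(v - size if v >= e else v for v in irb)
    return (ira, irb)


def _reflect_quad(quad, x, y):
    if quad is None:
        return None

    def reflect(span):
        s, e = span
        if s >= x and e <= y:
            return (x + (y - e), x + (y - s))
        return span

    ira, irb = reflect(quad[0]), reflect(quad[1])
    if ira[0] > irb[0]:
        ira, irb = irb, ira
    return (ira, irb)


def _pick_inversion(genome: ChloroGenome, quad, rng,
                    max_tries: int = 200) -> tuple[int, int] | None:
    """Two intergenic breakpoints outside the IR copies whose segment
    contains at least one feature but not all of them."""
    n = genome.length
    feats = sorted(genome.features, key=lambda f: f.intervals[0][0])
    if len(feats) < 2:
        return None
    forbidden = [f.intervals[0] for f in feats]
    if quad is not None:
        forbidden = forbidden + [quad[0], quad[1]]
    blocked = np.zeros(n, dtype=bool)
    for s, e in forbidden:
        blocked[s + 1 : e] = True  # a breakpoint AT a span start is allowed
    allowed = np.flatnonzero(~blocked)
    if len(allowed) < 2:
        return None

    for _ in range(max_tries):
        x, y = sorted(int(allowed[i]) for i in rng.integers(0, len(allowed), size=2))
        if x == y:
            continue
        # breakpoints must not split a forbidden span; containment is fine
        inside = [f for f in feats
                  if f.intervals[0][0] >= x and f.intervals[0][1] <= y]
        straddle = [f for f in feats
                    if f.intervals[0][0] < y and f.intervals[0][1] > x
                    and f not in inside]
        if straddle:
            continue
        if quad is not None:
            bad = False
            copies_inside = 0
            for s, e in (quad[0], quad[1]):
                if s < x < e or s < y < e:  # breakpoint splits an IR copy
                    bad = True
                elif x <= s and e <= y:
                    copies_inside += 1
            # flipping exactly one copy would turn the IR into a direct
            # repeat; a segment must contain both copies or neither
            if bad or copies_inside == 1:
                continue
        if inside and len(inside) < len(feats):
            return (x, y)
    return None


def replay_events(ancestor: ChloroGenome, tree: dendropy.Tree,
                  events: list[dict]) -> dict[str, ChloroGenome]:
    """Re-derive every leaf genome from the ancestor using only the logged
    event coordinates (no randomness)."""
    tree = tree.clone(depth=1)
    _label_nodes(tree)
    by_branch: dict[str, list[dict]] = {}
    for ev in events:
        by_branch.setdefault(ev["branch"], []).append(ev)

    leaves: dict[str, ChloroGenome] = {}

    def descend(node, genome: ChloroGenome):
        for child in node.child_nodes():
            label = _node_label(child)
            g = genome
            for ev in by_branch.get(label, []):
                g = _apply_event(g, ev)
            if child.is_leaf():
                leaves[label] = ChloroGenome(id=label, length=g.length,
                                             features=list(g.features),
                                             sequence=g.sequence)
            else:
                descend(child, g)

    descend(tree.seed_node, ancestor)
    return leaves
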