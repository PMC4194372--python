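"""Per-genome architecture metrics and inverted-repeat / quadripartite detection.

The quadripartite architecture of most green-plant plastomes consists of two
identical reverse-complement copies of a large inverted repeat (IRa/IRb,
usually carrying the rRNA operon) separating a large and a small single-copy
region (LSC/SSC).  Detection here is exact (mismatch tolerance 0): a single
integer IR length per genome implies an exact repeat.  Candidate pairs are
found by seed-and-extend on k-mer anchors against the reverse complement,
then the maximal-length pair of disjoint copies is returned.

Repeated-sequence content is measured REPuter-style: all maximal exact
repeats of at least ``min_len`` bases, in forward and palindromic
(reverse-complement) orientation, are masked on the working sequence (with
one IR copy removed first when the quadripartite structure is known) and the
masked fraction is reported.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .genome_io import ChloroGenome, GeneFeature, GenomeParseError

__all__ = [
    "GenomeMetrics",
    "QuadripartiteStructure",
    "at_content",
    "detect_inverted_repeat",
    "intergenic_fraction",
    "repeat_fraction",
    "partition_conformity",
    "genome_metrics",
    "revcomp",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------


def at_content(sequence: str) -> float:
    """A+T percentage of a nucleotide sequence, to 0.1 (N excluded)."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    at = s.count("A") + s.count("T")
    acgt = at + s.count("C") + s.count("G")
    if acgt == 0:
        raise ValueError("sequence contains no A/C/G/T")
    return round_half_up(100.0 * at / acgt, 1)


# ---------------------------------------------------------------------------
# Inverted repeat detection


@dataclass
class QuadripartiteStructure:
    """IRa/IRb plus the two single-copy regions of a circular genome.

    Spans are ``(start, end)`` in unwrapped coordinates: ``end`` may exceed
    the genome length when a region wraps the origin; reduce modulo the
    length to map back onto the circle.  ``ira`` is the copy with the
    smaller start; ``lsc`` the longer single-copy region.
    """

    ira: tuple[int, int]
    irb: tuple[int, int]
    lsc: tuple[int, int]
    ssc: tuple[int, int]
    ir_length: int
    genome_length: int
    rrn_orientation: str = "absent"

    def region_of(self, position: float) -> str:
        n = self.genome_length
        for label, (s, e) in (("IRa", self.ira), ("IRb", self.irb),
                              ("LSC", self.lsc), ("SSC", self.ssc)):
            if (position - s) % n < (e - s):
                return label
        raise ValueError(f"position {position} not on the circle")

    def compartment_of(self, feature: GeneFeature) -> str:
        region = self.region_of(feature.midpoint(self.genome_length))
        return "IR" if region in ("IRa", "IRb") else region

    def contains(self, span: tuple[int, int], which: str) -> bool:
        s, e = getattr(self, which)
        n = self.genome_length
        s2, e2 = span
        ext = e2 - s2 if e2 > s2 else e2 + n - s2
        return (s2 - s) % n + ext <= (e - s)


def _eq_rc(seq: str, p: int, q: int) -> bool:
    return _COMP.get(seq[p]) == seq[q]


def _maximal_rc_pairs(seq: str, min_len: int, k: int | None = None):
    """Maximal pairs (a, b, L): circular segments [a,a+L) and [b,b+L) that
    are exact reverse complements, found by k-mer seed and extend."""
    n = len(seq)
    if n < 2 * min_len:
        return []
    if k is None:
        k = min(min_len, 20)
    ext = seq + seq[: k - 1]
    pos: dict[str, list[int]] = defaultdict(list)
    for i in range(n):
        pos[ext[i : i + k]].append(i)

    visited: set[tuple[int, int]] = set()
    found: dict[tuple[int, int, int], None] = {}
    max_ext = n - k
    for i in range(n):
        rc = revcomp(ext[i : i + k])
        for j in pos.get(rc, ()):
            if (i, j) in visited:
                continue
            left = 0
            while left < max_ext and _eq_rc(seq, (i - 1 - left) % n, (j + k + left) % n):
                left += 1
            right = 0
            while left + right < max_ext and _eq_rc(
                seq, (i + k + right) % n, (j - 1 - right) % n
            ):
                right += 1
            L = k + left + right
            a = (i - left) % n
            b = (j - right) % n
            for t in range(L - k + 1):
                visited.add(((a + t) % n, (b + L - k - t) % n))
            if L >= min_len:
                key = (a, b, L) if a <= b else (b, a, L)
                found[key] = None
    return list(found)


def _circ_disjoint(a: int, b: int, L: int, n: int) -> bool:
    if a == b or 2 * L > n:
        return False
    gap1 = (b - (a + L)) % n
    gap2 = (a - (b + L)) % n
    return gap1 + gap2 == n - 2 * L


def _trim_to_disjoint(a: int, b: int, L: int, n: int) -> tuple[int, int, int] | None:
    """Largest disjoint sub-pair of an overlapping reverse-complement pair.

    A prefix of copy A pairs with the same-length suffix of copy B (and
    vice versa), so trimming from matched ends preserves the repeat.
    """
    for sub in range(L - 1, 0, -1):
        for aa, bb in (
            (a, (b + L - sub) % n),        # prefix of A / suffix of B
            ((a + L - sub) % n, b),        # suffix of A / prefix of B
        ):
            if _circ_disjoint(aa, bb, sub, n):
                return (aa, bb, sub)
    return None


def detect_inverted_repeat(
    sequence: str,
    min_len: int = 1000,
    require_rrn: list[GeneFeature] | None = None,
    genome_id: str = "",
) -> QuadripartiteStructure | None:
    """Find the maximal pair of disjoint exact reverse-complement segments.

    Returns ``None`` when no candidate of at least ``min_len`` exists.  When
    ``require_rrn`` is given, only candidates whose two copies jointly
    contain every listed rRNA feature span qualify, and the rRNA-operon
    orientation relative to the SSC is reported.
    """
    if not sequence:
        raise GenomeParseError(f"{genome_id}: sequence absent")
    seq = sequence.upper()
    n = len(seq)

    candidates = []
    for a, b, L in _maximal_rc_pairs(seq, min_len):
        if not _circ_disjoint(a, b, L, n):
            trimmed = _trim_to_disjoint(a, b, L, n)
            if trimmed is None or trimmed[2] < min_len:
                continue
            a, b, L = min(trimmed[0], trimmed[1]), max(trimmed[0], trimmed[1]), trimmed[2]
        candidates.append((a, b, L))

    def qualifies(a: int, b: int, L: int) -> bool:
        if not require_rrn:
            return True
        quad = _build_quad(a, b, L, n)
        for f in require_rrn:
            begin, ext = f.extent(n)
            span = (begin, begin + ext)
            if not (quad.contains(span, "ira") or quad.contains(span, "irb")):
                return False
        return True

    candidates = [c for c in candidates if qualifies(*c)]
    if not candidates:
        return None
    # maximal length, ties broken by smallest IRa start
    L_best = max(c[2] for c in candidates)
    a, b, L = min((c for c in candidates if c[2] == L_best), key=lambda c: c[0])
    quad = _build_quad(a, b, L, n)
    if require_rrn:
        quad.rrn_orientation = _rrn_orientation(quad, require_rrn)
    return quad


def _build_quad(a: int, b: int, L: int, n: int) -> QuadripartiteStructure:
    gap1 = ((a + L) % n, (a + L) % n + (b - (a + L)) % n)  # after IRa
    gap2 = ((b + L) % n, (b + L) % n + (a - (b + L)) % n)  # after IRb
    len1 = gap1[1] - gap1[0]
    len2 = gap2[1] - gap2[0]
    lsc, ssc = (gap1, gap2) if len1 >= len2 else (gap2, gap1)
    return QuadripartiteStructure(
        ira=(a, a + L), irb=(b, b + L), lsc=lsc, ssc=ssc,
        ir_length=L, genome_length=n)


def _rrn_orientation(quad: QuadripartiteStructure, rrn: list[GeneFeature]) -> str:
    """Direction of rRNA-operon transcription relative to the SSC."""
    n = quad.genome_length
    ref = None
    for f in rrn:
        if f.base_name == "rrs":
            ref = f
            break
    if ref is None and rrn:
        ref = rrn[0]
    if ref is None:
        return "absent"
    mid = ref.midpoint(n)
    region = quad.region_of(mid)
    if region not in ("IRa", "IRb"):
        return "absent"
    copy = quad.ira if region == "IRa" else quad.irb
    # +1 strand transcribes toward increasing coordinates, i.e. toward the
    # region that follows this IR copy on the circle.
    downstream = quad.region_of(copy[1] % n) if ref.strand == 1 else \
        quad.region_of((copy[0] - 1) % n)
    return "toward_ssc" if downstream == "SSC" else "toward_lsc"


# ---------------------------------------------------------------------------
# Coverage metrics


def intergenic_fraction(genome: ChloroGenome) -> float:
    """Percent of the genome not covered by conserved-gene features.

    Feature intervals cover exons plus introns, so introns count as genic;
    free-standing ORFs are non-conserved and therefore count as intergenic.
    Overlapping features are counted once.
    """
    covered = np.zeros(genome.length, dtype=bool)
    for f in genome.features:
        if not f.conserved:
            continue
        for s, e in f.intervals:
            covered[s:e] = True
    return round_half_up(100.0 * (1.0 - covered.mean()), 1)


def collapse_ir(sequence: str, quad: QuadripartiteStructure) -> str:
    """Working sequence with the IRb copy spliced out."""
    n = len(sequence)
    s, e = quad.irb
    if e <= n:
        return sequence[:s] + sequence[e:]
    return sequence[e % n : s]


def repeat_fraction(
    sequence: str,
    quad: QuadripartiteStructure | None = None,
    min_len: int = 30,
) -> float:
    """Percent of the (IR-collapsed) sequence covered by repeats >= min_len.

    A base is masked when it lies inside a maximal exact repeat of at least
    ``min_len`` bases occurring elsewhere in forward or reverse-complement
    (palindromic) orientation; equivalently, when some ``min_len``-window
    containing it has a second (forward or palindromic) occurrence.
    """
    seq = sequence.upper()
    if quad is not None:
        seq = collapse_ir(seq, quad)
    n = len(seq)
    if n < min_len:
        return 0.0
    k = min_len
    ext = seq + seq[: k - 1]
    pos: dict[str, list[int]] = defaultdict(list)
    for i in range(n):
        pos[ext[i : i + k]].append(i)

    masked = np.zeros(n, dtype=bool)
    for i in range(n):
        km = ext[i : i + k]
        repeated = len(pos[km]) > 1
        if not repeated:
            rc_hits = pos.get(revcomp(km), [])
            repeated = any(j != i for j in rc_hits)
        if repeated:
            if i + k <= n:
                masked[i : i + k] = True
            else:
                masked[i:] = True
                masked[: i + k - n] = True
    return round_half_up(100.0 * masked.mean(), 1)


def partition_conformity(
    genome: ChloroGenome,
    quad: QuadripartiteStructure,
    reference_partition: dict[str, str],
) -> float | None:
    """Fraction of conserved genes found in their reference compartment.

    ``reference_partition`` maps gene names to {LSC, SSC, IR}; genes absent
    from the reference are skipped.  Returns None when no gene overlaps the
    reference (undefined).
    """
    if quad is None:
        raise ValueError("quadripartite structure required")
    seen: dict[str, bool] = {}
    for f in genome.features:
        if not f.conserved:
            continue
        ref = reference_partition.get(f.base_name)
        if ref is None:
            continue
        ok = quad.compartment_of(f) == ref
        # a gene matching in any copy/occurrence counts as conforming
        seen[f.base_name] = seen.get(f.base_name, False) or ok
    if not seen:
        return None
    return sum(seen.values()) / len(seen)


# ---------------------------------------------------------------------------


@dataclass
class GenomeMetrics:
    """Architecture summary of one genome (sizes in bp, percentages 0-100)."""

    genome_id: str
    total_bp: int
    ir_bp: int
    at_pct: float | None
    n_genes: int
    n_gene_occurrences: int
    intergenic_pct: float
    repeat_pct: float | None


def genome_metrics(
    genome: ChloroGenome,
    ir_min_len: int = 1000,
    repeat_min_len: int = 30,
) -> GenomeMetrics:
    """Assemble the standard architecture metrics for one genome.

    Sequence-dependent metrics (A+T%, IR, repeats) are None/0 when the
    record carries no sequence.
    """
    occurrences = [f for f in genome.features if f.conserved]
    quad = None
    at = rep = None
    if genome.sequence is not None:
        rrn = [f for f in occurrences if f.category == "rRNA"]
        quad = detect_inverted_repeat(
            genome.sequence, min_len=ir_min_len,
            require_rrn=rrn or None, genome_id=genome.id)
        at = at_content(genome.sequence)
        rep = repeat_fraction(genome.sequence, quad, min_len=repeat_min_len)
    return GenomeMetrics(
        genome_id=genome.id,
        total_bp=genome.length,
        ir_bp=quad.ir_length if quad else 0,
        at_pct=at,
        n_genes=genome.n_genes,
        n_gene_occurrences=len(occurrences),
        intergenic_pct=intergenic_fraction(genome),
        repeat_pct=rep,
    )
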