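import numpy as np
import pytest

from plastarch.architecture import (
    at_content,
    detect_inverted_repeat,
    genome_metrics,
    intergenic_fraction,
    partition_conformity,
    repeat_fraction,
    revcomp,
)
from plastarch.genome_io import GenomeParseError

from .conftest import make_feature, make_genome, random_seq, rc
from .oracles import ir_oracle_best, masked_fraction


class TestATContent:
    def test_pure_at_and_gc(self):
        assert at_content("ATAT") == 100.0
        assert at_content("GCGC") == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            at_content("")

    def test_matches_independent_tally(self):
        rng = np.random.default_rng(42)
        seq = random_seq(rng, 10_000)
        counts = {b: 0 for b in "ACGT"}
        for b in seq:
            counts[b] += 1
        expected = 100.0 * (counts["A"] + counts["T"]) / sum(counts.values())
        assert at_content(seq) == pytest.approx(expected, abs=0.05)

    def test_at_plus_gc_is_100(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 5000)
        s = seq.upper()
        gc = 100.0 * (s.count("G") + s.count("C")) / len(s)
        assert at_content(seq) + gc == pytest.approx(100.0, abs=0.06)

    def test_n_excluded_from_denominator(self):
        assert at_content("ATNN") == 100.0


def plant_ir(rng, n, ir_len, ira_start, irb_start):
    """Random circular sequence with an exact planted IR; flanks are fixed
    so the planted repeat cannot extend by chance."""
    seq = list(random_seq(rng, n))
    copy = random_seq(rng, ir_len)
    seq[ira_start:ira_start + ir_len] = copy
    seq[irb_start:irb_start + ir_len] = rc(copy)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    def pin(p, q):
        if comp[seq[p % n]] == seq[q % n]:
            seq[p % n] = "A" if comp["A"] != seq[q % n] else "C"

    pin(ira_start - 1, irb_start + ir_len)
    pin(ira_start + ir_len, irb_start - 1)
    return "".join(seq)


class TestInvertedRepeat:
    def test_random_sequence_has_no_large_ir(self):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 20_000)
        assert detect_inverted_repeat(seq, min_len=1000) is None

    def test_planted_5kb_ir_recovered_exactly(self):
        rng = np.random.default_rng(6)
        seq = plant_ir(rng, 50_000, 5000, ira_start=10_000, irb_start=30_000)
        quad = detect_inverted_repeat(seq, min_len=1000)
        assert quad is not None
        assert quad.ir_length == 5000
        assert quad.ira == (10_000, 15_000)
        assert quad.irb == (30_000, 35_000)
        # the two SC regions partition the rest of the circle
        assert (quad.lsc[1] - quad.lsc[0]) + (quad.ssc[1] - quad.ssc[0]) == 40_000

    def test_ir_copies_are_reverse_complements(self):
        rng = np.random.default_rng(7)
        seq = plant_ir(rng, 20_000, 2000, ira_start=2000, irb_start=12_000)
        quad = detect_inverted_repeat(seq, min_len=500)
        s1, e1 = quad.ira
        s2, e2 = quad.irb
        assert seq[s1:e1] == rc(seq[s2:e2])

    def test_sequence_absent_errors(self):
        with pytest.raises(GenomeParseError):
            detect_inverted_repeat("", min_len=100)

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_quadratic_oracle(self, seed):
        """Seed-and-extend equals the anti-diagonal brute-force scan on
        small circles, with and without planted repeats."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(300, 600))
        if seed % 3 == 0:
            seq = random_seq(rng, n)
        else:
            ir_len = int(rng.integers(40, 90))
            a = int(rng.integers(0, n // 4))
            b = int(rng.integers(n // 2, 3 * n // 4))
            seq = plant_ir(rng, n, ir_len, a, b)
        got = detect_inverted_repeat(seq, min_len=30)
        want = ir_oracle_best(seq, min_len=30)
        if want is None:
            assert got is None
        else:
            assert got is not None
            assert got.ir_length == want[2]
            assert (got.ira[0], got.irb[0]) == (want[0], want[1])


class TestIntergenicFraction:
    def test_fully_tiled_and_empty(self):
        g1 = make_genome("a", 1000, [make_feature("psbA", 0, 1000)])
        assert intergenic_fraction(g1) == 0.0
        g2 = make_genome("b", 1000, [])
        assert intergenic_fraction(g2) == 100.0

    def test_overlapping_genes_counted_once(self):
        g = make_genome("c", 1000, [
            make_feature("psbA", 100, 500),
            make_feature("psbB", 400, 700),
        ])
        assert intergenic_fraction(g) == 40.0

    def test_orfs_count_as_intergenic(self):
        g = make_genome("d", 1000, [
            make_feature("orf999", 0, 600, conserved=False, category="orf"),
            make_feature("psbA", 600, 800),
        ])
        assert intergenic_fraction(g) == 80.0

    def test_monotone_under_feature_addition(self):
        rng = np.random.default_rng(9)
        feats = []
        last = 100.0
        for i in range(20):
            s = int(rng.integers(0, 1900))
            e = s + int(rng.integers(10, 100))
            feats.append(make_feature(f"g{i}", s, min(e, 2000)))
            cur = intergenic_fraction(make_genome("m", 2000, feats))
            assert cur <= last
            last = cur

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(10)
        feats = [make_feature(f"g{i}", int(s), int(s) + 50)
                 for i, s in enumerate(rng.integers(0, 950, size=8))]
        g = make_genome("e", 1000, feats)
        mask = np.zeros(1000, dtype=bool)
        for f in feats:
            for s, e in f.intervals:
                mask[s:e] = True
        assert intergenic_fraction(g) == pytest.approx(
            100.0 * (1 - mask.mean()), abs=0.05)


class TestRepeatFraction:
    def test_short_sequence_is_zero(self):
        assert repeat_fraction("ACGT", min_len=30) == 0.0

    def test_random_sequence_is_zero(self):
        rng = np.random.default_rng(11)
        assert repeat_fraction(random_seq(rng, 10_000), min_len=30) == 0.0

    def test_planted_forward_duplicate(self):
        rng = np.random.default_rng(12)
        seq = list(random_seq(rng, 10_000))
        seq[500:600] = seq[5000:5100]
        frac = repeat_fraction("".join(seq), min_len=30)
        assert frac == 2.0  # 200 of 10,000 bases masked

    def test_planted_palindromic_repeat(self):
        rng = np.random.default_rng(13)
        seq = list(random_seq(rng, 10_000))
        seq[7000:7100] = rc("".join(seq[1000:1100]))
        assert repeat_fraction("".join(seq), min_len=30) == 2.0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(14)
        seq = list(random_seq(rng, 3000))
        seq[100:160] = seq[2000:2060]
        seq = "".join(seq)
        base = repeat_fraction(seq, min_len=30)
        for shift in (1, 500, 1499):
            rotated = seq[shift:] + seq[:shift]
            assert repeat_fraction(rotated, min_len=30) == base

    def test_matches_bruteforce_kmer_scan(self):
        rng = np.random.default_rng(15)
        seq = list(random_seq(rng, 1200))
        seq[100:150] = seq[700:750]
        seq = "".join(seq)
        assert repeat_fraction(seq, min_len=30) == pytest.approx(
            masked_fraction(seq, 30), abs=0.05)

    def test_ir_collapsed_before_scanning(self):
        """With the quadripartite structure supplied, the IR itself does
        not count as repeated sequence."""
        rng = np.random.default_rng(16)
        seq = plant_ir(rng, 30_000, 3000, ira_start=5000, irb_start=20_000)
        quad = detect_inverted_repeat(seq, min_len=1000)
        assert quad is not None
        assert repeat_fraction(seq, quad, min_len=30) == 0.0
        assert repeat_fraction(seq, None, min_len=30) >= 19.0


class TestPartitionConformity:
    def _genome_with_quad(self, relocate=0):
        rng = np.random.default_rng(17)
        seq = plant_ir(rng, 30_000, 3000, ira_start=10_000, irb_start=20_000)
        quad = detect_inverted_repeat(seq, min_len=1000)
        feats = []
        ref = {}
        # 27 genes in LSC (the long gap), 3 relocatable to SSC
        for i in range(30):
            name = f"g{i}"
            ref[name] = "LSC"
        for i in range(30):
            if i < relocate:
                start = 13_100 + i * 300  # inside the SSC gap [13000, 20000)
            else:
                start = 100 + i * 300     # inside the wrapping LSC gap
            feats.append(make_feature(f"g{i}", start, start + 200))
        g = make_genome("pq", 30_000, feats, sequence=seq)
        return g, quad, ref

    def test_perfect_layout(self):
        g, quad, ref = self._genome_with_quad(relocate=0)
        assert partition_conformity(g, quad, ref) == 1.0

    def test_three_of_thirty_relocated(self):
        g, quad, ref = self._genome_with_quad(relocate=3)
        assert partition_conformity(g, quad, ref) == pytest.approx(0.9)

    def test_disjoint_reference_is_undefined(self):
        g, quad, _ = self._genome_with_quad()
        assert partition_conformity(g, quad, {"zzz": "LSC"}) is None

    def test_missing_quad_errors(self):
        g, _, ref = self._genome_with_quad()
        with pytest.raises(ValueError):
            partition_conformity(g, None, ref)


def test_genome_metrics_assembles_consistent_summary(sim_clade):
    _, ancestor, _ = sim_clade
    m = genome_metrics(ancestor)
    assert m.total_bp == ancestor.length
    assert m.ir_bp > 0
    assert 0 <= m.at_pct <= 100
    assert 0 <= m.intergenic_pct <= 100
    assert 0 <= m.repeat_pct <= 100
    assert m.n_genes <= m.n_gene_occurrences
    assert m.ir_bp <= m.total_bp / 2
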