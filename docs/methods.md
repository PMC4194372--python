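# Methods

## Coordinates, names and the conserved-gene catalog

All coordinates are 0-based half-open on the circular genome; GenBank
1-based closed locations are converted on read. A feature wrapping the
origin is stored as two spans `[s, L) + [0, e)`; its circular midpoint,
which orders the signed gene sequence, is `(begin + extent/2) mod L`.

Cross-genome comparison needs a controlled vocabulary, so a conserved-gene
catalog (137 genes: proteins, rrs/rrl/rrf, and tRNAs named
`trn<AA>-<anticodon>`) and a synonym table (`rrn16→rrs`, `ycf9→psbZ`,
`trnfM→trnMf-cau`, …) ship as package data. The catalog is a curated
union of the ~75-gene green-algal core, the eleven ndh genes, and genes
with sporadic distributions across prasinophyte and deep-branching
streptophyte plastomes (ndhJ, rbcR, rpl21, rps15, rps16, ycf66, ftsI,
ftsW, rpl22, ycf65, accD, cemA, tilS, rne, rnpB, ycf20, …). Unknown
symbols pass through lowercased and flagged non-conserved; free-standing
ORFs are parsed but never count as conserved, so they are excluded from
gene counts, pair/block analysis, and the genic cover. Fragments of
trans-spliced or split genes (ycf3a/ycf3b, rps12 parts) are separate
gene-order elements but collapse onto one base name for repertoire
purposes.

Gene and CDS/RNA records describing the same locus (same normalized name,
overlapping circular extents) merge into one feature spanning exons and
introns; disjoint same-name records (IR duplicates, duplicated tRNAs)
stay separate occurrences.

## Architecture metrics

- **A+T%**: `100·(A+T)/(A+C+G+T)`, N excluded. All percentages are
  rounded half-up to one decimal (synteny percentages to integers).
- **Gene counts**: `n_genes` counts unique conserved base names once;
  `n_gene_occurrences` includes IR duplicates and duplicated tRNAs.
- **Intergenic fraction**: percent of the circle not covered by conserved
  features, introns counted genic and ORFs intergenic, overlaps counted
  once. The published per-genome values do not state their exact
  genic/ORF convention, so this is a documented default; only
  internal-consistency invariants (bounds, monotonicity under feature
  addition, per-base oracle equivalence) are asserted about it.
- **Repeat fraction**: REPuter-style masking. On the working sequence
  (one IR copy spliced out when the quadripartite structure is known), a
  base is masked when it lies in a maximal exact repeat ≥ 30 bp with a
  second occurrence in forward or reverse-complement (palindromic)
  orientation. This is computed by marking every circular 30-mer window
  with a second (forward or palindromic) occurrence — equivalent to
  masking all maximal repeats ≥ 30 bp, because every window of such a
  repeat recurs and every recurring window lies in one. The union of
  overlapping maximal repeats is masked once. Removing one IR copy first
  reflects the convention under which an IR-bearing genome can report 0%
  repeats.

## Inverted-repeat detection

Detection is exact (mismatch tolerance 0): published IR sizes are single
integers, implying an exact repeat, and near-identical-copy handling is
out of scope. Candidate pairs are found by seeding on k-mers
(k = min(min_len, 20)) that match the reverse complement elsewhere on the
circle, extending each anchor maximally in both directions, and keeping
pairs ≥ `min_len` (default 1000 bp). The result is the maximal-length
pair of *disjoint* segments, ties broken by smallest IRa start; an
overlapping maximal extension is trimmed from matched ends to its largest
disjoint sub-pair (a prefix of one copy pairs with the same-length suffix
of the other). When rRNA features are supplied, only candidates whose two
copies jointly contain every rRNA span qualify, and the rRNA-operon
orientation is reported as transcription toward the SSC or LSC, read from
the strand of rrs within its copy. The two gaps between the copies are
the single-copy regions, the longer being the LSC. A quadratic
anti-diagonal brute-force scan serves as the independent oracle in tests.

## Signed gene order and colinear blocks

Orders are extracted from conserved features sorted by circular midpoint,
signs from coding strand; by default one IR copy (IRb) is dropped first,
because comparison maps draw the IR once. Adjacencies are canonicalized
under the reverse-reading symmetry. For block detection, both orders are
reduced to genes occurring exactly once in each (duplicates are skipped
with a warning). An adjacency of genome 1 is preserved in genome 2 when
the two genes are consecutive there (up to `max_gap` intervening genes,
default 0) with the same relative signs, directly or reversed-and-
flipped. Blocks are the maximal circular runs of preserved adjacencies —
with unique gene occurrences this equals the maximal common circular
signed substrings, which the brute-force oracle enumerates directly.
Runs below `min_len` (default 2: single shared genes are not blocks) are
discarded. Synteny percentages divide unique block genes by each
genome's unique conserved gene count, rounded half-up to integers;
ties for the largest block resolve to the first by genome-1 position.
The published block counts came from an unpublished program whose gap
tolerance is unknown; `min_len`, `max_gap` and IR collapsing are exposed
as configuration for that reason.

Ancestral-pair selection over a panel applies two rules: (A) the pair is
present in ≥ 2 ingroup lineages and ≥ 1 outgroup; (B) a member gene is
absent from ≥ 2 ingroup lineages or from both outgroups, and the pair
survives in ≥ 1 ingroup lineage. Absent cells are split into
"absent_gene_loss" (a member gene missing from that genome's repertoire)
versus "absent_rearranged".

## Dollo parsimony

Characters are binary per leaf. Pseudogenes count as absent by default
(a pseudogene is a loss in progress) but are preserved in reports and can
be toggled. The gain is placed at the root for ancestral characters
(present in an outgroup) and at the LCA of the present leaves otherwise.
The minimal loss set for a single-gain model is the set of edges above
maximal all-absent subtrees strictly below the gain; on a polytomy each
lost child subtree is its own event. Exhaustive search over edge subsets
is the test oracle (all rooted 6-leaf topologies × all presence
patterns). For the real study system the package ships the fixed
12-taxon species topology and curated character states (IR presence; the
six Prasinococcales-specific genes). Note one annotation tension: the
ndh operon is described as wholly absent from *Prasinoderma* in one
summary sentence, but the two-loss ndhJ scenario (one loss after the
Prasinococcales split, one on the MBIC 10622 branch) requires ndhJ in
*Prasinoderma*; the curated state follows the explicit loss scenario.

## Simulator

The generator emulates the study conditions: defaults of 110 conserved
genes, ~100 kb, A+T 62%, intergenic 15%, a 12 kb IR containing the rRNA
operon — mid-range values of the compared genomes (64–200 kb, 86–128
genes, A+T 58–68%, intergenic 9–46%). Protein gene lengths are drawn
uniformly (300–1800 bp) then scaled to hit the genome-size target;
rRNA/tRNA lengths are fixed at biological values; spacers are a Dirichlet
split of the budget implied by the intergenic target. Sequence is i.i.d.
with the A+T bias — no codon structure or substitution model, since the
pipeline never translates. The four bases flanking the planted IR copies
are pinned non-complementary so the planted repeat ends exactly at its
boundaries.

Evolution applies, per branch in preorder: `n_losses` gene losses
(uniform over currently present eligible genes), IR loss with probability
`p_ir_loss` (deletion of one copy — the copy-correction view, matching
how IR loss manifests as a blank IR column with genes retained once),
then `n_inversions` segment inversions. Breakpoints are sampled from
intergenic positions only (features are never split); segments must
contain at least one but not all features, and must contain both IR
copies or neither — flipping exactly one copy would silently convert the
IR into a direct repeat. rRNA genes and IR-resident genes are not
eligible for loss (IR content changes only through IR loss). Every event
is logged with exact coordinates; replaying the log through the same
editing primitives reproduces each leaf byte-for-byte, which the tests
assert.

What the simulator does *not* emulate: nucleotide substitution, intron
gain/loss, IR boundary expansion/contraction, duplicated tRNAs outside
the IR, and horizontally acquired ORFs. Passing tests therefore
demonstrate correctness of the comparative machinery on rearrangement-
and-loss histories, not robustness to annotation noise or near-identical
repeats in real records.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the block engine against
exhaustive enumeration for circles of ≤ 6 genes plus 1000 seeded random
cases of 7–12 genes; the Dollo engine against brute force on all 945
rooted 6-leaf topologies × all 64 presence patterns; and 100 seeded
planted-truth replicates for IR/repeat recovery. Simulated study clades
use 12 leaves at 20–100 kb. All randomness flows from explicit seeds;
reports and simulator outputs are byte-deterministic for fixed inputs.

## Known limitations

- Exact-match IR detection misses diverged (mismatched) IR copies.
- Block detection with `max_gap > 0` uses per-adjacency gap tolerance;
  chains are not re-validated globally, so very large gap values can link
  runs a stricter definition would split.
- The accession-level checks need the GenBank records on disk; they are
  not redistributed with the package.
- With `max_gap = 0` the block decomposition is a partition of the shared
  single-copy genes; published counts from other tools may bundle
  IR-resident genes differently (`--collapse-ir` switches the handling).
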