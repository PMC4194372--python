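"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive each quantity by exhaustive enumeration or
direct scanning, sharing no code with the implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# Inverted repeats


def ir_oracle_pairs(seq: str, min_len: int):
    """All maximal circular reverse-complement segment pairs >= min_len,
    found by scanning every anti-diagonal of the match matrix."""
    n = len(seq)
    pairs = set()
    for a in range(n):
        for b in range(n):
            # run starting at (a, b): A grows right from a, B grows left from b
            if COMP.get(seq[a]) != seq[b]:
                continue
            # maximal start: predecessor cell must mismatch
            if COMP.get(seq[(a - 1) % n]) == seq[(b + 1) % n]:
                continue
            L = 0
            while L < n and COMP.get(seq[(a + L) % n]) == seq[(b - L) % n]:
                L += 1
            if L >= min_len:
                s1, s2 = a, (b - L + 1) % n
                key = (min(s1, s2), max(s1, s2), L)
                pairs.add(key)
    return pairs


def circ_disjoint(a: int, b: int, L: int, n: int) -> bool:
    if a == b or 2 * L > n:
        return False
    return (b - (a + L)) % n + (a - (b + L)) % n == n - 2 * L


def ir_oracle_best(seq: str, min_len: int):
    """(ira_start, irb_start, length) of the maximal disjoint pair, or None."""
    n = len(seq)
    best = None
    for a, b, L in ir_oracle_pairs(seq, min_len):
        cands = []
        if circ_disjoint(a, b, L, n):
            cands.append((a, b, L))
        else:
            for sub in range(L - 1, min_len - 1, -1):
                done = False
                for aa, bb in ((a, (b + L - sub) % n), ((a + L - sub) % n, b)):
                    if circ_disjoint(aa, bb, sub, n):
                        cands.append((min(aa, bb), max(aa, bb), sub))
                        done = True
                if done:
                    break
        for cand in cands:
            if best is None or (cand[2], -cand[0]) > (best[2], -best[0]):
                best = cand
    return best


# ---------------------------------------------------------------------------
# Repeated 30-mers


def repeated_positions(seq: str, k: int) -> set[int]:
    """Positions whose circular k-mer occurs elsewhere forward or as a
    reverse complement, by direct all-vs-all comparison."""
    n = len(seq)
    if n < k:
        return set()
    ext = seq + seq[: k - 1]
    kmers = [ext[i : i + k] for i in range(n)]
    rcs = ["".join(COMP[c] for c in reversed(w)) for w in kmers]
    out = set()
    for i in range(n):
        for j in range(n):
            if j != i and kmers[j] == kmers[i]:
                out.add(i)
                break
            if j != i and rcs[j] == kmers[i]:
                out.add(i)
                break
    return out


def masked_fraction(seq: str, k: int) -> float:
    n = len(seq)
    mask = [False] * n
    for p in repeated_positions(seq, k):
        for t in range(k):
            mask[(p + t) % n] = True
    return 100.0 * sum(mask) / n


# ---------------------------------------------------------------------------
# Signed circular common substrings (synteny blocks)


def block_oracle(r1, r2):
    """Gene sets of all maximal common circular signed substrings of two
    circular signed sequences (direct or reversed-and-flipped)."""
    n = len(r1)
    fwd = list(r2)
    rev = [(name, -sign) for name, sign in reversed(r2)]
    m = len(r2)
    substrings = set()
    for reading in (fwd, rev):
        doubled = reading + reading
        for i in range(m):
            for L in range(1, m + 1):
                substrings.add(tuple(doubled[i : i + L]))

    def is_common(s, L):
        return tuple(r1[(s + t) % n] for t in range(L)) in substrings

    cand = {(s, L) for s in range(n) for L in range(1, n + 1) if is_common(s, L)}
    maximal = set()
    for s, L in cand:
        if L < n and (((s - 1) % n, L + 1) in cand or (s, L + 1) in cand):
            continue
        maximal.add(frozenset(r1[(s + t) % n][0] for t in range(L)))
    return maximal


# ---------------------------------------------------------------------------
# Dollo minimal losses


def leafset(subtree):
    """Leaves of a nested-tuple tree."""
    if not isinstance(subtree, tuple):
        return frozenset([subtree])
    out = frozenset()
    for child in subtree:
        out |= leafset(child)
    return out


def subtrees(tree):
    """All proper subtrees (each standing for the edge above it)."""
    out = []
    if isinstance(tree, tuple):
        for child in tree:
            out.append(child)
            out.extend(subtrees(child))
    return out


def all_rooted_trees(leaves):
    """Every rooted binary topology on a list of labels, as nested tuples."""
    if len(leaves) == 1:
        return [leaves[0]]
    first, rest = leaves[0], leaves[1:]
    out = []
    for r in range(len(rest)):
        for others in combinations(rest, r):
            left_labels = [first, *others]
            right_labels = [l for l in rest if l not in others]
            if not right_labels:
                continue
            for lt in all_rooted_trees(left_labels):
                for rt in all_rooted_trees(right_labels):
                    out.append((lt, rt))
    return out


def to_newick(tree) -> str:
    if not isinstance(tree, tuple):
        return tree
    return "(" + ",".join(to_newick(c) for c in tree) + ")"


def dollo_oracle(tree, present: frozenset, gain_policy: str) -> int:
    """Minimum number of loss edges for a single-gain model, by exhaustive
    search over edge subsets of increasing size."""
    if gain_policy == "root":
        gain = tree
    else:
        # smallest subtree containing all present leaves
        gain = tree
        changed = True
        while changed and isinstance(gain, tuple):
            changed = False
            for child in gain:
                if present <= leafset(child):
                    gain = child
                    changed = True
                    break
    absent = leafset(gain) - present
    edges = subtrees(gain)
    edge_leaves = [leafset(e) for e in edges]
    for k in range(0, len(edges) + 1):
        for combo in combinations(range(len(edges)), k):
            lost = frozenset().union(*(edge_leaves[i] for i in combo)) \
                if combo else frozenset()
            if lost == absent:
                return k
    raise AssertionError("unreachable: losing every leaf edge explains any pattern")
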