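"""Controlled vocabulary of conserved chloroplast genes and name normalization.

Plastid annotations are notoriously inconsistent in how they spell gene
symbols (``rrn16`` vs ``rrs``, ``trnL(UAA)`` vs ``trnL-uaa``, ``ycf9`` vs
``psbZ``).  Cross-genome repertoire and gene-order comparison requires a
controlled vocabulary, so a curated catalog of conserved genes and a synonym
table ship with the package as data.  Unknown names pass through lowercased
and are flagged non-conserved.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

__all__ = [
    "Catalog",
    "default_catalog",
    "normalize_name",
    "split_part_suffix",
    "FRAGMENTED_GENES",
]

# Genes known to occur as separately encoded fragments (trans-spliced or
# split loci).  A trailing single-letter suffix on these base names is
# treated as a part label, e.g. ycf3a / ycf3b.
FRAGMENTED_GENES = frozenset({"ycf3", "rps12"})

_TRNA_RE = re.compile(
    r"^trn(?P<aa>[A-Za-z]{1,2})\s*[-_(]?\s*(?P<ac>[acgunACGUN]{3})?\)?$"
)
_ORF_RE = re.compile(r"^orf\s*_?(?P<num>\d+[a-z]?)$", re.IGNORECASE)


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files("plastarch.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


class Catalog:
    """Conserved-gene catalog: canonical names, categories, synonyms."""

    def __init__(self, genes: dict[str, str], synonyms: dict[str, str] | None = None):
        #: canonical name -> category ({protein, tRNA, rRNA, other})
        self.genes = dict(genes)
        self.synonyms = dict(synonyms or {})
        self._lower = {g.lower(): g for g in self.genes}
        self._syn_lower = {s.lower(): c for s, c in self.synonyms.items()}

    def __contains__(self, name: str) -> bool:
        return self.canonical(name) is not None

    def __len__(self) -> int:
        return len(self.genes)

    def canonical(self, name: str) -> str | None:
        """Canonical catalog spelling for *name* (or its base name), else None."""
        key = name.lower()
        key = self._syn_lower.get(key, key).lower()
        hit = self._lower.get(key)
        if hit is not None:
            return hit
        base, part = split_part_suffix(key)
        if part is not None:
            return self._lower.get(base)
        return None

    def category(self, name: str) -> str:
        canon = self.canonical(name)
        if canon is not None:
            return self.genes[canon]
        return infer_category(name)

    def names(self, category: str | None = None) -> list[str]:
        if category is None:
            return sorted(self.genes)
        return sorted(g for g, c in self.genes.items() if c == category)


@lru_cache(maxsize=1)
def default_catalog() -> Catalog:
    genes = {name: cat for name, cat in _read_tsv("conserved_genes.tsv")}
    synonyms = {syn: canon for syn, canon in _read_tsv("gene_synonyms.tsv")}
    return Catalog(genes, synonyms)


def split_part_suffix(name: str) -> tuple[str, str | None]:
    """Split a part label off a fragmented-gene name: ycf3a -> (ycf3, a)."""
    for base in FRAGMENTED_GENES:
        if name.lower().startswith(base) and len(name) == len(base) + 1:
            suffix = name[-1].lower()
            if suffix.isalpha():
                return base, suffix
    return name, None


def infer_category(name: str) -> str:
    low = name.lower()
    if low.startswith("trn"):
        return "tRNA"
    if low in ("rrs", "rrl", "rrf") or low.startswith("rrn"):
        return "rRNA"
    if _ORF_RE.match(low):
        return "orf"
    return "protein"


def normalize_name(raw: str, catalog: Catalog | None = None) -> tuple[str, str, bool]:
    """Normalize a raw annotation symbol.

    Returns ``(name, category, conserved)``.  tRNAs become
    ``trn<AA>-<anticodon>`` with a lowercase anticodon, rRNAs map onto
    rrs/rrl/rrf, synonyms collapse onto catalog spellings, free-standing
    ORFs become ``orfNNN``; anything unrecognized is lowercased and flagged
    non-conserved.  Idempotent.
    """
    if catalog is None:
        catalog = default_catalog()
    name = raw.strip()
    if not name:
        raise ValueError("empty gene name")

    m = _ORF_RE.match(name)
    if m:
        return f"orf{m.group('num').lower()}", "orf", False

    m = _TRNA_RE.match(name)
    if m:
        aa = m.group("aa")
        if aa.lower() == "fm":
            aa = "Mf"
        aa = aa[0].upper() + aa[1:].lower()
        ac = m.group("ac")
        if ac:
            cand = f"trn{aa}-{ac.lower().replace('t', 'u')}"
        else:
            cand = f"trn{aa}"
        canon = catalog.canonical(cand)
        if canon is not None:
            return canon, "tRNA", True
        return cand, "tRNA", False

    canon = catalog.canonical(name)
    if canon is not None:
        base, part = split_part_suffix(name.lower())
        if part is not None and canon.lower() == base:
            # keep the part label on the feature name; conservation follows
            # the base gene
            return base + part, catalog.genes[canon], True
        return canon, catalog.genes[canon], True
    return name.lower(), infer_category(name), False
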