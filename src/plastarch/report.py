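"""Study-level report: architecture table, pairwise synteny, core genes and
Dollo loss counts for a set of genomes, written as deterministic TSV/JSON."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from . import __version__
from .architecture import detect_inverted_repeat, genome_metrics
from .gene_order import colinear_blocks, extract_signed_order, synteny_stats
from .genome_io import ChloroGenome, read_gene_order_tsv, read_genome_record
from .repertoire import build_presence_matrix, core_genes, dollo_table

logger = logging.getLogger("plastarch")

__all__ = ["StudyConfig", "StudyReport", "run_study", "load_genome_dir"]


@dataclass(frozen=True)
class StudyConfig:
    """Conventions that the convention-sensitive numbers depend on."""

    min_len: int = 2          # minimum genes per colinear block
    max_gap: int = 0          # intervening genes tolerated inside a block
    collapse_ir: bool = True  # drop the IRb copy before order extraction
    ir_min_len: int = 1000
    repeat_min_len: int = 30
    pseudogene_as_present: bool = False

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class StudyReport:
    metrics: pd.DataFrame
    synteny: pd.DataFrame
    core: list[str]
    losses: pd.DataFrame | None
    provenance: dict
    failures: dict[str, str] = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "metrics.tsv", sep="\t")
        self.synteny.to_csv(outdir / "synteny.tsv", sep="\t")
        if self.losses is not None:
            self.losses.to_csv(outdir / "losses.tsv", sep="\t")
        payload = {
            "core_genes": self.core,
            "n_core_genes": len(self.core),
            "provenance": self.provenance,
            "failures": self.failures,
        }
        (outdir / "study.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_genome_dir(path) -> dict[str, ChloroGenome]:
    """Read every .gb/.gbk (GenBank) and .tsv (gene-order) file in a directory."""
    genomes: dict[str, ChloroGenome] = {}
    for p in sorted(Path(path).iterdir()):
        if p.suffix in (".gb", ".gbk", ".genbank"):
            g = read_genome_record(p)
        elif p.suffix == ".tsv":
            g = read_gene_order_tsv(p)
        else:
            continue
        genomes[g.id] = g
    return genomes


def run_study(
    genomes: dict[str, ChloroGenome],
    tree: dendropy.Tree | None = None,
    config: StudyConfig | None = None,
    outgroup_ids: list[str] | None = None,
) -> StudyReport:
    """Compute the full comparative report for a panel of genomes.

    A genome failing one stage is dropped from that table with a logged
    reason, never silently.  The report is deterministic for fixed inputs
    and config.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    config = config or StudyConfig()
    failures: dict[str, str] = {}

    # per-genome metrics
    rows = []
    quads = {}
    for gid in sorted(genomes):
        g = genomes[gid]
        try:
            m = genome_metrics(g, ir_min_len=config.ir_min_len,
                               repeat_min_len=config.repeat_min_len)
            rows.append(asdict(m))
            if g.sequence is not None:
                rrn = [f for f in g.features if f.conserved and f.category == "rRNA"]
                quads[gid] = detect_inverted_repeat(
                    g.sequence, min_len=config.ir_min_len,
                    require_rrn=rrn or None, genome_id=gid)
            else:
                quads[gid] = None
        except Exception as exc:  # noqa: BLE001 - partial-failure policy
            logger.warning("metrics failed for %s: %s", gid, exc)
            failures[f"metrics/{gid}"] = str(exc)
            quads[gid] = None
    metrics = pd.DataFrame(rows).set_index("genome_id") if rows else pd.DataFrame()

    # pairwise synteny
    orders = {}
    for gid in sorted(genomes):
        try:
            collapse = quads.get(gid) if config.collapse_ir else None
            orders[gid] = extract_signed_order(genomes[gid], collapse=collapse)
        except Exception as exc:  # noqa: BLE001
            logger.warning("gene order failed for %s: %s", gid, exc)
            failures[f"order/{gid}"] = str(exc)
    pair_rows = []
    ids = sorted(orders)
    for i, g1 in enumerate(ids):
        for g2 in ids[i + 1:]:
            blocks = colinear_blocks(orders[g1], orders[g2],
                                     min_len=config.min_len, max_gap=config.max_gap)
            stats = synteny_stats(blocks, orders[g1], orders[g2])
            pair_rows.append({
                "genome1": g1, "genome2": g2,
                "n_blocks": stats["n_blocks"],
                "n_block_genes": stats["n_block_genes"],
                "pct_of_g1": stats["pct_of_g1"],
                "pct_of_g2": stats["pct_of_g2"],
                "largest_block_len": len(stats["largest_block"]),
            })
    synteny = pd.DataFrame(pair_rows)

    # repertoires and Dollo
    matrix = build_presence_matrix(list(genomes.values()))
    core = core_genes(matrix, pseudogene_as_present=config.pseudogene_as_present)
    losses = None
    if tree is not None:
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        uncovered = [gid for gid in genomes if gid not in leaves
                     and gid not in (outgroup_ids or [])]
        if uncovered:
            raise ValueError(f"tree leaves do not cover genomes: {uncovered}")
        losses = dollo_table(tree, matrix, outgroup_ids=outgroup_ids,
                             pseudogene_as_present=config.pseudogene_as_present)

    provenance = {
        "plastarch_version": __version__,
        "config": asdict(config),
        "config_hash": config.hash(),
        "n_genomes": len(genomes),
        "genomes": sorted(genomes),
    }
    return StudyReport(metrics=metrics, synteny=synteny, core=core,
                       losses=losses, provenance=provenance, failures=failures)
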