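"""Simulate the study clade and archive its gene orders and event log.

Writes one gene-order TSV per leaf plus the ancestor, the labeled tree,
and the exact per-branch event log under results/simulated_clade/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, study_clade  # noqa: E402

from plastarch.genome_io import write_gene_order_tsv  # noqa: E402


def main():
    cfg, ancestor, clade = study_clade()
    out = RESULTS / "simulated_clade"
    out.mkdir(parents=True, exist_ok=True)
    write_gene_order_tsv(ancestor, out / "ancestor.tsv")
    for gid in sorted(clade.genomes):
        write_gene_order_tsv(clade.genomes[gid], out / f"{gid}.tsv")
    clade.tree.write(path=str(out / "tree.nwk"), schema="newick")
    (out / "events.json").write_text(json.dumps(clade.events, indent=2) + "\n")
    n_loss = sum(1 for e in clade.events if e["event"] == "gene_loss")
    n_inv = sum(1 for e in clade.events if e["event"] == "inversion")
    n_ir = sum(1 for e in clade.events if e["event"] == "ir_loss")
    print(f"simulated {len(clade.genomes)} leaf genomes from a "
          f"{ancestor.length:,} bp / {ancestor.n_genes}-gene ancestor")
    print(f"events: {n_loss} gene losses, {n_inv} inversions, {n_ir} IR losses")
    print(f"IR retained in {sum(clade.ir_present.values())} of "
          f"{len(clade.ir_present)} leaves")


if __name__ == "__main__":
    main()
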