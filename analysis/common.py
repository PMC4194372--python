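"""Shared study conditions for the analysis drivers.

All drivers work on the same deterministic simulated clade: a mid-size
chloroplast-like ancestor (~100 kb, 110 conserved genes, 12 kb IR with the
rRNA operon) evolved along the fixed 12-taxon prasinophyte topology with a
few inversions and gene losses per branch and a 20% chance of losing one
IR copy.
"""

from pathlib import Path

from plastarch.prasinophytes import prasinophyte_tree
from plastarch.simulate import SimulationConfig, evolve, simulate_ancestor

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_SEED = 2014


def study_clade():
    cfg = SimulationConfig(seed=STUDY_SEED)
    ancestor = simulate_ancestor(cfg)
    tree = prasinophyte_tree()
    clade = evolve(ancestor, tree, cfg)
    return cfg, ancestor, clade
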