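import numpy as np
import pytest

from plastarch.genome_io import ChloroGenome, GeneFeature
from plastarch.prasinophytes import prasinophyte_tree
from plastarch.simulate import IRConfig, SimulationConfig, evolve, simulate_ancestor

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_feature(name, start, end, strand=1, conserved=True, category="protein",
                 length=None):
    """Single- or wrap-span feature; end <= length means plain span."""
    if length is not None and end > length:
        intervals = ((start, length), (0, end - length))
    else:
        intervals = ((start, end),)
    return GeneFeature(name=name, category=category, strand=strand,
                       intervals=intervals, conserved=conserved)


def make_genome(gid, length, feats, sequence=None):
    return ChloroGenome(id=gid, length=length, features=list(feats),
                        sequence=sequence)


@pytest.fixture(scope="session")
def sim_clade():
    """One compact simulated clade reused by several test modules."""
    cfg = SimulationConfig(n_genes=60, genome_bp=40_000, ir=IRConfig(length=6000),
                           n_inversions=2, n_losses=1, p_ir_loss=0.2, seed=11)
    ancestor = simulate_ancestor(cfg)
    tree = prasinophyte_tree()
    return cfg, ancestor, evolve(ancestor, tree, cfg)
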