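"""The prasinophyte study system: taxa, lineages, fixed species tree, and
curated presence/absence characters.

Twelve prasinophyte chloroplast genomes spanning six lineages (clades I,
II, III, V, VI and VII of the green-algal 18S rDNA classification) are
compared against the deep-branching streptophytes *Mesostigma viride* and
*Chlorokybus atmophyticus*.  The species tree used for character mapping is
fixed input (inferred elsewhere from concatenated chloroplast proteins):
the Prasinococcales (clade VI) branch first, then Pyramimonadales +
Mamiellophyceae (I + II), then the Nephroselmidophyceae (III), then
*Pycnococcus* (V), with the two clade-VII picoalgae as successive
independent lineages.

The binary characters recorded here are curated from the published genome
annotations: presence of the inverted repeat, and the distribution of the
six chloroplast genes retained only by the Prasinococcales among
chlorophytes (ndhJ, rbcR, rpl21, rps15, rps16, ycf66).
"""

from __future__ import annotations

from importlib import resources

from .genome_io import tree_from_string

__all__ = [
    "TAXA",
    "ACCESSIONS",
    "LINEAGES",
    "OUTGROUPS",
    "IR_PRESENCE",
    "PRASINOCOCCALES_GENES",
    "prasinophyte_tree",
]

#: short label -> (species, clade)
TAXA: dict[str, tuple[str, str]] = {
    "PCUS": ("Prasinococcus sp. CCMP 1194", "VI"),
    "MBIC": ("Prasinophyceae sp. MBIC 106222", "VI"),
    "PRMA": ("Prasinoderma coloniale CCMP 1220", "VI"),
    "PYRA": ("Pyramimonas parkeae CCMP 726", "I"),
    "MICR": ("Micromonas sp. RCC 299", "II"),
    "MONO": ("Monomastix sp. OKE-1", "II"),
    "OSTR": ("Ostreococcus tauri", "II"),
    "NAST": ("Nephroselmis astigmatica NIES 252", "III"),
    "NOLI": ("Nephroselmis olivacea NIES 484", "III"),
    "PYCN": ("Pycnococcus provasolii CCMP 1203", "V"),
    "PICO": ("Picocystis salinarum CCMP 1897", "VII"),
    "CCMP1205": ("Prasinophyceae sp. CCMP 1205", "VII"),
    "MESO": ("Mesostigma viride", "streptophyte"),
    "CHLO": ("Chlorokybus atmophyticus", "streptophyte"),
}

#: GenBank accessions of the compared records (for users who fetch them)
ACCESSIONS: dict[str, str] = {
    "PCUS": "KJ746597",
    "PRMA": "KJ746598",
    "PICO": "KJ746599",
    "NAST": "KJ746600",
    "CCMP1205": "KJ746601",
    "MBIC": "KJ746602",
    "NOLI": "NC_000927",
    "PYRA": "NC_012099",
    "MONO": "NC_012101",
    "OSTR": "NC_008289",
    "MICR": "NC_012575",
    "PYCN": "NC_012097",
    "MESO": "NC_002186",
    "CHLO": "NC_008822",
}

LINEAGES: dict[str, str] = {label: clade for label, (_, clade) in TAXA.items()
                            if clade != "streptophyte"}
OUTGROUPS = ["MESO", "CHLO"]

#: inverted-repeat presence per prasinophyte genome
IR_PRESENCE: dict[str, bool] = {
    "PCUS": False, "MBIC": False, "PRMA": False,
    "PYRA": True, "MICR": True, "MONO": False, "OSTR": True,
    "NAST": True, "NOLI": True,
    "PYCN": False, "PICO": True, "CCMP1205": False,
}

#: the six Prasinococcales-only genes: prasinophyte leaves where each is
#: encoded (all six are ancestral: present in the streptophyte outgroups)
PRASINOCOCCALES_GENES: dict[str, set[str]] = {
    "ndhJ": {"PCUS", "PRMA"},
    "rbcR": {"PCUS", "MBIC", "PRMA"},
    "rpl21": {"PCUS", "MBIC", "PRMA"},
    "rps15": {"PCUS", "MBIC", "PRMA"},
    "rps16": {"PCUS", "MBIC", "PRMA"},
    "ycf66": {"PCUS", "MBIC", "PRMA"},
}


def prasinophyte_tree(with_outgroups: bool = False):
    """The fixed rooted species tree of the 12 prasinophyte genomes."""
    name = ("prasinophyte_tree_outgroups.nwk" if with_outgroups
            else "prasinophyte_tree.nwk")
    newick = resources.files("plastarch.data").joinpath(name).read_text()
    return tree_from_string(newick)
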