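"""Bundled example trees.

The 12-taxon chordate species tree below is a hand-built reconstruction of a
widely accepted backbone topology (amphioxus, tunicate, lamprey, cartilaginous
fish, teleost, amniotes, ...). It exists so that every stage of the pipeline
can be exercised without downloading anything; branch lengths are round
numbers chosen for simulation convenience, not estimates.
"""

from __future__ import annotations

from .treeio import SpeciesTree

# Leaves are 4-letter species codes; internal nodes carry clade names used
# when reporting ancestral gene complements.
EXAMPLE_SPECIES_NEWICK = (
    "(Blan:1.0,(Cint:0.9,(Pmar:0.8,(Cmil:0.7,(Drer:0.6,(Xlae:0.5,"
    "((Acar:0.3,Ggal:0.3)Sauropsida:0.2,(Oana:0.3,(Mdom:0.2,"
    "(Mmus:0.1,Hsap:0.1)Eutheria:0.1)Theria:0.1)Mammalia:0.2)"
    "Amniota:0.1)Tetrapoda:0.1)Osteichthyes:0.1)Gnathostomata:0.1)"
    "Vertebrata:0.1)Olfactores:0.1)Chordata;"
)


def example_species_tree() -> SpeciesTree:
    """Return a fresh copy of the bundled 12-taxon species tree."""
    return SpeciesTree.from_newick(EXAMPLE_SPECIES_NEWICK)


def two_taxon_species_tree(depth: float = 1.0) -> SpeciesTree:
    """Ultrametric 2-taxon tree used for birth-death calibration checks."""
    return SpeciesTree.from_newick(f"(A:{depth!r},B:{depth!r})AB;")
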