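import numpy as np
import pytest

from orthosel.simulate import (
    SimRegime,
    simulate_codon_alignment,
    uniform_codon_freqs,
)
from orthosel.trees import LabeledTree


@pytest.fixture(scope="session")
def uniform_pi():
    return uniform_codon_freqs()


@pytest.fixture(scope="session")
def tree8_two_class():
    """8-taxon unrooted tree; the (e..h) clade carries branch class 1."""
    return LabeledTree.from_newick(
        "((a:0.3,b:0.3):0.2,(c:0.3,d:0.3):0.2,"
        "((e:0.3 #1,f:0.3 #1)#1:0.2,(g:0.3 #1,h:0.3 #1)#1:0.2)#1:0.2);"
    )


@pytest.fixture(scope="session")
def tree8_foreground_stem():
    """8-taxon tree; the long (e..h) stem branch is the foreground.

    The foreground is a single internal branch of 0.4 substitutions/codon,
    emulating the long post-duplication stem lineages on which episodic
    positive selection is typically tested.
    """
    return LabeledTree.from_newick(
        "((a:0.3,b:0.3):0.2,(c:0.3,d:0.3):0.2,"
        "((e:0.3,f:0.3):0.2,(g:0.3,h:0.3):0.2)#1:0.4);"
    )


@pytest.fixture(scope="session")
def sim_alignment(uniform_pi):
    """Factory for one-call codon-alignment simulations."""

    def make(tree, site_classes, n_codons, seed, kappa=2.0, scaling="per-matrix"):
        regime = SimRegime(
            tree=tree,
            kappa=kappa,
            codon_freqs=uniform_pi,
            site_classes=site_classes,
            n_codons=n_codons,
            seed=seed,
            scaling=scaling,
        )
        return simulate_codon_alignment(regime)

    return make


@pytest.fixture(scope="session")
def small_genomes():
    """4 genomes, 1 target family + 3 decoys, no duplication/loss."""
    from orthosel.simulate import simulate_genomes

    return simulate_genomes(
        4, 3, 0.0, 0.0, seed=7, n_codons=150, species_branch_length=0.3
    )
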