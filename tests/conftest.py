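import dendropy
import numpy as np
import pytest

from delimix.formats import LocusAlignment


@pytest.fixture
def toy_haploid():
    """Five haploid copies, 12 sites, three haplotype classes."""
    return LocusAlignment(
        "toy",
        ["i1", "i2", "i3", "i4", "i5"],
        [
            "ACGTACGTACGT",
            "ACGTACGTACGT",
            "ACGAACGTACGT",
            "ACGAACGTTCGT",
            "ACGAACGTTCGT",
        ],
        ploidy=1,
    )


@pytest.fixture
def toy_diploid():
    """Two diploid individuals at one short locus."""
    return LocusAlignment(
        "nuc",
        ["A_a", "A_b", "B_a", "B_b"],
        ["ACGT", "ACGT", "ACTT", "ACTT"],
        ploidy=2,
    )


def rooted_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


@pytest.fixture
def caterpillar8():
    return rooted_tree("(t1,(t2,(t3,(t4,(t5,(t6,(t7,t8)))))));")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
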