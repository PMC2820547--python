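import numpy as np
import pytest

from clonescan import LocusAlignment, concatenate


def aln_from_columns(columns, taxa=None, name="toy"):
    """Build an alignment from a list of column strings (one char per taxon)."""
    n = len(columns[0])
    taxa = taxa or [f"t{i+1}" for i in range(n)]
    rows = ["".join(col[i] for col in columns) for i in range(n)]
    return LocusAlignment(name, taxa, rows)


@pytest.fixture
def quartet_aln():
    """Four strains, one constant / one informative / two singleton columns."""
    return aln_from_columns(["AAAA", "AAAT", "AATT", "A-AT"])


@pytest.fixture
def two_locus_toy():
    """Perfectly associated alleles: two haplotype groups at both loci."""
    taxa = ["s1", "s2", "s3", "s4"]
    l1 = LocusAlignment("l1", taxa, ["AAAA", "AAAA", "TTTT", "TTTT"])
    l2 = LocusAlignment("l2", taxa, ["CCCC", "CCCC", "GGGG", "GGGG"])
    return concatenate([l1, l2])


@pytest.fixture
def conflicting_loci():
    """Two loci whose perfect phylogenies support incompatible quartets."""
    taxa = ["t1", "t2", "t3", "t4"]
    l1 = LocusAlignment("l1", taxa, ["AAA", "AAA", "GGG", "GGG"])  # 12|34
    l2 = LocusAlignment("l2", taxa, ["AAA", "GGG", "AAA", "GGG"])  # 13|24
    return concatenate([l1, l2])


def random_alignment(rng, n, L, name="rand"):
    codes = rng.integers(0, 4, size=(n, L))
    rows = ["".join("ACGT"[c] for c in row) for row in codes]
    return LocusAlignment(name, [f"s{j+1}" for j in range(n)], rows)
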