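"""Shared fixtures: toy domain tables, libraries and hand-built complexes."""

import pytest

from strandscape.kernel_model import Complex, DomainTable, Strand
from strandscape.library import LibrarySpec, build_library


@pytest.fixture(scope="session")
def table10():
    """Two orthogonal 10-nt domains (the smallest preset's domain set)."""
    return DomainTable({"a": 10, "b": 10})


@pytest.fixture(scope="session")
def table_many():
    return DomainTable({"a": 10, "b": 10, "c": 10, "t": 4, "x": 10})


@pytest.fixture(scope="session")
def toy21_library():
    """A (2, 1) toy library: 4 strands over one 8-nt domain."""
    return build_library(LibrarySpec.from_mapping("toy21", 2, {"a": 8}))


@pytest.fixture(scope="session")
def fig1_strand(table10):
    """The self-complementary single strand whose CRN has 3 structures."""
    return Strand((table10.domain("a"), table10.domain("a*")))


@pytest.fixture(scope="session")
def holliday(table_many):
    """Heterogeneous 4-strand junction with one migratable a/a* pair of pairs."""
    t = table_many
    A = Strand((t.domain("b"), t.domain("a")))
    B = Strand((t.domain("a*"), t.domain("c")))
    C = Strand((t.domain("c*"), t.domain("a")))
    D = Strand((t.domain("a*"), t.domain("b*")))
    pairs = frozenset(
        {((0, 0), (3, 1)), ((0, 1), (1, 0)), ((1, 1), (2, 0)), ((2, 1), (3, 0))}
    )
    return Complex((A, B, C, D), pairs)


def crossing_pairs_bruteforce(c: Complex) -> bool:
    """Independent O(p^2) crossing test over the linearized complex."""
    offsets = []
    total = 0
    for s in c.strands:
        offsets.append(total)
        total += len(s)
    lin = []
    for (si, pi), (sj, pj) in c.pairs:
        a, b = offsets[si] + pi, offsets[sj] + pj
        lin.append((min(a, b), max(a, b)))
    for idx, (a1, b1) in enumerate(lin):
        for a2, b2 in lin[idx + 1 :]:
            if (a1 < a2 < b1 < b2) or (a2 < a1 < b2 < b1):
                return True
    return False
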