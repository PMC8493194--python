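"""Strand libraries and genome encodings of strand subsets.

An (n, m) library is the exhaustive list of strands with n domains, each
position drawn from the 2m tokens (m base domains plus their complements),
giving (2m)**n strands.  A genome is a boolean membership vector over the
library with a cap on how many strands may be selected at once.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from itertools import product
from typing import Iterable

import numpy as np
import yaml

from .kernel_model import DomainTable, Strand

__all__ = [
    "LibrarySpec",
    "Library",
    "Genome",
    "PRESETS",
    "build_library",
    "get_preset",
    "subset_count",
    "genome_to_strands",
    "random_genome",
    "library_manifest_csv",
]

DEFAULT_MAX_STRANDS = 7  # strand subsets of "up to seven" strands
DEFAULT_SIZE_CAP = 1_000_000


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of an (n, m) library: n domains per strand, m base domains."""

    name: str
    n: int
    domain_lengths: tuple[tuple[str, int], ...]  # (base name, nt length), sorted

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n (domains per strand) must be >= 1")
        if not self.domain_lengths:
            raise ValueError("at least one domain type required")
        names = [b for b, _ in self.domain_lengths]
        if len(set(names)) != len(names):
            raise ValueError("duplicate domain names in spec")
        for _, length in self.domain_lengths:
            if length < 1:
                raise ValueError("domain lengths must be positive")
        object.__setattr__(
            self, "domain_lengths", tuple(sorted(self.domain_lengths))
        )

    @property
    def m(self) -> int:
        return len(self.domain_lengths)

    @property
    def size(self) -> int:
        """Number of strands in the full library: (2m)**n."""
        return (2 * self.m) ** self.n

    def domain_table(self) -> DomainTable:
        return DomainTable(dict(self.domain_lengths))

    @classmethod
    def from_mapping(cls, name: str, n: int, lengths: dict[str, int]) -> "LibrarySpec":
        return cls(name, n, tuple(sorted(lengths.items())))

    @classmethod
    def from_yaml(cls, text: str) -> "LibrarySpec":
        doc = yaml.safe_load(text)
        return cls.from_mapping(doc["name"], int(doc["n"]), dict(doc["domains"]))

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {"name": self.name, "n": self.n, "domains": dict(self.domain_lengths)},
            sort_keys=True,
        )


# Library presets.  L1 is small enough for exhaustive subset evaluation,
# L2 is a 4-domain refinement of L1 (same 20 nt of strand, shorter domains),
# L3 uses six domain types with one shorter domain.
PRESETS: dict[str, LibrarySpec] = {
    "L1": LibrarySpec.from_mapping("L1", 2, {"a": 10, "b": 10}),
    "L2": LibrarySpec.from_mapping("L2", 4, {"a": 5, "b": 5}),
    "L3": LibrarySpec.from_mapping(
        "L3", 3, {"a": 17, "b": 17, "c": 17, "d": 15, "e": 17, "f": 17}
    ),
}


@dataclass(frozen=True)
class Library:
    """A fully enumerated (n, m) library with a stable strand order."""

    spec: LibrarySpec
    strands: tuple[Strand, ...]

    def __len__(self) -> int:
        return len(self.strands)

    def domain_table(self) -> DomainTable:
        return self.spec.domain_table()

    def index_of(self, strand: Strand) -> int:
        try:
            return self.strands.index(strand)
        except ValueError:
            raise KeyError(f"strand {strand.name!r} not in library {self.spec.name}")


def build_library(spec: LibrarySpec, size_cap: int = DEFAULT_SIZE_CAP) -> Library:
    """Enumerate all (2m)**n ordered domain tuples, lexicographically.

    Strands are ordered tuples: ``a b`` and ``b a`` are distinct entries and
    reverse-complement-equivalent strands are not deduplicated.
    """
    if spec.size > size_cap:
        raise ValueError(
            f"library {spec.name} has {spec.size} strands, over the cap {size_cap}"
        )
    table = spec.domain_table()
    tokens = table.tokens()
    strands = tuple(
        Strand(tuple(table.domain(t) for t in combo))
        for combo in product(tokens, repeat=spec.n)
    )
    return Library(spec, strands)


def get_preset(name: str) -> Library:
    return build_library(PRESETS[name])


def subset_count(library: Library) -> int:
    """Number of non-empty strand subsets: 2**|strands| - 1."""
    return 2 ** len(library.strands) - 1


@dataclass(frozen=True)
class Genome:
    """Boolean membership vector selecting a strand subset from a library."""

    bits: tuple[int, ...]
    max_strands: int = DEFAULT_MAX_STRANDS

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("genome bits must be 0/1")
        k = self.popcount
        if not (1 <= k <= self.max_strands):
            raise ValueError(
                f"genome must select between 1 and {self.max_strands} strands, got {k}"
            )

    @property
    def popcount(self) -> int:
        return sum(self.bits)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.bits) if b)

    def bitstring(self) -> str:
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_indices(
        cls, indices: Iterable[int], size: int, max_strands: int = DEFAULT_MAX_STRANDS
    ) -> "Genome":
        idx = set(indices)
        return cls(tuple(1 if i in idx else 0 for i in range(size)), max_strands)


def genome_to_strands(g: Genome, library: Library) -> list[Strand]:
    """Selected strands in library order (deterministic)."""
    if len(g.bits) != len(library.strands):
        raise ValueError(
            f"genome length {len(g.bits)} does not match library size {len(library.strands)}"
        )
    return [library.strands[i] for i in g.indices]


def random_genome(
    library: Library, rng: np.random.Generator, max_strands: int = DEFAULT_MAX_STRANDS
) -> Genome:
    """Uniform popcount in [1, max_strands], then uniform strand choice."""
    cap = min(max_strands, len(library.strands))
    k = int(rng.integers(1, cap + 1))
    idx = rng.choice(len(library.strands), size=k, replace=False)
    return Genome.from_indices((int(i) for i in idx), len(library.strands), max_strands)


def library_manifest_csv(library: Library) -> str:
    """CSV manifest: index, strand name, domain tokens."""
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["index", "strand"])
    for i, s in enumerate(library.strands):
        w.writerow([i, s.name])
    return buf.getvalue()
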