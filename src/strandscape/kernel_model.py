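"""Domain-level data model for multistranded DNA complexes.

A *domain* is a short nucleotide stretch treated as an atomic binding unit;
``x*`` denotes the Watson-Crick complement of ``x``.  A *complex* is a
connected, pseudoknot-free arrangement of strands joined by domain-level
pairs.  Complexes are written in kernel notation: ``d(`` opens a helix that
is closed by a bare ``)`` (the closer implicitly being the complement of the
opener) and ``+`` separates strands, e.g. ``a( a*( + ) )`` for the duplex of
two ``a a*`` strands.

Pseudoknot-freeness is defined relative to the complex's stored circular
strand order: when the strands are laid out on a line (with ``+`` breaks) no
two pairs may cross.  Circular rotations of the strand order describe the
same physical object; :func:`canonical_form` picks the rotation whose kernel
string is lexicographically minimal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator, Mapping

__all__ = [
    "DomainType",
    "DomainTable",
    "Strand",
    "Complex",
    "KernelParseError",
    "parse_kernel",
    "write_kernel",
    "canonical_form",
    "make_complex",
    "load_pil",
    "dump_pil",
]

#: a domain occurrence: (strand index, 0-based position within the strand)
Occ = tuple[int, int]
#: an unordered pair of occurrences, stored sorted
Pair = tuple[Occ, Occ]


class KernelParseError(ValueError):
    """Raised on malformed kernel notation; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at character {position})"
        super().__init__(message)


@dataclass(frozen=True, order=True)
class DomainType:
    """An atomic binding unit with a nucleotide length.

    ``base`` never carries a ``*``; the complement flag does.  The printed
    name of the complement of ``a`` is ``a*``; ``complement`` is an
    involution preserving length.
    """

    base: str
    length: int
    is_complement: bool = False

    def __post_init__(self) -> None:
        if not self.base or "*" in self.base:
            raise ValueError(f"invalid domain base name {self.base!r}")
        if self.length <= 0:
            raise ValueError("domain length must be positive")

    @property
    def name(self) -> str:
        return self.base + ("*" if self.is_complement else "")

    @property
    def complement(self) -> "DomainType":
        return DomainType(self.base, self.length, not self.is_complement)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


class DomainTable(Mapping[str, int]):
    """Lookup table from base domain names to nucleotide lengths.

    Resolves arbitrary kernel tokens: trailing ``*`` markers are normalized
    modulo two, so ``x**`` resolves to ``x``.
    """

    def __init__(self, lengths: Mapping[str, int]):
        self._lengths: dict[str, int] = {}
        for base, length in lengths.items():
            if "*" in base:
                raise ValueError(f"base domain name may not contain '*': {base!r}")
            if length <= 0:
                raise ValueError(f"domain {base!r} must have positive length")
            self._lengths[base] = int(length)

    def __getitem__(self, base: str) -> int:
        return self._lengths[base]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def domain(self, token: str) -> DomainType:
        """Resolve a kernel token (e.g. ``a``, ``b*``, ``a**``) to a domain."""
        stars = len(token) - len(token.rstrip("*"))
        base = token[: len(token) - stars] if stars else token
        if base not in self._lengths:
            raise KeyError(f"unknown domain name {base!r}")
        return DomainType(base, self._lengths[base], bool(stars % 2))

    def tokens(self) -> list[str]:
        """All 2m domain tokens in lexicographic order."""
        out: list[str] = []
        for base in self._lengths:
            out.extend((base, base + "*"))
        return sorted(out)

    @property
    def max_length(self) -> int:
        return max(self._lengths.values())


@dataclass(frozen=True, order=True)
class Strand:
    """An ordered, non-empty run of domains.  Identified by its name."""

    domains: tuple[DomainType, ...]

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("strand must contain at least one domain")

    @property
    def name(self) -> str:
        return " ".join(d.name for d in self.domains)

    def __len__(self) -> int:
        return len(self.domains)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def _offsets(strands: tuple[Strand, ...]) -> list[int]:
    offs, total = [], 0
    for s in strands:
        offs.append(total)
        total += len(s)
    return offs


def _linearize(strands: tuple[Strand, ...], pairs: Iterable[Pair]) -> list[tuple[int, int]]:
    offs = _offsets(strands)
    out = []
    for (si, pi), (sj, pj) in pairs:
        a, b = offs[si] + pi, offs[sj] + pj
        out.append((a, b) if a < b else (b, a))
    return sorted(out)


def pairs_noncrossing(strands: tuple[Strand, ...], pairs: Iterable[Pair]) -> bool:
    """True iff no two pairs cross in the linearized strand order."""
    lin = _linearize(strands, pairs)
    for i, (a1, b1) in enumerate(lin):
        for a2, b2 in lin[i + 1 :]:
            if a1 < a2 < b1 < b2:
                return False
    return True


def strands_connected(n_strands: int, pairs: Iterable[Pair]) -> bool:
    if n_strands <= 1:
        return True
    parent = list(range(n_strands))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (si, _), (sj, _) in pairs:
        parent[find(si)] = find(sj)
    return len({find(i) for i in range(n_strands)}) == 1


def _norm_pair(a: Occ, b: Occ) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Complex:
    """A connected, pseudoknot-free multistranded structure.

    ``strands`` is the stored circular order; ``pairs`` joins occurrences of
    complementary domains, each occurrence in at most one pair, non-crossing
    under the stored linearization.
    """

    strands: tuple[Strand, ...]
    pairs: frozenset[Pair]

    def __post_init__(self) -> None:
        n = len(self.strands)
        if n == 0:
            raise ValueError("complex must contain at least one strand")
        seen: set[Occ] = set()
        for pair in self.pairs:
            (si, pi), (sj, pj) = pair
            for s, p in pair:
                if not (0 <= s < n and 0 <= p < len(self.strands[s])):
                    raise ValueError(f"occurrence {(s, p)} out of range")
                if (s, p) in seen:
                    raise ValueError(f"occurrence {(s, p)} paired twice")
                seen.add((s, p))
            d1 = self.strands[si].domains[pi]
            d2 = self.strands[sj].domains[pj]
            if d1.complement != d2:
                raise ValueError(f"pair {pair} joins non-complementary domains {d1}/{d2}")
        if not pairs_noncrossing(self.strands, self.pairs):
            raise ValueError("pairing is crossing (pseudoknot) in stored strand order")
        if not strands_connected(n, self.pairs):
            raise ValueError("complex is not connected")

    # -- basic queries ---------------------------------------------------

    @property
    def n_strands(self) -> int:
        return len(self.strands)

    def domain_at(self, occ: Occ) -> DomainType:
        return self.strands[occ[0]].domains[occ[1]]

    @property
    def paired(self) -> dict[Occ, Occ]:
        """Occurrence -> partner map (both directions)."""
        out: dict[Occ, Occ] = {}
        for a, b in self.pairs:
            out[a] = b
            out[b] = a
        return out

    def unpaired_occs(self) -> list[Occ]:
        taken = self.paired
        return [
            (si, pi)
            for si, s in enumerate(self.strands)
            for pi in range(len(s))
            if (si, pi) not in taken
        ]

    # -- rotations and canonical form ------------------------------------

    def rotate(self, k: int) -> "Complex":
        """Rotate the circular strand order by k; must stay non-crossing."""
        n = len(self.strands)
        k %= n
        strands = self.strands[k:] + self.strands[:k]
        pairs = frozenset(
            _norm_pair(((si - k) % n, pi), ((sj - k) % n, pj))
            for (si, pi), (sj, pj) in self.pairs
        )
        return Complex(strands, pairs)

    def valid_rotations(self) -> list[int]:
        n = len(self.strands)
        out = []
        for k in range(n):
            strands = self.strands[k:] + self.strands[:k]
            pairs = [
                _norm_pair(((si - k) % n, pi), ((sj - k) % n, pj))
                for (si, pi), (sj, pj) in self.pairs
            ]
            if pairs_noncrossing(strands, pairs):
                out.append(k)
        return out

    @property
    def kernel(self) -> str:
        """Kernel string in the stored strand order."""
        return _kernel_string(self.strands, self.pairs)

    @property
    def canonical_kernel(self) -> str:
        return canonical_form(self).kernel

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.kernel


def _kernel_string(strands: tuple[Strand, ...], pairs: Iterable[Pair]) -> str:
    offs = _offsets(strands)
    opener: dict[Occ, bool] = {}
    for (a, b) in pairs:
        la = offs[a[0]] + a[1]
        lb = offs[b[0]] + b[1]
        opener[a] = la < lb
        opener[b] = lb < la
    parts = []
    for si, strand in enumerate(strands):
        toks = []
        for pi, dom in enumerate(strand.domains):
            occ = (si, pi)
            if occ in opener:
                toks.append(dom.name + "(" if opener[occ] else ")")
            else:
                toks.append(dom.name)
        parts.append(" ".join(toks))
    return " + ".join(parts)


@lru_cache(maxsize=65536)
def canonical_form(c: Complex) -> Complex:
    """The rotation of ``c`` with the lexicographically minimal kernel string.

    Idempotent; rotation-invariant: ``canonical_form(c.rotate(k)) ==
    canonical_form(c)`` for every valid rotation k.
    """
    best: Complex | None = None
    best_key: str | None = None
    for k in c.valid_rotations():
        cand = c.rotate(k)
        key = cand.kernel
        if best_key is None or key < best_key:
            best, best_key = cand, key
    assert best is not None  # stored order is always a valid rotation
    return best


def make_complex(strands: Iterable[Strand], pairs: Iterable[tuple[Occ, Occ]]) -> Complex | None:
    """Build a canonical complex from a proposed strand order and pair set.

    Searches circular rotations for one under which the pairing is
    non-crossing.  Returns None when no rotation works or the strands are
    not all connected by pairs.
    """
    strands = tuple(strands)
    norm = frozenset(_norm_pair(a, b) for a, b in pairs)
    if not strands_connected(len(strands), norm):
        return None
    n = len(strands)
    for k in range(n):
        rot_strands = strands[k:] + strands[:k]
        rot_pairs = [
            _norm_pair(((si - k) % n, pi), ((sj - k) % n, pj))
            for (si, pi), (sj, pj) in norm
        ]
        if pairs_noncrossing(rot_strands, rot_pairs):
            try:
                return canonical_form(Complex(rot_strands, frozenset(rot_pairs)))
            except ValueError:
                return None
    return None


# ---------------------------------------------------------------------------
# kernel notation I/O
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<plus>\+)|(?P<close>\))|(?P<name>[A-Za-z0-9_]+\**)(?P<open>\()?)")


def parse_kernel(text: str, table: DomainTable) -> Complex:
    """Parse one kernel-notation line into a (validated) complex.

    Grammar: ``name`` (unpaired domain), ``name(`` (helix opener), ``)``
    (helix closer, implicitly the complement of its opener) and ``+``
    (strand break).
    """
    strands: list[list[DomainType]] = [[]]
    stack: list[tuple[Occ, DomainType]] = []
    pairs: list[Pair] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip():
                raise KernelParseError(f"unexpected character {text[pos]!r}", pos)
            break
        if m.group("plus"):
            if not strands[-1]:
                raise KernelParseError("empty strand before '+'", pos)
            strands.append([])
        elif m.group("close"):
            if not stack:
                raise KernelParseError("unbalanced ')'", pos)
            opener_occ, opener_dom = stack.pop()
            closer_dom = opener_dom.complement
            occ = (len(strands) - 1, len(strands[-1]))
            strands[-1].append(closer_dom)
            pairs.append(_norm_pair(opener_occ, occ))
        else:
            try:
                dom = table.domain(m.group("name"))
            except KeyError as exc:
                raise KernelParseError(str(exc), m.start("name")) from None
            occ = (len(strands) - 1, len(strands[-1]))
            strands[-1].append(dom)
            if m.group("open"):
                stack.append((occ, dom))
        pos = m.end()
    if stack:
        raise KernelParseError("unbalanced '(': helix never closed", len(text))
    if not strands[-1]:
        raise KernelParseError("empty strand at end of line", len(text))
    try:
        return Complex(tuple(Strand(tuple(d)) for d in strands), frozenset(pairs))
    except ValueError as exc:
        raise KernelParseError(str(exc)) from None


def write_kernel(c: Complex, canonical: bool = True) -> str:
    """Inverse of :func:`parse_kernel`; canonical strand order by default."""
    return canonical_form(c).kernel if canonical else c.kernel


# ---------------------------------------------------------------------------
# PIL-style text files: domain declarations + one named complex per line
# ---------------------------------------------------------------------------

_LENGTH_RE = re.compile(r"^length\s+([A-Za-z0-9_]+)\s*=\s*(\d+)$")
_COMPLEX_RE = re.compile(r"^([A-Za-z0-9_.\-]+)\s*=\s*(.+)$")


def load_pil(text: str) -> tuple[DomainTable, dict[str, Complex]]:
    """Read a PIL-style document: ``length x = N`` lines then named kernels."""
    lengths: dict[str, int] = {}
    raw: list[tuple[str, str]] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        m = _LENGTH_RE.match(line)
        if m:
            lengths[m.group(1)] = int(m.group(2))
            continue
        m = _COMPLEX_RE.match(line)
        if m:
            raw.append((m.group(1), m.group(2)))
            continue
        raise KernelParseError(f"unparseable line: {line!r}")
    table = DomainTable(lengths)
    complexes = {name: parse_kernel(kern, table) for name, kern in raw}
    return table, complexes


def dump_pil(table: DomainTable, complexes: Mapping[str, Complex]) -> str:
    lines = [f"length {base} = {table[base]}" for base in sorted(table)]
    lines += [f"{name} = {write_kernel(c)}" for name, c in complexes.items()]
    return "\n".join(lines) + "\n"
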