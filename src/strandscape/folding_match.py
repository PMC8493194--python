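"""Sequence-level evaluation: fold, check well-formedness, match structures.

The bundled folding oracle is a deterministic stand-in for a thermodynamic
MFE engine: over every circular ordering of the input strand multiset it
maximizes the number of paired nucleotides, restricted to aligned pairings
of fully sequence-complementary domain tokens, subject to the structure
being non-crossing and (for multistranded inputs) connected.  External
engines can be plugged in behind the same contract (strand multiset in,
nucleotide pairing out).

Well-formedness then maps nucleotide pairs back onto the domain design:
every hybridized nucleotide must join complementary domain types at
mirrored offsets, and a domain pair counts as hybridized when at least
``hybridization_fraction`` of its nucleotides are paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

from sympy.utilities.iterables import multiset_permutations

from .enumerator import CRN
from .kernel_model import Complex, DomainTable, Occ, Strand, canonical_form, make_complex

__all__ = [
    "SequenceAssignment",
    "FoldParams",
    "FoldedComplex",
    "MatchReport",
    "NotWellFormed",
    "revcomp",
    "fold_mfe",
    "wellformed_domains",
    "match_overlap",
    "evaluate_assignment",
]

_COMP = str.maketrans("ACGT", "TGCA")

#: nucleotide position inside a complex: (strand index, nt offset)
NtOcc = tuple[int, int]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SequenceAssignment:
    """Nucleotide sequences for base domains; complements are derived."""

    seqs: tuple[tuple[str, str], ...]  # (base name, sequence), sorted

    def __post_init__(self) -> None:
        for base, seq in self.seqs:
            if "*" in base:
                raise ValueError("assignments are keyed by base domain names")
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"sequence for {base!r} must be non-empty over ACGT")
        object.__setattr__(self, "seqs", tuple(sorted(self.seqs)))

    @classmethod
    def from_mapping(cls, seqs: Mapping[str, str]) -> "SequenceAssignment":
        return cls(tuple(sorted(seqs.items())))

    def as_dict(self) -> dict[str, str]:
        return dict(self.seqs)

    def seq_for(self, domain) -> str:
        base = dict(self.seqs)[domain.base]
        return revcomp(base) if domain.is_complement else base

    def validate_against(self, table: DomainTable) -> None:
        d = self.as_dict()
        for base in table:
            if base not in d:
                raise ValueError(f"no sequence for domain {base!r}")
            if len(d[base]) != table[base]:
                raise ValueError(
                    f"sequence for {base!r} has length {len(d[base])}, expected {table[base]}"
                )

    def to_fasta(self) -> str:
        return "".join(f">{base}\n{seq}\n" for base, seq in self.seqs)

    @classmethod
    def from_fasta(cls, text: str) -> "SequenceAssignment":
        seqs: dict[str, str] = {}
        name = None
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name is not None:
                seqs[name] += line.upper()
        return cls.from_mapping(seqs)


@dataclass(frozen=True)
class FoldParams:
    max_complex_size: int = 3
    hybridization_fraction: float = 0.5
    #: search-effort cap on the branch-and-bound fold (node expansions)
    max_nodes: int = 200_000
    #: cap on distinct circular strand orderings tried per multiset
    max_orderings: int = 2000

    def __post_init__(self) -> None:
        if self.max_complex_size < 1:
            raise ValueError("max_complex_size must be >= 1")
        if not (0 < self.hybridization_fraction <= 1):
            raise ValueError("hybridization_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FoldedComplex:
    """A strand ordering with a non-crossing nucleotide pairing."""

    strands: tuple[Strand, ...]
    sequences: tuple[str, ...]  # one full sequence per strand
    base_pairs: frozenset[tuple[NtOcc, NtOcc]]
    paired_nt: int = 0

    @property
    def n_strands(self) -> int:
        return len(self.strands)


class NotWellFormed(ValueError):
    """A folded structure does not follow the domain-level design."""

    def __init__(self, reason: str, base_pair: tuple[NtOcc, NtOcc] | None = None):
        self.reason = reason
        self.base_pair = base_pair
        msg = reason if base_pair is None else f"{reason} at nucleotide pair {base_pair}"
        super().__init__(msg)


@dataclass(frozen=True)
class MatchReport:
    """Agreement between folded (well-formed) and enumerated structures."""

    n_overlap: int
    n_enumerated: int
    matched: tuple[str, ...]
    params: FoldParams

    @property
    def proportion(self) -> float:
        if self.n_enumerated == 0:
            return 0.0
        return 100.0 * self.n_overlap / self.n_enumerated

    def as_dict(self) -> dict:
        return {
            "n_overlap": self.n_overlap,
            "n_enumerated": self.n_enumerated,
            "proportion": self.proportion,
            "matched": list(self.matched),
            "max_complex_size": self.params.max_complex_size,
            "hybridization_fraction": self.params.hybridization_fraction,
        }


# ---------------------------------------------------------------------------
# the bundled deterministic folding oracle
# ---------------------------------------------------------------------------


def _distinct_circular_orderings(
    names: Sequence[str], cap: int
) -> list[tuple[str, ...]]:
    """Distinct orderings of a multiset up to rotation, deterministically."""
    seen: set[tuple[str, ...]] = set()
    out: list[tuple[str, ...]] = []
    for perm in multiset_permutations(sorted(names)):
        tup = tuple(perm)
        canon = min(tup[i:] + tup[:i] for i in range(len(tup)))
        if canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
        if len(out) >= cap:
            break
    return out


def _best_pairing(
    tokens: list[tuple[int, str, int]], connected_required: bool, n_strands: int, max_nodes: int
) -> tuple[int, tuple[tuple[int, int], ...]] | None:
    """Max-weight non-crossing token pairing; lexicographically minimal ties.

    ``tokens`` is (strand index, sequence, nt length) per domain occurrence
    in linear order.  A token i may pair a later token j iff their
    sequences are exact reverse complements.  When ``connected_required``,
    only pairings whose pairs connect all strands qualify.  Explored
    depth-first in lexicographic pair order with a DP upper bound, so the
    first leaf attaining the final best weight is the lexicographic
    minimum.  Returns None when no qualifying pairing exists.
    """
    t = len(tokens)
    match = [[False] * t for _ in range(t)]
    for i in range(t):
        for j in range(i + 1, t):
            match[i][j] = tokens[j][1] == revcomp(tokens[i][1])

    # unconstrained interval DP as an admissible bound
    dp = [[0] * (t + 1) for _ in range(t + 1)]
    for span in range(2, t + 1):
        for i in range(0, t - span + 1):
            j = i + span  # interval [i, j)
            best = dp[i + 1][j]
            for k in range(i + 1, j):
                if match[i][k]:
                    cand = tokens[i][2] + dp[i + 1][k] + dp[k + 1][j]
                    if cand > best:
                        best = cand
            dp[i][j] = best

    best_w = -1
    best_pairs: tuple[tuple[int, int], ...] | None = None
    nodes = 0

    def connected(pairs: Iterable[tuple[int, int]]) -> bool:
        if n_strands <= 1:
            return True
        parent = list(range(n_strands))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in pairs:
            parent[find(tokens[i][0])] = find(tokens[j][0])
        return len({find(s) for s in range(n_strands)}) == 1

    def rec(segments: tuple[tuple[int, int], ...], pairs: list, w: int) -> None:
        nonlocal best_w, best_pairs, nodes
        nodes += 1
        if nodes > max_nodes:
            return
        bound = w + sum(dp[a][b] for a, b in segments)
        if bound <= best_w:
            return
        while segments and segments[0][0] >= segments[0][1]:
            segments = segments[1:]
        if not segments:
            if w > best_w and (not connected_required or connected(pairs)):
                best_w = w
                best_pairs = tuple(pairs)
            return
        (i, j), rest = segments[0], segments[1:]
        for k in range(i + 1, j):
            if match[i][k]:
                pairs.append((i, k))
                rec(((i + 1, k), (k + 1, j)) + rest, pairs, w + tokens[i][2])
                pairs.pop()
        rec(((i + 1, j),) + rest, pairs, w)

    rec(((0, t),), [], 0)
    if best_pairs is None:
        return None
    return best_w, best_pairs


def fold_mfe(
    strands: Sequence[Strand],
    assignment: SequenceAssignment,
    params: FoldParams = FoldParams(),
) -> FoldedComplex | None:
    """Fold a strand multiset with the bundled oracle.

    Deterministic and invariant under reordering of the input multiset.
    Returns None when no connected pairing exists for a multistranded
    input (the complex does not form).
    """
    if not (1 <= len(strands) <= params.max_complex_size):
        raise ValueError(
            f"strand multiset size {len(strands)} outside [1, {params.max_complex_size}]"
        )
    by_name = {s.name: s for s in strands}
    orderings = _distinct_circular_orderings(
        [s.name for s in strands], params.max_orderings
    )
    best_key: tuple | None = None
    best: tuple[int, tuple, tuple[Strand, ...], list] | None = None
    for names in orderings:
        order = tuple(by_name[n] for n in names)
        tokens: list[tuple[int, str, int]] = []
        for si, s in enumerate(order):
            for dom in s.domains:
                tokens.append((si, assignment.seq_for(dom), dom.length))
        res = _best_pairing(tokens, len(order) > 1, len(order), params.max_nodes)
        if res is None:
            continue
        w, token_pairs = res
        key = (-w, names, token_pairs)
        if best_key is None or key < best_key:
            best_key = key
            best = (w, token_pairs, order, tokens)
    if best is None:
        return None
    w, token_pairs, order, tokens = best
    # expand domain-token pairs into aligned nucleotide pairs
    nt_offset: list[int] = []
    cursor: dict[int, int] = {}
    for si, seq, length in tokens:
        nt_offset.append(cursor.get(si, 0))
        cursor[si] = cursor.get(si, 0) + length
    base_pairs = set()
    for i, j in token_pairs:
        si, _, li = tokens[i]
        sj, _, lj = tokens[j]
        for k in range(li):
            base_pairs.add(((si, nt_offset[i] + k), (sj, nt_offset[j] + lj - 1 - k)))
    sequences = tuple(
        "".join(assignment.seq_for(d) for d in s.domains) for s in order
    )
    return FoldedComplex(order, sequences, frozenset(base_pairs), paired_nt=w)


def wellformed_domains(
    f: FoldedComplex, params: FoldParams = FoldParams()
) -> Complex:
    """Map a nucleotide pairing back to the domain design, or reject.

    Raises :class:`NotWellFormed` when a paired nucleotide joins
    non-complementary domain types or sits at a mis-aligned offset, or when
    the resulting domain-level structure is not a valid connected complex.
    """
    # domain occupancy map per strand: nt position -> (domain pos, offset, domain)
    layout: list[list[tuple[int, int, object]]] = []
    for s in f.strands:
        row: list[tuple[int, int, object]] = []
        for dpos, dom in enumerate(s.domains):
            for off in range(dom.length):
                row.append((dpos, off, dom))
        layout.append(row)

    counts: dict[tuple[Occ, Occ], int] = {}
    for bp in f.base_pairs:
        (s1, n1), (s2, n2) = bp
        d1pos, off1, dom1 = layout[s1][n1]
        d2pos, off2, dom2 = layout[s2][n2]
        if dom1.complement != dom2:
            raise NotWellFormed(
                f"nucleotides pair incompatible domains {dom1.name}/{dom2.name}", bp
            )
        if off2 != dom1.length - 1 - off1:
            raise NotWellFormed("mis-aligned hybridization offset", bp)
        occ1, occ2 = (s1, d1pos), (s2, d2pos)
        key = (occ1, occ2) if occ1 <= occ2 else (occ2, occ1)
        counts[key] = counts.get(key, 0) + 1

    pairs = set()
    used: set[Occ] = set()
    for (occ1, occ2), n_paired in sorted(counts.items()):
        dom = f.strands[occ1[0]].domains[occ1[1]]
        if n_paired < params.hybridization_fraction * dom.length:
            continue
        if occ1 in used or occ2 in used:
            raise NotWellFormed(f"domain occurrence {occ1} hybridizes two partners")
        used.update((occ1, occ2))
        pairs.add((occ1, occ2))

    result = make_complex(f.strands, pairs)
    if result is None:
        raise NotWellFormed("domain-level structure is disconnected or crossing")
    return result


def match_overlap(
    folded: Iterable[Complex], crn: CRN, params: FoldParams = FoldParams()
) -> MatchReport:
    """Overlap between folded well-formed structures and the enumerated CRN.

    Both sides are canonicalized, so circular permutations of strand order
    match.  The denominator counts enumerated structures within the
    folding size cap (the only ones observable by the folding side).
    """
    folded_keys = {canonical_form(c).kernel for c in folded}
    enum_keys = {
        c.kernel for c in crn.structures if c.n_strands <= params.max_complex_size
    }
    matched = tuple(sorted(folded_keys & enum_keys))
    return MatchReport(len(matched), len(enum_keys), matched, params)


def evaluate_assignment(
    assignment: SequenceAssignment,
    crn: CRN,
    params: FoldParams = FoldParams(),
) -> MatchReport:
    """Fold every multiset of the CRN's strands up to the size cap and match.

    Emulates a complex-ensemble evaluation: each distinct strand multiset
    is folded independently; folds that are not well formed (or do not
    form a connected complex) contribute nothing.
    """
    selected = sorted(
        {s for c in crn.initial for s in c.strands}, key=lambda s: s.name
    )
    folded: list[Complex] = []
    for size in range(1, params.max_complex_size + 1):
        for multiset in combinations_with_replacement(selected, size):
            f = fold_mfe(multiset, assignment, params)
            if f is None:
                continue
            try:
                folded.append(wellformed_domains(f, params))
            except NotWellFormed:
                continue
    return match_overlap(folded, crn, params)
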