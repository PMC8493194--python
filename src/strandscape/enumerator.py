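"""Domain-level reaction enumeration of strand-set self-assembly networks.

Starting from a set of single strands, the enumerator repeatedly applies
four move generators -- hybridization (``bind``), dissociation (``open``),
three-way branch migration (``branch3``) and four-way branch migration
(``branch4``) -- canonicalizing every product, until no new structure or
reaction appears or a hard cap fires.

Reactions are split into *fast* (unimolecular) and *slow* (bimolecular).
Complexes classified as transient are condensed out of the reported network
and are barred from bimolecular reactions during enumeration.  A complex is
transient when either

* its strongly connected component under fast 1->1 reactions has a fast
  1->1 exit to another component (it spontaneously converts onward), or
* it can both spontaneously fall apart (a fast 1->2 dissociation) and
  spontaneously convert (a fast 1->1 reaction) -- a short-lived assembly
  intermediate.

A complex whose only spontaneous option is dissociation (e.g. a fully
closed duplex) is metastable and kept.  Initial strands are always kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations, product as iproduct
from math import log2
from typing import Iterable, Sequence

import networkx as nx

from .kernel_model import (
    Complex,
    DomainTable,
    Occ,
    Pair,
    Strand,
    canonical_form,
    make_complex,
    parse_kernel,
)

__all__ = [
    "Reaction",
    "EnumParams",
    "CRN",
    "bind_moves",
    "open_moves",
    "branch3_moves",
    "branch4_moves",
    "enumerate_detailed",
    "enumerate_crn",
    "condense",
    "crn_metrics",
    "reversible_pairs",
]

RTYPES = ("bind", "open", "branch3", "branch4")


def _ckey(c: Complex) -> str:
    return c.kernel  # complexes handled here are always canonical


def _sorted_side(cs: Iterable[Complex]) -> tuple[Complex, ...]:
    return tuple(sorted(cs, key=_ckey))


@dataclass(frozen=True)
class Reaction:
    """A typed reaction between canonical complexes (multiset semantics)."""

    rtype: str
    reactants: tuple[Complex, ...]
    products: tuple[Complex, ...]

    def __post_init__(self) -> None:
        if self.rtype not in RTYPES:
            raise ValueError(f"unknown reaction type {self.rtype!r}")
        object.__setattr__(self, "reactants", _sorted_side(self.reactants))
        object.__setattr__(self, "products", _sorted_side(self.products))
        rs = sorted(s for c in self.reactants for s in c.strands)
        ps = sorted(s for c in self.products for s in c.strands)
        if rs != ps:
            raise ValueError("strand multiset not conserved across reaction")

    @property
    def is_fast(self) -> bool:
        """Unimolecular reactions are fast; bimolecular slow."""
        return len(self.reactants) == 1

    @property
    def key(self) -> tuple:
        return (
            self.rtype,
            tuple(_ckey(c) for c in self.reactants),
            tuple(_ckey(c) for c in self.products),
        )

    def is_noop(self) -> bool:
        return self.reactants == self.products

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lhs = " + ".join(f"[{_ckey(c)}]" for c in self.reactants)
        rhs = " + ".join(f"[{_ckey(c)}]" for c in self.products)
        return f"{lhs} -> {rhs} [{self.rtype}]"


@dataclass(frozen=True)
class EnumParams:
    """Enumeration bounds and semantics knobs.

    ``release_cutoff`` is the maximum nucleotide length of a duplex domain
    that may spontaneously open; None means "the longest domain in play"
    (everything can open).  Growth is artificially bounded by
    ``max_complex_size`` / ``max_structures`` / ``max_reactions``.
    """

    max_complex_size: int = 6
    release_cutoff: int | None = None
    max_structures: int = 5000
    max_reactions: int = 20000
    transient_policy: bool = True
    max_fates: int = 64

    def __post_init__(self) -> None:
        if self.max_complex_size < 1 or self.max_structures < 1 or self.max_reactions < 1:
            raise ValueError("enumeration caps must be positive")
        if self.release_cutoff is not None and self.release_cutoff < 0:
            raise ValueError("release_cutoff must be non-negative")

    def cutoff_for(self, complexes: Iterable[Complex]) -> int:
        if self.release_cutoff is not None:
            return self.release_cutoff
        lengths = [d.length for c in complexes for s in c.strands for d in s.domains]
        return max(lengths) if lengths else 0


@dataclass(frozen=True)
class CRN:
    """Structures plus typed reactions enumerated from an initial strand set."""

    structures: tuple[Complex, ...]
    reactions: tuple[Reaction, ...]
    initial: tuple[Complex, ...]
    truncated: bool = False
    condensed: bool = False

    def __post_init__(self) -> None:
        known = set(self.structures)
        for r in self.reactions:
            for c in r.reactants + r.products:
                if c not in known:
                    raise ValueError(f"reaction references unknown structure {_ckey(c)}")
        for c in self.initial:
            if c not in known:
                raise ValueError("initial complex missing from structures")

    @property
    def n_structures(self) -> int:
        return len(self.structures)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def structure_keys(self) -> list[str]:
        return [_ckey(c) for c in self.structures]

    # -- serialization ---------------------------------------------------

    def to_json(self, table: DomainTable) -> str:
        doc = {
            "domains": {b: table[b] for b in sorted(table)},
            "initial": [_ckey(c) for c in self.initial],
            "structures": [_ckey(c) for c in self.structures],
            "reactions": [
                {
                    "type": r.rtype,
                    "reactants": [_ckey(c) for c in r.reactants],
                    "products": [_ckey(c) for c in r.products],
                }
                for r in self.reactions
            ],
            "truncated": self.truncated,
            "condensed": self.condensed,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> tuple["CRN", DomainTable]:
        doc = json.loads(text)
        table = DomainTable(doc["domains"])

        def cx(kern: str) -> Complex:
            return canonical_form(parse_kernel(kern, table))

        structures = tuple(cx(k) for k in doc["structures"])
        reactions = tuple(
            Reaction(
                r["type"],
                tuple(cx(k) for k in r["reactants"]),
                tuple(cx(k) for k in r["products"]),
            )
            for r in doc["reactions"]
        )
        crn = cls(
            structures,
            reactions,
            tuple(cx(k) for k in doc["initial"]),
            bool(doc.get("truncated", False)),
            bool(doc.get("condensed", False)),
        )
        return crn, table

    def to_pil(self, table: DomainTable) -> str:
        lines = [f"length {b} = {table[b]}" for b in sorted(table)]
        for i, c in enumerate(self.structures):
            lines.append(f"s{i} = {_ckey(c)}")
        for r in self.reactions:
            lhs = " + ".join(_ckey(c) for c in r.reactants)
            rhs = " + ".join(_ckey(c) for c in r.products)
            lines.append(f"reaction [{r.rtype}] {lhs} -> {rhs}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# move generators
# ---------------------------------------------------------------------------


def single_strand_complex(s: Strand) -> Complex:
    return Complex((s,), frozenset())


def _norm(a: Occ, b: Occ) -> Pair:
    return (a, b) if a <= b else (b, a)


def bind_moves(
    a: Complex, b: Complex | None, params: EnumParams
) -> list[Reaction]:
    """Hybridization: form one new pair between unpaired complements.

    With ``b`` None only intramolecular binds within ``a`` are generated
    (1 -> 1); otherwise one product per admissible intermolecular pairing of
    ``a`` with ``b`` (2 -> 1).  Products must be connected and non-crossing
    under some rotation; crossing candidates are silently discarded.
    """
    out: dict[tuple, Reaction] = {}
    if b is None:
        free = a.unpaired_occs()
        for o1, o2 in combinations(free, 2):
            if a.domain_at(o1).complement != a.domain_at(o2):
                continue
            prod = make_complex(a.strands, set(a.pairs) | {_norm(o1, o2)})
            if prod is None:
                continue
            r = Reaction("bind", (a,), (prod,))
            if not r.is_noop():
                out[r.key] = r
        return sorted(out.values(), key=lambda r: r.key)

    if a.n_strands + b.n_strands > params.max_complex_size:
        return []
    free_a = a.unpaired_occs()
    free_b = b.unpaired_occs()
    na, nb = a.n_strands, b.n_strands
    for oa in free_a:
        da = a.domain_at(oa)
        for ob in free_b:
            if da.complement != b.domain_at(ob):
                continue
            # insert b (under each of its rotations) as a contiguous block
            for rb in range(nb):
                b_strands = b.strands[rb:] + b.strands[:rb]
                b_pairs = [
                    _norm(((si - rb) % nb, pi), ((sj - rb) % nb, pj))
                    for (si, pi), (sj, pj) in b.pairs
                ]
                ob_rot = ((ob[0] - rb) % nb, ob[1])
                for ins in range(na + 1):
                    strands = a.strands[:ins] + b_strands + a.strands[ins:]

                    def remap_a(o: Occ) -> Occ:
                        return (o[0] if o[0] < ins else o[0] + nb, o[1])

                    def remap_b(o: Occ) -> Occ:
                        return (o[0] + ins, o[1])

                    pairs = {_norm(remap_a(x), remap_a(y)) for x, y in a.pairs}
                    pairs |= {_norm(remap_b(x), remap_b(y)) for x, y in b_pairs}
                    pairs.add(_norm(remap_a(oa), remap_b(ob_rot)))
                    prod = make_complex(strands, pairs)
                    if prod is None:
                        continue
                    r = Reaction("bind", (a, b), (prod,))
                    if not r.is_noop():
                        out[r.key] = r
    return sorted(out.values(), key=lambda r: r.key)


def _split_products(
    strands: tuple[Strand, ...], pairs: set[Pair]
) -> list[Complex] | None:
    """Connected components as canonical sub-complexes (relative order kept)."""
    n = len(strands)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for (si, _), (sj, _) in pairs:
        g.add_edge(si, sj)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort()
    products = []
    for comp in comps:
        remap = {old: new for new, old in enumerate(comp)}
        sub_strands = tuple(strands[i] for i in comp)
        sub_pairs = {
            _norm((remap[si], pi), (remap[sj], pj))
            for (si, pi), (sj, pj) in pairs
            if si in remap and sj in remap
        }
        sub = make_complex(sub_strands, sub_pairs)
        if sub is None:
            return None
        products.append(sub)
    return products


def _rewrite(
    c: Complex, new_pairs: set[Pair], rtype: str
) -> Reaction | None:
    """Build the reaction c -> products for a rewritten pair set."""
    products = _split_products(c.strands, new_pairs)
    if products is None:
        return None
    r = Reaction(rtype, (c,), tuple(products))
    return None if r.is_noop() else r


def open_moves(c: Complex, params: EnumParams) -> list[Reaction]:
    """Dissociation: remove one pair whose domain length <= release cutoff."""
    cutoff = params.cutoff_for([c])
    out: dict[tuple, Reaction] = {}
    for pair in c.pairs:
        if c.domain_at(pair[0]).length > cutoff:
            continue
        r = _rewrite(c, set(c.pairs) - {pair}, "open")
        if r is not None:
            out[r.key] = r
    return sorted(out.values(), key=lambda r: r.key)


def branch3_moves(c: Complex, params: EnumParams) -> list[Reaction]:
    """Three-way branch migration.

    Pattern: an unpaired domain x at (s, p) sits next to an anchor pair
    along its strand; on the partner strand, the helix-continuation
    position holds x's complement, currently paired to another occurrence
    of x's type.  The move re-points that complement onto x.  Remote
    (non-adjacent) invasions are not generated.
    """
    paired = c.paired
    out: dict[tuple, Reaction] = {}
    for x in c.unpaired_occs():
        s, p = x
        dx = c.domain_at(x)
        for direction in (1, -1):
            anchor = (s, p - direction)
            if anchor[1] < 0 or anchor[1] >= len(c.strands[s]) or anchor not in paired:
                continue
            t, q = paired[anchor]
            cont = (t, q - direction)  # antiparallel helix continuation
            if cont[1] < 0 or cont[1] >= len(c.strands[t]):
                continue
            if c.domain_at(cont) != dx.complement:
                continue
            x_old = paired.get(cont)
            if x_old is None or x_old == x:
                continue
            new_pairs = set(c.pairs) - {_norm(cont, x_old)} | {_norm(cont, x)}
            r = _rewrite(c, new_pairs, "branch3")
            if r is not None:
                out[r.key] = r
    return sorted(out.values(), key=lambda r: r.key)


def _pair_tree(lin: list[tuple[int, int]]) -> dict[tuple[int, int], tuple[int, int] | None]:
    """Immediate enclosing pair for each pair of a non-crossing linearization."""
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    stack: list[tuple[int, int]] = []
    events = sorted(
        [(i, "o", p) for p in lin for i in (p[0],)]
        + [(j, "c", p) for p in lin for j in (p[1],)]
    )
    for _, kind, p in events:
        if kind == "o":
            parent[p] = stack[-1] if stack else None
            stack.append(p)
        else:
            stack.pop()
    return parent


def branch4_moves(c: Complex, params: EnumParams) -> list[Reaction]:
    """Four-way branch migration: partner exchange at a junction.

    Two pairs of the same base domain type that border a common loop
    (siblings under one enclosing pair, or immediate parent/child) exchange
    partners.  Pure helix stacking is excluded by requiring material (other
    occurrences or a strand break) in both connecting gaps of the loop.
    """
    out: dict[tuple, Reaction] = {}
    n = c.n_strands
    for k in c.valid_rotations():
        rc = c.rotate(k)
        offs = []
        total = 0
        for s in rc.strands:
            offs.append(total)
            total += len(s)

        def linpos(o: Occ) -> int:
            return offs[o[0]] + o[1]

        def occ_of(lp: int) -> Occ:
            for si in range(len(offs) - 1, -1, -1):
                if lp >= offs[si]:
                    return (si, lp - offs[si])
            raise AssertionError

        def gap_nonempty(u: int, v: int) -> bool:
            """Material strictly between linear positions u < v, or a break."""
            if v > u + 1:
                return True
            return occ_of(u)[0] != occ_of(v)[0]

        lin = {}
        for pair in rc.pairs:
            i, j = sorted(linpos(o) for o in pair)
            lin[(i, j)] = pair
        parent = _pair_tree(sorted(lin))
        plist = sorted(lin)
        for p1, p2 in combinations(plist, 2):
            i1, j1 = p1
            i2, j2 = p2
            base1 = rc.domain_at(occ_of(i1)).base
            if base1 != rc.domain_at(occ_of(i2)).base:
                continue
            new_lin: list[tuple[int, int]] | None = None
            if parent.get(p1) == parent.get(p2) and j1 < i2:
                # siblings on a common loop
                if rc.domain_at(occ_of(i1)) != rc.domain_at(occ_of(i2)):
                    continue
                if not gap_nonempty(j1, i2):
                    continue
                if parent.get(p1) is None:
                    # top level: the outer face must also hold material or a
                    # strand break, otherwise this is coaxial stacking
                    outer = i1 > 0 or j2 < total - 1 or len(rc.strands) > 1
                    if not outer:
                        continue
                new_lin = [(i1, j2), (j1, i2)]
            elif parent.get(p2) == p1:
                # immediate parent/child bordering the same internal loop
                if rc.domain_at(occ_of(i2)) != rc.domain_at(occ_of(j1)):
                    continue
                if not (gap_nonempty(i1, i2) and gap_nonempty(j2, j1)):
                    continue
                new_lin = [(i1, i2), (j2, j1)]
            if new_lin is None:
                continue
            new_pairs = set(rc.pairs) - {lin[p1], lin[p2]}
            ok = True
            for u, v in new_lin:
                ou, ov = occ_of(u), occ_of(v)
                if rc.domain_at(ou).complement != rc.domain_at(ov):
                    ok = False
                    break
                new_pairs.add(_norm(ou, ov))
            if not ok:
                continue
            products = _split_products(rc.strands, new_pairs)
            if products is None:
                continue
            r = Reaction("branch4", (canonical_form(c),), tuple(products))
            if not r.is_noop():
                out[r.key] = r
    return sorted(out.values(), key=lambda r: r.key)


# ---------------------------------------------------------------------------
# closure, classification, condensation
# ---------------------------------------------------------------------------


def _unimolecular_moves(c: Complex, params: EnumParams) -> list[Reaction]:
    moves = bind_moves(c, None, params)
    moves += open_moves(c, params)
    moves += branch3_moves(c, params)
    moves += branch4_moves(c, params)
    return moves


def _classify(
    structures: Iterable[Complex], reactions: Iterable[Reaction]
) -> dict[Complex, bool]:
    """Map complex -> is_transient under the module's resting semantics."""
    structures = list(structures)
    fast11 = nx.DiGraph()
    fast11.add_nodes_from(structures)
    split_exit: set[Complex] = set()
    one_one_exit: set[Complex] = set()
    for r in reactions:
        if not r.is_fast:
            continue
        src = r.reactants[0]
        if len(r.products) == 1:
            fast11.add_edge(src, r.products[0])
            one_one_exit.add(src)
        else:
            split_exit.add(src)
    scc_of: dict[Complex, int] = {}
    sccs = list(nx.strongly_connected_components(fast11))
    for i, comp in enumerate(sccs):
        for node in comp:
            scc_of[node] = i
    scc_outgoing = set()
    for u, v in fast11.edges:
        if scc_of[u] != scc_of[v]:
            scc_outgoing.add(scc_of[u])
    return {
        c: (scc_of[c] in scc_outgoing) or (c in split_exit and c in one_one_exit)
        for c in structures
    }


def enumerate_detailed(
    strands: Sequence[Strand], params: EnumParams = EnumParams()
) -> CRN:
    """Breadth-first closure producing the detailed (uncondensed) CRN.

    Deterministic: work queues are processed in canonical kernel order.
    When ``transient_policy`` is on, complexes currently classified as
    transient do not take part in bimolecular binds (initial strands are
    exempt).  Caps set ``truncated`` rather than raising.
    """
    if not strands:
        raise ValueError("need at least one strand")
    initial = tuple(
        dict.fromkeys(canonical_form(single_strand_complex(s)) for s in strands)
    )
    structures: dict[Complex, None] = dict.fromkeys(initial)
    reactions: dict[tuple, Reaction] = {}
    uni_done: set[Complex] = set()
    bim_done: set[tuple[str, str]] = set()
    truncated = False

    def overflow() -> bool:
        return (
            len(structures) > params.max_structures
            or len(reactions) > params.max_reactions
        )

    def add_structure(c: Complex) -> None:
        if c not in structures:
            structures[c] = None

    while True:
        progress = False
        # unimolecular closure
        while True:
            todo = sorted(
                (c for c in structures if c not in uni_done), key=_ckey
            )
            if not todo or truncated:
                break
            for c in todo:
                uni_done.add(c)
                for r in _unimolecular_moves(c, params):
                    if r.key in reactions:
                        continue
                    reactions[r.key] = r
                    progress = True
                    for p in r.products:
                        add_structure(p)
                    if overflow():
                        truncated = True
                        break
                if truncated:
                    break
        if truncated:
            break
        # classification gates bimolecular reactions
        if params.transient_policy:
            transient = _classify(structures, reactions.values())
        else:
            transient = {c: False for c in structures}
        reactors = sorted(
            (c for c in structures if (not transient[c]) or c in initial),
            key=_ckey,
        )
        for i, a in enumerate(reactors):
            for b in reactors[i:]:
                sig = (_ckey(a), _ckey(b))
                if sig in bim_done:
                    continue
                bim_done.add(sig)
                for r in bind_moves(a, b, params):
                    if r.key in reactions:
                        continue
                    reactions[r.key] = r
                    progress = True
                    for p in r.products:
                        add_structure(p)
                    if overflow():
                        truncated = True
                        break
                if truncated:
                    break
            if truncated:
                break
        if truncated or not progress:
            break

    ordered = _sorted_side(structures)
    rlist = tuple(sorted(reactions.values(), key=lambda r: r.key))
    return CRN(ordered, rlist, initial, truncated=truncated, condensed=False)


def _fates(
    start: Complex,
    transient: dict[Complex, bool],
    fast_by_src: dict[Complex, list[Reaction]],
    initial: set[Complex],
    max_fates: int,
) -> tuple[set[tuple[Complex, ...]], bool]:
    """Multisets of kept complexes reachable from ``start`` via fast moves."""
    kept = lambda c: (not transient.get(c, False)) or c in initial
    fates: set[tuple[Complex, ...]] = set()
    seen: set[tuple[Complex, ...]] = set()
    stack: list[tuple[Complex, ...]] = [(start,)]
    overflow = False
    while stack:
        state = stack.pop()
        if state in seen:
            continue
        seen.add(state)
        if len(seen) > 50 * max(1, max_fates):
            overflow = True
            break
        expand_idx = next(
            (i for i, c in enumerate(state) if not kept(c)), None
        )
        if expand_idx is None:
            fates.add(state)
            if len(fates) >= max_fates:
                overflow = True
                break
            continue
        c = state[expand_idx]
        rest = state[:expand_idx] + state[expand_idx + 1 :]
        for r in fast_by_src.get(c, []):
            nxt = tuple(sorted(rest + r.products, key=_ckey))
            stack.append(nxt)
    return fates, overflow


def condense(detailed: CRN, params: EnumParams = EnumParams()) -> CRN:
    """Collapse transient complexes, rewiring reactions onto kept complexes.

    Kept complexes are the resting ones plus the initial strands.  A
    detailed reaction between kept complexes survives as-is; transient
    products are replaced by every multiset of kept complexes reachable
    from them through fast reactions (their fates).  No-op reactions are
    dropped.
    """
    transient = _classify(detailed.structures, detailed.reactions)
    initial = set(detailed.initial)
    kept = [c for c in detailed.structures if (not transient[c]) or c in initial]
    kept_set = set(kept)
    fast_by_src: dict[Complex, list[Reaction]] = {}
    for r in detailed.reactions:
        if r.is_fast:
            fast_by_src.setdefault(r.reactants[0], []).append(r)
    for v in fast_by_src.values():
        v.sort(key=lambda r: r.key)

    out: dict[tuple, Reaction] = {}
    truncated = detailed.truncated
    fate_cache: dict[Complex, set[tuple[Complex, ...]]] = {}

    def fates_of(c: Complex) -> set[tuple[Complex, ...]]:
        nonlocal truncated
        if c not in fate_cache:
            f, overflow = _fates(c, transient, fast_by_src, initial, params.max_fates)
            truncated = truncated or overflow
            fate_cache[c] = f
        return fate_cache[c]

    for r in detailed.reactions:
        if any(c not in kept_set for c in r.reactants):
            continue
        options: list[list[tuple[Complex, ...]]] = []
        feasible = True
        for p in r.products:
            if p in kept_set:
                options.append([(p,)])
            else:
                f = sorted(fates_of(p), key=lambda ms: tuple(map(_ckey, ms)))
                if not f:
                    feasible = False
                    break
                options.append(f)
        if not feasible:
            continue
        for combo in iproduct(*options):
            prods = tuple(sorted((c for part in combo for c in part), key=_ckey))
            cand = Reaction(r.rtype, r.reactants, prods)
            if not cand.is_noop():
                out[cand.key] = cand
    rlist = tuple(sorted(out.values(), key=lambda r: r.key))
    return CRN(
        _sorted_side(kept),
        rlist,
        detailed.initial,
        truncated=truncated,
        condensed=True,
    )


def enumerate_crn(
    strands: Sequence[Strand], params: EnumParams = EnumParams()
) -> CRN:
    """Enumerate and (when ``transient_policy`` is on) condense the CRN."""
    detailed = enumerate_detailed(strands, params)
    if params.transient_policy:
        return condense(detailed, params)
    return detailed


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def crn_metrics(crn: CRN) -> dict[str, float]:
    """Summary statistics used as MAP-Elites descriptors and fitnesses.

    ``mss`` (mean structure size) averages strand counts over all
    structures; ``ert`` is the Shannon entropy (bits) of the reaction-type
    distribution, zero when there is at most one reaction.
    """
    if not crn.structures:
        raise ValueError("empty CRN")
    n_structures = crn.n_structures
    n_reactions = crn.n_reactions
    mss = sum(c.n_strands for c in crn.structures) / n_structures
    if n_reactions <= 1:
        ert = 0.0
    else:
        counts: dict[str, int] = {}
        for r in crn.reactions:
            counts[r.rtype] = counts.get(r.rtype, 0) + 1
        total = sum(counts.values())
        ert = -sum((k / total) * log2(k / total) for k in counts.values())
    return {
        "n_structures": n_structures,
        "n_reactions": n_reactions,
        "mss": mss,
        "ert": ert,
    }


def reversible_pairs(crn: CRN) -> int:
    """Count reactions that come with an exact reverse partner (pairs)."""
    sides = {
        (tuple(map(_ckey, r.reactants)), tuple(map(_ckey, r.products)))
        for r in crn.reactions
    }
    count = 0
    for lhs, rhs in sides:
        if (rhs, lhs) in sides and (lhs, rhs) <= (rhs, lhs):
            count += 1
    return count
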