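"""Independent brute-force oracles for the move generators and graph metrics.

These deliberately re-derive results with naive exhaustive search (all
permutations, all rewrites, direct scans) rather than the production code
paths, and are compared against the package implementations in the suite.
"""

from itertools import combinations, permutations

import networkx as nx

from strandscape.kernel_model import Complex, canonical_form

RxnKey = tuple[tuple[str, ...], tuple[str, ...]]


def _kernels(cs) -> tuple[str, ...]:
    return tuple(sorted(canonical_form(c).kernel for c in cs))


def _crossing(strand_lens, pairs) -> bool:
    offs, total = [], 0
    for L in strand_lens:
        offs.append(total)
        total += L
    lin = []
    for (si, pi), (sj, pj) in pairs:
        a, b = offs[si] + pi, offs[sj] + pj
        lin.append((min(a, b), max(a, b)))
    for i, (a1, b1) in enumerate(lin):
        for a2, b2 in lin[i + 1 :]:
            if a1 < a2 < b1 < b2 or a2 < a1 < b2 < b1:
                return True
    return False


def _components(n, pairs):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((si, sj) for (si, _), (sj, _) in pairs)
    return [sorted(c) for c in nx.connected_components(g)]


def _products_of(strands, pairs):
    """Split into canonical connected components; None when any is crossing."""
    comps = _components(len(strands), pairs)
    out = []
    for comp in comps:
        remap = {old: new for new, old in enumerate(comp)}
        sub_strands = tuple(strands[i] for i in comp)
        sub_pairs = {
            tuple(sorted(((remap[si], pi), (remap[sj], pj))))
            for (si, pi), (sj, pj) in pairs
            if si in remap and sj in remap
        }
        if _crossing([len(s) for s in sub_strands], sub_pairs):
            return None
        out.append(canonical_form(Complex(sub_strands, frozenset(sub_pairs))))
    return out


def _rewrite_key(reactants, strands, pairs) -> RxnKey | None:
    prods = _products_of(strands, pairs)
    if prods is None:
        return None
    key = (_kernels(reactants), _kernels(prods))
    if key[0] == key[1]:
        return None  # no-op
    return key


def _free(c: Complex):
    taken = c.paired
    return [
        (si, pi)
        for si, s in enumerate(c.strands)
        for pi in range(len(s))
        if (si, pi) not in taken
    ]


def oracle_bind(a: Complex, b: Complex | None, max_complex_size: int) -> set[RxnKey]:
    """Every single pair addition; intermolecular over ALL interleavings."""
    out: set[RxnKey] = set()
    if b is None:
        for o1, o2 in combinations(_free(a), 2):
            if a.domain_at(o1).complement != a.domain_at(o2):
                continue
            pairs = set(a.pairs) | {tuple(sorted((o1, o2)))}
            if _crossing([len(s) for s in a.strands], pairs):
                continue
            key = _rewrite_key([a], a.strands, pairs)
            if key:
                out.add(key)
        return out
    if a.n_strands + b.n_strands > max_complex_size:
        return out
    instances = [("a", i) for i in range(a.n_strands)] + [
        ("b", j) for j in range(b.n_strands)
    ]
    for perm in permutations(instances):
        pos = {inst: k for k, inst in enumerate(perm)}
        strands = tuple(
            (a if src == "a" else b).strands[i] for src, i in perm
        )

        def remap(src, occ):
            return (pos[(src, occ[0])], occ[1])

        base = {
            tuple(sorted((remap("a", x), remap("a", y)))) for x, y in a.pairs
        } | {tuple(sorted((remap("b", x), remap("b", y)))) for x, y in b.pairs}
        for oa in _free(a):
            da = a.domain_at(oa)
            for ob in _free(b):
                if da.complement != b.domain_at(ob):
                    continue
                pairs = base | {
                    tuple(sorted((remap("a", oa), remap("b", ob))))
                }
                if _crossing([len(s) for s in strands], pairs):
                    continue
                if len(_components(len(strands), pairs)) != 1:
                    continue
                key = _rewrite_key([a, b], strands, pairs)
                if key:
                    out.add(key)
    return out


def oracle_open(c: Complex, release_cutoff: int) -> set[RxnKey]:
    """Every single pair removal gated by the release cutoff."""
    out: set[RxnKey] = set()
    for pair in c.pairs:
        if c.domain_at(pair[0]).length > release_cutoff:
            continue
        key = _rewrite_key([c], c.strands, set(c.pairs) - {pair})
        if key:
            out.add(key)
    return out


def oracle_branch3(c: Complex) -> set[RxnKey]:
    """Every adjacent-anchor displacement, found by scanning all triples."""
    out: set[RxnKey] = set()
    paired = c.paired
    for x in _free(c):
        s, p = x
        dx = c.domain_at(x)
        for y, x_old in paired.items():
            # y must hold x's complement and currently pair x_old
            if c.domain_at(y) != dx.complement or x_old == x:
                continue
            for d in (1, -1):
                anchor = (s, p - d)
                if anchor[1] < 0 or anchor[1] >= len(c.strands[s]):
                    continue
                if paired.get(anchor) != (y[0], y[1] + d):
                    continue
                pairs = set(c.pairs)
                pairs.discard(tuple(sorted((y, x_old))))
                pairs.add(tuple(sorted((y, x))))
                key = _rewrite_key([c], c.strands, pairs)
                if key:
                    out.add(key)
    return out


def oracle_branch4(c: Complex) -> set[RxnKey]:
    """Every partner exchange between same-type pairs on a common loop."""
    out: set[RxnKey] = set()
    n = c.n_strands
    for k in range(n):
        strands = c.strands[k:] + c.strands[:k]
        rot_pairs = {
            tuple(
                sorted((((si - k) % n, pi), ((sj - k) % n, pj)))
            )
            for (si, pi), (sj, pj) in c.pairs
        }
        offs, total = [], 0
        for s in strands:
            offs.append(total)
            total += len(s)

        def lp(occ):
            return offs[occ[0]] + occ[1]

        def occ_at(x):
            for si in range(len(offs) - 1, -1, -1):
                if x >= offs[si]:
                    return (si, x - offs[si])

        intervals = {tuple(sorted((lp(p[0]), lp(p[1])))): p for p in rot_pairs}

        def parent_of(iv):
            best = None
            for other in intervals:
                if other == iv:
                    continue
                if other[0] < iv[0] and iv[1] < other[1]:
                    if best is None or (other[0] > best[0]):
                        best = other
            return best

        def gap(u, v):
            return v > u + 1 or occ_at(u)[0] != occ_at(v)[0]

        for iv1, iv2 in combinations(sorted(intervals), 2):
            i1, j1 = iv1
            i2, j2 = iv2
            dom_i1 = strands[occ_at(i1)[0]].domains[occ_at(i1)[1]]
            dom_i2 = strands[occ_at(i2)[0]].domains[occ_at(i2)[1]]
            dom_j1 = strands[occ_at(j1)[0]].domains[occ_at(j1)[1]]
            dom_j2 = strands[occ_at(j2)[0]].domains[occ_at(j2)[1]]
            if dom_i1.base != dom_i2.base:
                continue
            new = None
            if parent_of(iv1) == parent_of(iv2) and j1 < i2:
                if dom_i1 == dom_i2 and gap(j1, i2):
                    outer = (
                        parent_of(iv1) is not None
                        or i1 > 0
                        or j2 < total - 1
                        or len(strands) > 1
                    )
                    if outer:
                        new = [(i1, j2), (j1, i2)]
            elif parent_of(iv2) == iv1:
                if dom_i2 == dom_j1 and gap(i1, i2) and gap(j2, j1):
                    new = [(i1, i2), (j2, j1)]
            if new is None:
                continue
            pairs = set(rot_pairs) - {intervals[iv1], intervals[iv2]}
            ok = True
            for u, v in new:
                ou, ov = occ_at(u), occ_at(v)
                du = strands[ou[0]].domains[ou[1]]
                dv = strands[ov[0]].domains[ov[1]]
                if du.complement != dv:
                    ok = False
                    break
                pairs.add(tuple(sorted((ou, ov))))
            if not ok:
                continue
            key = _rewrite_key([c], strands, pairs)
            if key:
                out.add(key)
    return out


# ---------------------------------------------------------------------------
# graph metric oracles (naive implementations for <= 12-node graphs)
# ---------------------------------------------------------------------------


def oracle_betweenness(g: nx.DiGraph) -> dict:
    """Unnormalized betweenness by explicit shortest-path enumeration."""
    nodes = list(g.nodes)
    nb = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for v in path[1:-1]:
                    nb[v] += 1.0 / len(paths)
    return nb


def oracle_edge_betweenness(g: nx.DiGraph) -> dict:
    eb = {e: 0.0 for e in g.edges}
    nodes = list(g.nodes)
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for e in zip(path, path[1:]):
                    eb[e] += 1.0 / len(paths)
    return eb


def oracle_flow_hierarchy(g: nx.DiGraph) -> float:
    """Fraction of edges on no cycle, by explicit cycle-membership search."""
    if g.number_of_edges() == 0:
        return 1.0
    on_cycle = 0
    for u, v in g.edges:
        # edge is on a cycle iff v can reach u
        if u == v or nx.has_path(g, v, u):
            on_cycle += 1
    return 1.0 - on_cycle / g.number_of_edges()


def oracle_grc(g: nx.DiGraph) -> float:
    n = g.number_of_nodes()
    reach = []
    for v in g.nodes:
        seen = {v}
        stack = [v]
        while stack:
            u = stack.pop()
            for w in g.successors(u):
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        reach.append((len(seen) - 1) / (n - 1))
    mx = max(reach)
    return sum(mx - r for r in reach) / (n - 1)


def oracle_clustering_mean(g: nx.Graph) -> float:
    """Mean local clustering by explicit triangle counting."""
    vals = []
    for v in g.nodes:
        nbrs = [u for u in g.neighbors(v) if u != v]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(
            1 for x, y in combinations(nbrs, 2) if g.has_edge(x, y)
        )
        vals.append(2.0 * links / (k * (k - 1)))
    return sum(vals) / len(vals)


def oracle_density(g: nx.DiGraph) -> float:
    n = g.number_of_nodes()
    return g.number_of_edges() / (n * (n - 1))
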