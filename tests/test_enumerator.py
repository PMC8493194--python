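"""Move generators, enumeration closure, condensation and CRN metrics."""

from itertools import combinations

import pytest

from strandscape.kernel_model import Complex, Strand, canonical_form, parse_kernel
from strandscape.enumerator import (
    CRN,
    EnumParams,
    Reaction,
    bind_moves,
    branch3_moves,
    branch4_moves,
    condense,
    crn_metrics,
    enumerate_crn,
    enumerate_detailed,
    open_moves,
    reversible_pairs,
    single_strand_complex,
)
import oracles
from conftest import crossing_pairs_bruteforce

P2 = EnumParams(max_complex_size=2)
P3 = EnumParams(max_complex_size=3)


def kernels(crn):
    return [c.kernel for c in crn.structures]


def rxn_keys(moves):
    return {
        (
            tuple(sorted(c.kernel for c in r.reactants)),
            tuple(sorted(c.kernel for c in r.products)),
        )
        for r in moves
    }


class TestBind:
    def test_intramolecular_hairpin(self, table10, fig1_strand):
        c = single_strand_complex(fig1_strand)
        moves = bind_moves(c, None, P2)
        assert len(moves) == 1
        assert moves[0].products[0].kernel == "a( )"
        assert moves[0].rtype == "bind"

    def test_intermolecular_duplex_seed(self, fig1_strand):
        c = canonical_form(single_strand_complex(fig1_strand))
        moves = bind_moves(c, c, P2)
        # one distinct product: the single-pair two-strand intermediate
        prods = {r.products[0].kernel for r in moves}
        assert prods == {"a a*( + ) a*"}

    def test_orthogonal_none(self, table10):
        a = single_strand_complex(Strand((table10.domain("a"), table10.domain("b"))))
        b = single_strand_complex(
            Strand((table10.domain("a"), table10.domain("b")))
        )
        assert bind_moves(a, None, P2) == []
        # a/b vs itself: a can bind nothing (no complements anywhere)
        assert bind_moves(a, b, P2) == []

    def test_size_cap(self, fig1_strand):
        c = canonical_form(single_strand_complex(fig1_strand))
        assert bind_moves(c, c, EnumParams(max_complex_size=1)) == []


class TestOpen:
    def test_hairpin_opens(self, table10):
        c = parse_kernel("a( )", table10)
        moves = open_moves(c, EnumParams(max_complex_size=2, release_cutoff=10))
        assert len(moves) == 1
        assert moves[0].products[0].kernel == "a a*"

    def test_cutoff_gate(self, table10):
        duplex = parse_kernel("a( + )", table10)
        assert open_moves(duplex, EnumParams(release_cutoff=9)) == []
        assert len(open_moves(duplex, EnumParams(release_cutoff=10))) == 1

    def test_duplex_single_pair_openings(self, table10):
        """Hand enumeration: both pair removals give the same canonical
        connected 2-strand intermediate -> one distinct open move."""
        duplex = parse_kernel("a( a*( + ) )", table10)
        moves = open_moves(duplex, P2)
        assert len(moves) == 1
        (r,) = moves
        assert len(r.products) == 1
        assert r.products[0].n_strands == 2
        assert len(r.products[0].pairs) == 1

    def test_default_cutoff_is_max_domain_length(self, table10):
        duplex = parse_kernel("a( + )", table10)
        assert len(open_moves(duplex, EnumParams())) == 1


class TestBranch3:
    def test_toehold_displacement(self, table_many):
        t = table_many
        invader = Strand((t.domain("t"), t.domain("x")))
        incumbent = Strand((t.domain("x"),))
        substrate = Strand((t.domain("x*"), t.domain("t*")))
        c = Complex(
            (invader, incumbent, substrate),
            frozenset({((0, 0), (2, 1)), ((1, 0), (2, 0))}),
        )
        moves = branch3_moves(canonical_form(c), EnumParams())
        assert len(moves) == 1
        (r,) = moves
        assert {p.kernel for p in r.products} == {"t( x( + ) )", "x"}

    def test_hairpin_no_invader(self, table10):
        assert branch3_moves(parse_kernel("a( )", table10), P2) == []

    def test_noop_suppressed(self, table10):
        """Symmetric displacement regenerating an isomorphic complex is
        filtered out (only productive rearrangements are kept)."""
        c = parse_kernel("a* a( ) a", table10)
        moves = branch3_moves(c, EnumParams())
        for r in moves:
            assert sorted(p.kernel for p in r.products) != [c.kernel]


class TestBranch4:
    def test_holliday_single_exchange(self, holliday):
        moves = branch4_moves(canonical_form(holliday), EnumParams())
        assert len(moves) == 1
        assert moves[0].rtype == "branch4"
        # the junction resolves into two duplexes
        assert len(moves[0].products) == 2

    def test_holliday_matches_bruteforce(self, holliday):
        got = rxn_keys(branch4_moves(canonical_form(holliday), EnumParams()))
        assert got == oracles.oracle_branch4(canonical_form(holliday))

    def test_too_few_pairs(self, table10):
        assert branch4_moves(parse_kernel("a( )", table10), P2) == []

    def test_duplex_no_junction(self, table10):
        assert branch4_moves(parse_kernel("a( a*( + ) )", table10), P2) == []


class TestEnumerate:
    def test_fig1_condensed(self, fig1_strand):
        crn = enumerate_crn([fig1_strand], EnumParams(max_complex_size=2, release_cutoff=10))
        assert sorted(kernels(crn)) == ["a a*", "a( )", "a( a*( + ) )"]
        assert crn.n_reactions == 4
        assert reversible_pairs(crn) == 2
        assert not crn.truncated

    def test_orthogonal_strand_alone(self, table10):
        s = Strand((table10.domain("a"), table10.domain("b")))
        crn = enumerate_crn([s], P2)
        assert kernels(crn) == ["a b"]
        assert crn.n_reactions == 0

    def test_two_single_domain_strands(self):
        from strandscape.kernel_model import DomainTable

        t = DomainTable({"a": 10})
        sa = Strand((t.domain("a"),))
        sb = Strand((t.domain("a*"),))
        crn = enumerate_crn([sa, sb], P2)
        assert sorted(kernels(crn)) == ["a", "a( + )", "a*"]
        assert reversible_pairs(crn) == 1

    def test_truncation_flag(self, fig1_strand):
        params = EnumParams(max_complex_size=6, max_structures=3)
        crn = enumerate_detailed([fig1_strand], params)
        assert crn.truncated

    def test_initial_in_structures(self, toy21_library):
        for s in toy21_library.strands:
            crn = enumerate_crn([s], P3)
            assert set(c.kernel for c in crn.initial) <= set(kernels(crn))


class TestCondense:
    def test_identity_when_all_resting(self, table10):
        s = Strand((table10.domain("a"), table10.domain("b")))
        det = enumerate_detailed([s], P2)
        cond = condense(det, P2)
        assert kernels(cond) == kernels(det)
        assert len(cond.reactions) == len(det.reactions)

    def test_fig1_intermediate_transient(self, fig1_strand):
        det = enumerate_detailed([fig1_strand], EnumParams(max_complex_size=2))
        cond = condense(det, EnumParams(max_complex_size=2))
        assert "a a*( + ) a*" in kernels(det)
        assert "a a*( + ) a*" not in kernels(cond)
        # the condensed duplex path is 2 aa* -> aa*.aa*
        duplex_rxns = [
            r
            for r in cond.reactions
            if len(r.reactants) == 2 and r.products[0].kernel == "a( a*( + ) )"
        ]
        assert len(duplex_rxns) == 1

    def test_fast_chain_condenses_to_endpoints(self, table10):
        """A -> B -> C via fast 1->1 reactions: B is condensed away."""
        x = Strand(
            (
                table10.domain("a"),
                table10.domain("a*"),
                table10.domain("a"),
                table10.domain("a*"),
            )
        )
        cA = canonical_form(Complex((x,), frozenset()))
        cB = canonical_form(Complex((x,), frozenset({((0, 0), (0, 1))})))
        cC = canonical_form(Complex((x,), frozenset({((0, 0), (0, 3))})))
        det = CRN(
            (cA, cB, cC),
            (Reaction("bind", (cA,), (cB,)), Reaction("branch3", (cB,), (cC,))),
            (cA,),
        )
        cond = condense(det, EnumParams())
        assert set(kernels(cond)) == {cA.kernel, cC.kernel}
        assert len(cond.reactions) == 1
        assert cond.reactions[0].reactants == (cA,)
        assert cond.reactions[0].products == (cC,)


class TestMetrics:
    def test_fig1_counts(self, fig1_strand):
        crn = enumerate_crn([fig1_strand], EnumParams(max_complex_size=2))
        m = crn_metrics(crn)
        assert m["n_structures"] == 3
        assert m["mss"] == pytest.approx(4 / 3)

    def test_ert_two_types_uniform(self, table10):
        s = Strand((table10.domain("a"), table10.domain("a*")))
        cS = canonical_form(single_strand_complex(s))
        cH = canonical_form(Complex((s,), frozenset({((0, 0), (0, 1))})))
        crn = CRN(
            (cS, cH),
            (Reaction("bind", (cS,), (cH,)), Reaction("open", (cH,), (cS,))),
            (cS,),
        )
        assert crn_metrics(crn)["ert"] == pytest.approx(1.0)

    def test_ert_four_types_uniform(self, table10):
        x = Strand(
            (
                table10.domain("a"),
                table10.domain("a*"),
                table10.domain("a"),
                table10.domain("a*"),
            )
        )
        c0 = canonical_form(Complex((x,), frozenset()))
        c1 = canonical_form(Complex((x,), frozenset({((0, 0), (0, 1))})))
        c2 = canonical_form(Complex((x,), frozenset({((0, 0), (0, 3))})))
        c3 = canonical_form(Complex((x,), frozenset({((0, 2), (0, 3))})))
        crn = CRN(
            (c0, c1, c2, c3),
            (
                Reaction("bind", (c0,), (c1,)),
                Reaction("open", (c1,), (c0,)),
                Reaction("branch3", (c1,), (c2,)),
                Reaction("branch4", (c2,), (c3,)),
            ),
            (c0,),
        )
        assert crn_metrics(crn)["ert"] == pytest.approx(2.0)

    def test_single_reaction_zero_entropy(self, table10):
        s = Strand((table10.domain("a"), table10.domain("a*")))
        cS = canonical_form(single_strand_complex(s))
        cH = canonical_form(Complex((s,), frozenset({((0, 0), (0, 1))})))
        crn = CRN((cS, cH), (Reaction("bind", (cS,), (cH,)),), (cS,))
        assert crn_metrics(crn)["ert"] == 0.0


class TestInvariants:
    def test_strand_conservation_enforced(self, table10, fig1_strand):
        cS = canonical_form(single_strand_complex(fig1_strand))
        cH = parse_kernel("a( )", table10)
        with pytest.raises(ValueError, match="conserved"):
            Reaction("bind", (cS, cS), (canonical_form(cH),))

    def test_conservation_on_enumerated_networks(self, toy21_library):
        for idx in combinations(range(4), 2):
            det = enumerate_detailed(
                [toy21_library.strands[i] for i in idx], P3
            )
            for r in det.reactions:
                rs = sorted(s.name for c in r.reactants for s in c.strands)
                ps = sorted(s.name for c in r.products for s in c.strands)
                assert rs == ps

    def test_reversibility_of_binds(self, toy21_library):
        """With the cutoff at the max domain length every bind has a
        matching open between the same species (detailed network)."""
        for idx in combinations(range(4), 2):
            det = enumerate_detailed(
                [toy21_library.strands[i] for i in idx], P3
            )
            sides = {
                (r.rtype,)
                + (
                    tuple(c.kernel for c in r.reactants),
                    tuple(c.kernel for c in r.products),
                )
                for r in det.reactions
            }
            for rtype, lhs, rhs in sides:
                if rtype == "bind":
                    assert ("open", rhs, lhs) in sides

    def test_monotone_in_complex_size(self, toy21_library):
        for idx in [(1,), (1, 2), (0, 3)]:
            strands = [toy21_library.strands[i] for i in idx]
            small = set(kernels(enumerate_detailed(strands, P2)))
            big = set(kernels(enumerate_detailed(strands, P3)))
            assert small <= big

    def test_determinism_byte_identical(self, toy21_library):
        strands = [toy21_library.strands[1], toy21_library.strands[2]]
        table = toy21_library.domain_table()
        a = enumerate_crn(strands, P3).to_json(table)
        b = enumerate_crn(strands, P3).to_json(table)
        assert a == b

    def test_input_order_irrelevant(self, toy21_library):
        s = toy21_library.strands
        a = enumerate_crn([s[1], s[2]], P3)
        b = enumerate_crn([s[2], s[1]], P3)
        assert set(kernels(a)) == set(kernels(b))
        assert {r.key for r in a.reactions} == {r.key for r in b.reactions}

    def test_no_crossing_in_any_structure(self, toy21_library):
        for idx in combinations(range(4), 2):
            det = enumerate_detailed(
                [toy21_library.strands[i] for i in idx], P3
            )
            for c in det.structures:
                assert not crossing_pairs_bruteforce(c)


class TestOracleEquivalence:
    """Generators agree with the exhaustive rewrite oracle on all <= 2-strand
    subsets of the (2, 1) toy library (max complex size 3)."""

    def _systems(self, toy21_library):
        for k in (1, 2):
            for idx in combinations(range(4), k):
                yield [toy21_library.strands[i] for i in idx]

    def test_unimolecular_moves(self, toy21_library):
        for strands in self._systems(toy21_library):
            det = enumerate_detailed(strands, P3)
            cutoff = P3.cutoff_for(det.structures)
            for c in det.structures:
                intra = rxn_keys(bind_moves(c, None, P3))
                assert intra == oracles.oracle_bind(c, None, P3.max_complex_size), c.kernel
                opens = rxn_keys(open_moves(c, P3))
                assert opens == oracles.oracle_open(c, cutoff), c.kernel
                b3 = rxn_keys(branch3_moves(c, P3))
                assert b3 == oracles.oracle_branch3(c), c.kernel
                b4 = rxn_keys(branch4_moves(c, P3))
                assert b4 == oracles.oracle_branch4(c), c.kernel

    def test_bimolecular_moves(self, toy21_library):
        for strands in self._systems(toy21_library):
            det = enumerate_detailed(strands, P3)
            structs = sorted(det.structures, key=lambda c: c.kernel)
            for a in structs:
                for b in structs:
                    if a.n_strands + b.n_strands > 3:
                        continue
                    got = rxn_keys(bind_moves(a, b, P3))
                    expected = oracles.oracle_bind(a, b, P3.max_complex_size)
                    assert got == expected, (a.kernel, b.kernel)


class TestSerialization:
    def test_json_roundtrip(self, toy21_library):
        strands = [toy21_library.strands[1]]
        crn = enumerate_crn(strands, P3)
        table = toy21_library.domain_table()
        again, table2 = CRN.from_json(crn.to_json(table))
        assert kernels(again) == kernels(crn)
        assert {r.key for r in again.reactions} == {r.key for r in crn.reactions}
        assert dict(table2) == dict(table)

    def test_pil_output(self, fig1_strand, table10):
        crn = enumerate_crn([fig1_strand], P2)
        text = crn.to_pil(table10)
        assert "length a = 10" in text
        assert "reaction [bind]" in text
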