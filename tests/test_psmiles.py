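"""Canonicalization: validation, rewriting operations and the
equivalence-class contract."""

from __future__ import annotations

import math

import numpy as np
import pytest
from rdkit import Chem

from polylingua import (PSMILESError, are_same_polymer, canonicalize, cyclize,
                        multiply, rotate, shortest_repeat, validate)
from polylingua.psmiles import _bracket_stars, heavy_atom_count

from conftest import FIXTURE_POLYMERS


def _random_rewriting(p: str, rng: np.random.Generator) -> str:
    """Atom-order permutation of the same repeat unit."""
    mol = Chem.MolFromSmiles(p)
    perm = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
    return _bracket_stars(Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm),
                                           canonical=False))


def _oracle_same(a: str, b: str) -> bool:
    """Brute-force polymer equality: cyclize common multiples (at least
    six-fold) of both units and compare RDKit canonical graphs."""
    na, nb = heavy_atom_count(a), heavy_atom_count(b)
    lcm = max(6 * max(na, nb), math.lcm(na, nb))
    lcm = math.lcm(lcm, na, nb)
    ga = Chem.MolToSmiles(cyclize(multiply(a, lcm // na)).mol)
    gb = Chem.MolToSmiles(cyclize(multiply(b, lcm // nb)).mol)
    return ga == gb


class TestValidate:
    @pytest.mark.parametrize("raw,valid,issue", [
        ("[*]CC[*]", True, None),
        ("CCO", False, "star_count:0"),
        ("[*]C([*])C[*]", False, "star_count:3"),
        ("[*]C(C[*]", False, "parse_error"),
        ("[*][*]", False, "star_star_bond"),
        ("[*]=CC[*]", False, "endpoint_order_mismatch"),
    ])
    def test_reports_violations_without_raising(self, raw, valid, issue):
        rep = validate(raw)
        assert rep.valid is valid
        assert rep.valid == (not rep.issues)
        if issue is not None:
            assert issue in rep.issues

    def test_non_string_input(self):
        assert not validate(None).valid


class TestMultiply:
    def test_nylon6_twofold_matches_handwritten_repeat(self):
        assert multiply("[*]CCCCCC(=O)N[*]", 2) == "[*]CCCCCC(=O)NCCCCCC(=O)N[*]"

    def test_identity_at_k1(self):
        for p in FIXTURE_POLYMERS:
            assert multiply(p, 1) == p

    @pytest.mark.parametrize("k", [2, 3])
    def test_heavy_atoms_scale_and_class_is_preserved(self, k):
        for p in FIXTURE_POLYMERS:
            q = multiply(p, k)
            assert heavy_atom_count(q) == k * heavy_atom_count(p)
            assert canonicalize(q) == canonicalize(p)

    def test_invalid_input_raises(self):
        with pytest.raises(PSMILESError):
            multiply("CCO", 2)


class TestRotate:
    def test_single_shift_of_peo_backbone(self):
        assert rotate("[*]CCO[*]", 1) in {"[*]COC[*]", "[*]OCC[*]"}

    def test_zero_shift_is_identity(self):
        for p in FIXTURE_POLYMERS:
            assert rotate(p, 0) == p

    def test_rotation_preserves_class_and_size(self):
        for p in FIXTURE_POLYMERS:
            for j in range(1, 4):
                r = rotate(p, j)
                assert heavy_atom_count(r) == heavy_atom_count(p)
                assert canonicalize(r) == canonicalize(p)


class TestCyclize:
    def test_peo_gives_three_membered_ring(self):
        per = cyclize("[*]CCO[*]")
        assert per.multiplicity == 1
        symbols = sorted(a.GetSymbol() for a in per.mol.GetAtoms())
        assert symbols == ["C", "C", "O"]
        assert per.mol.GetRingInfo().NumRings() == 1

    def test_two_atom_backbone_multiplies_before_closure(self):
        # closing a 2-atom backbone directly would duplicate an existing
        # bond, which molecular graphs disallow
        per = cyclize("[*]CC([*])c1ccccc1")
        assert per.multiplicity == 2
        assert per.mol.GetBondWithIdx(per.closure_bond) is not None

    def test_mismatched_endpoint_orders_error(self):
        with pytest.raises(PSMILESError):
            cyclize("[*]=CC[*]")


class TestShortestRepeat:
    def test_peo_worked_example(self):
        q = shortest_repeat("[*]CCOCCO[*]")
        assert heavy_atom_count(q) == 3
        assert canonicalize(q) == canonicalize("[*]COC[*]")

    def test_prime_unit_unchanged(self):
        assert shortest_repeat("[*]CCO[*]") == "[*]CCO[*]"

    def test_polyethylene_reduces_to_one_carbon(self):
        q = shortest_repeat("[*]CC[*]")
        assert heavy_atom_count(q) == 1
        assert _oracle_same(q, "[*]CC[*]")

    def test_reduction_agrees_with_graph_oracle(self):
        for p in FIXTURE_POLYMERS[:10]:
            q = shortest_repeat(multiply(p, 2))
            assert _oracle_same(q, p)


class TestCanonicalize:
    def test_peo_example(self):
        assert canonicalize("[*]CCOCCO[*]") == canonicalize("[*]COC[*]")

    def test_idempotent(self):
        for p in FIXTURE_POLYMERS:
            c = canonicalize(p)
            assert canonicalize(c) == c

    def test_twenty_rewritings_collapse_to_one_string(self):
        rng = np.random.default_rng(42)
        variants = [_random_rewriting("[*]CC([*])c1ccncc1", rng)
                    for _ in range(20)]
        assert len({canonicalize(v) for v in variants}) == 1

    def test_invalid_input_raises(self):
        with pytest.raises(PSMILESError):
            canonicalize("[*]CC")


class TestAreSamePolymer:
    def test_nylon6_one_vs_two_fold(self):
        assert are_same_polymer("[*]CCCCCC(=O)N[*]",
                                "[*]CCCCCC(=O)NCCCCCC(=O)N[*]")

    def test_reflexive(self):
        for p in FIXTURE_POLYMERS:
            assert are_same_polymer(p, p)

    def test_different_side_chains_differ(self):
        assert not are_same_polymer("[*]CC([*])CC", "[*]CC([*])CCC")
        assert not _oracle_same("[*]CC([*])CC", "[*]CC([*])CCC")

    def test_agrees_with_graph_isomorphism_oracle_on_pairs(self):
        polys = FIXTURE_POLYMERS[:12]
        for i, a in enumerate(polys):
            for b in polys[i:]:
                assert are_same_polymer(a, b) == _oracle_same(a, b), (a, b)


class TestInvarianceSuite:
    """Translation, multiplication and permutation must collapse to a
    single canonical string that agrees with the graph oracle."""

    @pytest.mark.parametrize("p", FIXTURE_POLYMERS)
    def test_all_rewritings_one_string(self, p):
        from polylingua.psmiles import _rotations

        rng = np.random.default_rng(7)
        c = canonicalize(p)
        variants = _rotations(p) + [multiply(p, 2), multiply(p, 3)]
        variants += [_random_rewriting(p, rng) for _ in range(20)]
        assert {canonicalize(v) for v in variants} == {c}
        assert _oracle_same(c, p)
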