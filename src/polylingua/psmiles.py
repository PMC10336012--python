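"""Polymer SMILES (PSMILES) validation, rewriting and canonicalization.

A PSMILES string is a SMILES string with exactly two ``[*]`` dummy atoms
that mark the two endpoints of a polymer repeat unit, e.g. ``[*]CC[*]``
for polyethylene.  The raw syntax is highly non-unique: the repeat-unit
window may be translated along the backbone, the unit may be written as
a k-fold multiple of itself, and the SMILES grammar permits arbitrary
atom-order permutations.  :func:`canonicalize` collapses all rewritings
of the same polymer to one unique string in four steps:

1. reduce to the shortest repeat unit (:func:`shortest_repeat`),
2. close the unit into a periodic molecule (:func:`cyclize`),
3. rank atoms with RDKit's canonical ranking of the periodic graph,
4. re-open the ring at the backbone bond whose cleavage yields the
   lexicographically smallest valid two-star string.

The canonical string is a fixed point of :func:`canonicalize` and is
identical for every rewriting of the same polymer, which is the property
the rest of the package (tokenization, fingerprinting, deduplication)
relies on.
"""

from __future__ import annotations

import functools
import logging
import re
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem, RDLogger
from rdkit.Chem import rdmolops

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "PSMILESError",
    "ValidationReport",
    "PeriodicMolecule",
    "validate",
    "multiply",
    "rotate",
    "cyclize",
    "shortest_repeat",
    "canonicalize",
    "are_same_polymer",
]


class PSMILESError(ValueError):
    """Raised when a string is not a well-formed PSMILES repeat unit."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`; ``valid`` iff ``issues`` is empty."""

    valid: bool
    issues: list[str] = field(default_factory=list)


@dataclass
class PeriodicMolecule:
    """A repeat unit closed onto itself.

    ``mol`` is the ring molecule, ``closure_bond`` the index of the bond
    joining the two former endpoint-attachment atoms, and ``multiplicity``
    how many copies of the input unit were fused before closure (1 unless
    the closure of a single unit would create a self-loop or a duplicate
    bond, which molecular graphs disallow).
    """

    mol: Chem.Mol
    closure_bond: int
    multiplicity: int
    backbone: tuple[int, ...]


_BOND_CHARS = "=#-/\\:~"


def _count_stars(raw: str) -> int:
    # bracketed [*] tokens plus any bare * atoms
    return raw.count("[*]") + raw.replace("[*]", "").count("*")


def _bracket_stars(smiles: str) -> str:
    """Rewrite bare ``*`` dummy atoms as ``[*]``."""
    out = smiles.replace("[*]", "\x00")
    out = out.replace("*", "[*]")
    return out.replace("\x00", "[*]")


def _star_indices(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]


def validate(raw: str) -> ValidationReport:
    """Check a string against the PSMILES invariants without raising.

    Reported issue codes: ``star_count:<n>``, ``parse_error``,
    ``star_star_bond``, ``star_valence:<n>``, ``endpoint_order_mismatch``.
    """
    valid, issues = _validate_cached(raw) if isinstance(raw, str) else (False, ("parse_error",))
    return ValidationReport(valid, list(issues))


@functools.lru_cache(maxsize=100_000)
def _parse_cached(raw: str):
    return Chem.MolFromSmiles(raw)


@functools.lru_cache(maxsize=100_000)
def _validate_cached(raw: str) -> tuple[bool, tuple[str, ...]]:
    issues: list[str] = []
    if not raw.strip():
        return False, ("parse_error",)
    n_star = _count_stars(raw)
    if n_star != 2:
        issues.append(f"star_count:{n_star}")
    mol = _parse_cached(raw)
    if mol is None:
        issues.append("parse_error")
        return False, tuple(issues)
    stars = _star_indices(mol)
    if len(stars) == 2 and not issues:
        a, b = stars
        if mol.GetBondBetweenAtoms(a, b) is not None:
            issues.append("star_star_bond")
        orders = []
        for s in stars:
            atom = mol.GetAtomWithIdx(s)
            if atom.GetDegree() != 1:
                issues.append(f"star_valence:{atom.GetDegree()}")
            elif mol.GetBondBetweenAtoms(a, b) is None:
                orders.append(next(iter(atom.GetBonds())).GetBondType())
        if len(orders) == 2 and orders[0] != orders[1]:
            issues.append("endpoint_order_mismatch")
    return not issues, tuple(issues)


def _mol(p: str) -> Chem.Mol:
    rep = validate(p)
    if not rep.valid:
        raise PSMILESError(f"invalid PSMILES {p!r}: {', '.join(rep.issues)}")
    return _parse_cached(p)


def _to_psmiles(mol: Chem.Mol) -> str:
    return _bracket_stars(Chem.MolToSmiles(mol))


def _attachment(mol: Chem.Mol, star: int) -> tuple[int, Chem.BondType]:
    atom = mol.GetAtomWithIdx(star)
    bond = next(iter(atom.GetBonds()))
    return bond.GetOtherAtomIdx(star), bond.GetBondType()


def _backbone(mol: Chem.Mol) -> tuple[int, ...]:
    """Atom indices on the endpoint-to-endpoint path, stars excluded."""
    s1, s2 = _star_indices(mol)
    path = rdmolops.GetShortestPath(mol, s1, s2)
    return tuple(path[1:-1])


def heavy_atom_count(p: str) -> int:
    """Number of non-dummy atoms in the repeat unit."""
    return sum(1 for a in _mol(p).GetAtoms() if a.GetAtomicNum() > 0)


def multiply(p: str, k: int) -> str:
    """Concatenate ``k`` copies of the repeat unit into one PSMILES.

    The infinite chain is unchanged; the heavy-atom count is ``k`` times
    that of ``p``.
    """
    if k < 1:
        raise PSMILESError("k must be >= 1")
    mol = _mol(p)
    if k == 1:
        return p
    # fast path: plain string concatenation when the unit is written
    # endpoint-to-endpoint with single attachment bonds
    m = re.fullmatch(r"\[\*\](.+)\[\*\]", p)
    if m and p[3] not in _BOND_CHARS and p[-4] not in _BOND_CHARS and "%" not in p:
        core = m.group(1)
        cand = "[*]" + core * k + "[*]"
        if validate(cand).valid:
            return cand
    acc = mol
    for _ in range(k - 1):
        acc = _join(acc, mol)
    return _to_psmiles(acc)


def _join(a: Chem.Mol, b: Chem.Mol) -> Chem.Mol:
    """Fuse the second endpoint of ``a`` to the first endpoint of ``b``."""
    sa = _star_indices(a)[1]
    na, oa = _attachment(a, sa)
    combo = Chem.RWMol(Chem.CombineMols(a, b))
    off = a.GetNumAtoms()
    sb = _star_indices(b)[0] + off
    nb, ob = _attachment(combo, sb)
    if oa != ob:
        raise PSMILESError("endpoint bond orders differ; chain is ill-defined")
    combo.AddBond(na, nb, oa)
    for idx in sorted((sa, sb), reverse=True):
        combo.RemoveAtom(idx)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


@functools.lru_cache(maxsize=100_000)
def _min_multiplicity(p: str) -> int:
    """Smallest k such that closing multiply(p, k) is a legal graph."""
    m = len(_backbone(_mol(p)))
    if m <= 1:
        return 3
    if m == 2:
        return 2
    return 1


def cyclize(p: str) -> PeriodicMolecule:
    """Close the repeat unit into a periodic (ring) molecule.

    The closure bond joins the two atoms formerly bonded to ``[*]`` and
    carries the shared endpoint-attachment bond order.  Units whose
    closure would form a self-loop or a duplicate bond are first
    multiplied to the smallest legal size.
    """
    t = _min_multiplicity(p)
    q = multiply(p, t)
    mol = _mol(q)
    s1, s2 = _star_indices(mol)
    n1, o1 = _attachment(mol, s1)
    n2, o2 = _attachment(mol, s2)
    if o1 != o2:
        raise PSMILESError("mismatched endpoint bond orders")
    rw = Chem.RWMol(mol)
    rw.AddBond(n1, n2, o1)
    for idx in sorted((s1, s2), reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:  # pragma: no cover - defensive
        raise PSMILESError(f"cyclization failed for {p!r}: {exc}") from exc
    # star removal shifts indices above the removed positions
    def shift(i: int) -> int:
        return i - sum(1 for s in (s1, s2) if s < i)

    u, v = shift(n1), shift(n2)
    closure = out.GetBondBetweenAtoms(u, v).GetIdx()
    backbone = tuple(shift(i) for i in _backbone(mol))
    return PeriodicMolecule(out, closure, t, backbone)


@functools.lru_cache(maxsize=100_000)
def _periodic_canonical(p: str, k: int = 1) -> str:
    """Canonical SMILES of the cyclized ``k``-fold repeat (no stars)."""
    return Chem.MolToSmiles(cyclize(multiply(p, k)).mol)


def _segment(mol: Chem.Mol, seg_len: int) -> str | None:
    """Extract the first ``seg_len`` backbone atoms (with side chains)
    of an open unit as a candidate PSMILES, or None if the cut is not
    clean (boundary inside a ring, or a side chain spanning it)."""
    stars = _star_indices(mol)
    bb = _backbone(mol)
    if seg_len >= len(bb):
        return None
    cut = mol.GetBondBetweenAtoms(bb[seg_len - 1], bb[seg_len])
    if cut is None or cut.IsInRing():
        return None
    # collect the segment: BFS from the first seg_len backbone atoms,
    # never crossing the cut bond or the later backbone
    keep = set(bb[:seg_len])
    later = set(bb[seg_len:]) | {stars[1]}
    frontier = list(keep)
    while frontier:
        a = frontier.pop()
        for nbr in mol.GetAtomWithIdx(a).GetNeighbors():
            i = nbr.GetIdx()
            if i in keep or i == stars[0]:
                continue
            if i in later:
                if i == bb[seg_len] and a == bb[seg_len - 1]:
                    continue  # the cut bond itself is not traversed
                return None  # a side chain or ring reaches across the boundary
            keep.add(i)
            frontier.append(i)
    rw = Chem.RWMol(mol)
    order = cut.GetBondType()
    star2 = rw.AddAtom(Chem.Atom(0))
    rw.AddBond(bb[seg_len - 1], star2, order)
    drop = [a.GetIdx() for a in mol.GetAtoms()
            if a.GetIdx() not in keep and a.GetIdx() not in (stars[0], star2)]
    for idx in sorted(drop, reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    s = _to_psmiles(out)
    return s if validate(s).valid else None


def _divisors_desc(n: int) -> list[int]:
    return [k for k in range(n, 1, -1) if n % k == 0]


def shortest_repeat(p: str) -> str:
    """Reduce a PSMILES to its shortest repeat unit.

    Tries, for each divisor k of the backbone length (largest first), to
    cut out the first 1/k of the backbone and checks that the candidate,
    multiplied back k times and cyclized, is graph-isomorphic to the
    cyclized input.  Returns ``p`` unchanged when no repetition exists.
    """
    mol = _mol(p)
    bb = _backbone(mol)
    m = len(bb)
    if m <= 1:
        return p
    ref: dict[int, str] = {}
    for k in _divisors_desc(m):
        q = _segment(mol, m // k)
        if q is None:
            continue
        t = _min_multiplicity(p)
        if t not in ref:
            ref[t] = _periodic_canonical(p, t)
        try:
            if _periodic_canonical(q, k * t) == ref[t]:
                return q
        except PSMILESError:
            continue
    return p


def _rotations(p: str) -> list[str]:
    """All translations of the repeat-unit window along the backbone.

    Element 0 re-opens the periodic molecule at its own closure bond
    (the identity rotation up to rewriting); subsequent elements cut at
    each eligible backbone bond in chain order.
    """
    per = cyclize(p)
    mol, t = per.mol, per.multiplicity
    closure = mol.GetBondWithIdx(per.closure_bond)
    u, v = closure.GetBeginAtomIdx(), closure.GetEndAtomIdx()
    g = nx.Graph()
    g.add_nodes_from(range(mol.GetNumAtoms()))
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    g.remove_edge(u, v)
    path = nx.shortest_path(g, u, v)
    ring_info = mol.GetRingInfo()
    cuts = [closure]
    for a, b in zip(path, path[1:]):
        bond = mol.GetBondBetweenAtoms(a, b)
        if bond.GetIsAromatic() or ring_info.NumBondRings(bond.GetIdx()) != 1:
            continue
        cuts.append(bond)
    out = []
    n_unit = heavy_atom_count(p)
    for bond in cuts:
        s = _open_at(mol, bond)
        if s is None:
            continue
        if t > 1:
            s = _reduce_to(s, n_unit)
            if s is None:
                continue
        out.append(s)
    return out


def _open_at(mol: Chem.Mol, bond: Chem.Bond) -> str | None:
    rw = Chem.RWMol(mol)
    a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    order = bond.GetBondType()
    rw.RemoveBond(a, b)
    da = rw.AddAtom(Chem.Atom(0))
    rw.AddBond(a, da, order)
    db = rw.AddAtom(Chem.Atom(0))
    rw.AddBond(b, db, order)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    s = _to_psmiles(out)
    return s if validate(s).valid else None


def _reduce_to(p: str, n_heavy: int) -> str | None:
    """Reduce a multiplied unit back to a unit of ``n_heavy`` atoms."""
    q = shortest_repeat(p)
    n_q = heavy_atom_count(q)
    if n_q == n_heavy:
        return q
    if n_heavy % n_q == 0:
        return multiply(q, n_heavy // n_q)
    return None


def rotate(p: str, j: int) -> str:
    """Shift the repeat-unit window ``j`` eligible positions along the
    periodic backbone.  ``rotate(p, 0)`` is ``p`` itself; every output
    canonicalizes to the same string as ``p``."""
    rots = _rotations(p)
    if not rots:
        return p
    j = j % len(rots)
    if j == 0:
        return p
    return rots[j]


def _rdkit_canonical(p: str) -> str:
    return _to_psmiles(Chem.MolFromSmiles(p))


def canonicalize(p: str) -> str:
    """Unique string representative of the polymer's equivalence class.

    Idempotent, and identical for every translation, multiplication and
    atom-order permutation of the same repeat unit.
    """
    q = shortest_repeat(p)
    cands = {_rdkit_canonical(r) for r in _rotations(q)}
    if not cands:  # no eligible cut found; fall back to the reduced unit
        return _rdkit_canonical(q)
    return min(cands)


def are_same_polymer(a: str, b: str) -> bool:
    """True iff the two PSMILES denote the same polymer."""
    return canonicalize(a) == canonicalize(b)
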