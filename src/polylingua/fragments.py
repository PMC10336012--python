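"""BRICS decomposition of polymer repeat units and recombination into
novel hypothetical polymers.

The repeat unit of a PSMILES string is cleaved at retrosynthetically
interesting bonds (the published BRICS rule set, as implemented in
RDKit).  The two chain endpoints are protected before cleavage so the
rules never fire on them, and re-emerge as link points of class 0
("chain endpoint").  Fragment link points of classes 1-16 follow the
BRICS pairing matrix; recombining compatible link points and capping
the two terminal links with ``[*]`` yields new, chemically valid
hypothetical polymers.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

from .psmiles import PSMILESError, canonicalize, validate

logger = logging.getLogger(__name__)

__all__ = ["Fragment", "FragmentLibrary", "brics_decompose", "reassemble",
           "build_library", "combine", "write_library", "read_library"]

#: chain-endpoint link class (former [*] positions); joins with any class
ENDPOINT_CLASS = 0

_PROTECT = "Xe"  # inert placeholder element absent from the BRICS rule alphabet


def _compatibility() -> set[tuple[int, int]]:
    pairs = set()
    for group in BRICS.reactionDefs:
        for l1, l2, _bond in group:
            a = int(re.sub("[ab]", "", l1))
            b = int(re.sub("[ab]", "", l2))
            pairs.add((a, b))
            pairs.add((b, a))
    return pairs


_COMPAT = _compatibility()

_DOUBLE_PAIRS = {
    (int(re.sub("[ab]", "", l1)), int(re.sub("[ab]", "", l2)))
    for group in BRICS.reactionDefs for l1, l2, bond in group if bond == "="
}
_DOUBLE_PAIRS |= {(b, a) for a, b in _DOUBLE_PAIRS}


def link_compatible(a: int, b: int) -> bool:
    """BRICS pairing matrix, extended so the chain-endpoint class joins
    with every class."""
    if a == ENDPOINT_CLASS or b == ENDPOINT_CLASS:
        return True
    return (a, b) in _COMPAT


@dataclass
class Fragment:
    """A two-or-more-point chemical fragment.

    Link points are dummy atoms whose isotope is the BRICS link class
    (0 for former chain endpoints) and whose atom-map number, when
    non-zero, identifies the cleaved bond it came from (shared with its
    partner fragment, enabling exact reassembly).
    """

    mol: Chem.Mol
    link_types: tuple[int, ...]
    canonical_key: str

    @property
    def n_links(self) -> int:
        return len(self.link_types)


@dataclass
class FragmentLibrary:
    """Deduplicated fragments with occurrence counts."""

    fragments: list[Fragment] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.fragments)

    def add(self, frag: Fragment) -> None:
        if frag.canonical_key in self.counts:
            self.counts[frag.canonical_key] += 1
        else:
            self.counts[frag.canonical_key] = 1
            self.fragments.append(frag)


def _link_classes(mol: Chem.Mol) -> tuple[int, ...]:
    return tuple(sorted(a.GetIsotope() for a in mol.GetAtoms()
                        if a.GetAtomicNum() == 0))


def _canonical_key(mol: Chem.Mol) -> str:
    clean = Chem.Mol(mol)
    for a in clean.GetAtoms():
        a.SetAtomMapNum(0)
    s = Chem.MolToSmiles(clean)
    # normalize through a reparse so keys are stable regardless of how
    # the fragment molecule was constructed (surgery leaves atom state
    # that changes dummy-atom bracketing)
    rt = Chem.MolFromSmiles(s)
    return Chem.MolToSmiles(rt) if rt is not None else s


def _as_fragment(mol: Chem.Mol) -> Fragment:
    return Fragment(mol, _link_classes(mol), _canonical_key(mol))


def brics_decompose(p: str) -> list[Fragment]:
    """Cleave a repeat unit at every BRICS bond.

    Endpoint ``[*]`` markers are protected during cleavage and restored
    as class-0 link points.  Matching atom-map numbers on the link
    dummies record which fragment ends were bonded, so
    :func:`reassemble` can rebuild the polymer exactly.
    """
    rep = validate(p)
    if not rep.valid:
        raise PSMILESError(f"invalid PSMILES {p!r}: {', '.join(rep.issues)}")
    protected = Chem.MolFromSmiles(p.replace("[*]", f"[{_PROTECT}]"))
    bonds = list(BRICS.FindBRICSBonds(protected))
    rw = Chem.RWMol(protected)
    for pair_id, ((a1, a2), (l1, l2)) in enumerate(bonds, start=1):
        bond = rw.GetBondBetweenAtoms(a1, a2)
        order = bond.GetBondType()
        rw.RemoveBond(a1, a2)
        for anchor, label in ((a1, l1), (a2, l2)):
            d = rw.AddAtom(Chem.Atom(0))
            rw.GetAtomWithIdx(d).SetIsotope(int(re.sub("[ab]", "", label)))
            rw.GetAtomWithIdx(d).SetAtomMapNum(pair_id)
            rw.AddBond(anchor, d, order)
    broken = rw.GetMol()
    # restore protected endpoints as class-0 link points
    for atom in broken.GetAtoms():
        if atom.GetSymbol() == _PROTECT:
            atom.SetAtomicNum(0)
            atom.SetIsotope(ENDPOINT_CLASS)
    Chem.SanitizeMol(broken)
    return [_as_fragment(frag)
            for frag in Chem.GetMolFrags(broken, asMols=True)]


def reassemble(fragments: list[Fragment]) -> str:
    """Rejoin fragments at their cleaved bonds (matched by atom-map
    number) and return the reconstructed PSMILES."""
    combo = fragments[0].mol
    for frag in fragments[1:]:
        combo = Chem.CombineMols(combo, frag.mol)
    rw = Chem.RWMol(combo)
    by_pair: dict[int, list[int]] = {}
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum():
            by_pair.setdefault(atom.GetAtomMapNum(), []).append(atom.GetIdx())
    drop = []
    for pair_id, dummies in by_pair.items():
        if len(dummies) != 2:
            raise PSMILESError(f"unpaired link point (pair {pair_id})")
        anchors, orders = [], []
        for d in dummies:
            bond = next(iter(rw.GetAtomWithIdx(d).GetBonds()))
            anchors.append(bond.GetOtherAtomIdx(d))
            orders.append(bond.GetBondType())
        rw.AddBond(anchors[0], anchors[1], orders[0])
        drop.extend(dummies)
    for idx in sorted(drop, reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    for atom in out.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
    Chem.SanitizeMol(out)
    from .psmiles import _to_psmiles  # avoid re-export churn

    return _to_psmiles(out)


def build_library(corpus: list[str], provenance: str = "") -> FragmentLibrary:
    """Decompose a PSMILES corpus into a deduplicated fragment library."""
    if not corpus:
        raise PSMILESError("empty corpus")
    bad = [i for i, p in enumerate(corpus) if not validate(p).valid]
    if bad:
        raise PSMILESError(f"invalid corpus members at indices {bad}")
    lib = FragmentLibrary(provenance=provenance)
    for p in corpus:
        for frag in brics_decompose(p):
            mol = Chem.Mol(frag.mol)
            for atom in mol.GetAtoms():
                atom.SetAtomMapNum(0)
            lib.add(_as_fragment(mol))
    return lib


def _joinable(lib: FragmentLibrary) -> list[Fragment]:
    return [f for f in lib.fragments if f.n_links >= 2]


def _link_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]


def _join_at(mol: Chem.Mol, d1: int, d2: int) -> Chem.Mol:
    """Fuse two link dummies of one (combined) molecule into a bond."""
    rw = Chem.RWMol(mol)
    a1 = next(iter(rw.GetAtomWithIdx(d1).GetBonds()))
    a2 = next(iter(rw.GetAtomWithIdx(d2).GetBonds()))
    c1, c2 = rw.GetAtomWithIdx(d1).GetIsotope(), rw.GetAtomWithIdx(d2).GetIsotope()
    order = (Chem.BondType.DOUBLE if (c1, c2) in _DOUBLE_PAIRS
             and a1.GetBondType() == Chem.BondType.DOUBLE
             else Chem.BondType.SINGLE)
    rw.AddBond(a1.GetOtherAtomIdx(d1), a2.GetOtherAtomIdx(d2), order)
    for idx in sorted((d1, d2), reverse=True):
        rw.RemoveAtom(idx)
    return rw.GetMol()


def _finish(mol: Chem.Mol, head: int, tail: int) -> str | None:
    """Turn the two terminal links into ``[*]`` endpoints, cap every
    other open link with hydrogen, and canonicalize."""
    rw = Chem.RWMol(mol)
    drop = []
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() != 0:
            continue
        if atom.GetIdx() in (head, tail):
            atom.SetIsotope(0)
            atom.SetAtomMapNum(0)
        else:
            drop.append(atom.GetIdx())
    for idx in sorted(drop, reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
        s = Chem.MolToSmiles(out)
        s = s.replace("[*]", "\x00").replace("*", "[*]").replace("\x00", "[*]")
        if not validate(s).valid:
            return None
        return s
    except Exception:
        return None


def _assemble(parts: list[Fragment], choose) -> str | None:
    """Chain fragments left to right; ``choose(options)`` picks among
    candidate link-atom indices."""
    mol = Chem.Mol(parts[0].mol)
    links = _link_atoms(mol)
    if len(links) < 2:
        return None
    head = choose(links)
    tail = choose([i for i in links if i != head])
    for frag in parts[1:]:
        off = mol.GetNumAtoms()
        nxt = Chem.Mol(frag.mol)
        nxt_links = [i + off for i in _link_atoms(nxt)]
        combo = Chem.CombineMols(mol, nxt)
        tail_cls = combo.GetAtomWithIdx(tail).GetIsotope()
        options = [i for i in nxt_links
                   if link_compatible(tail_cls, combo.GetAtomWithIdx(i).GetIsotope())]
        if not options:
            return None
        join = choose(options)
        remaining = [i for i in nxt_links if i != join]
        if not remaining:
            return None
        new_tail = choose(remaining)
        # deleting the two dummies shifts indices; track head/tail
        kept = [head, new_tail]
        shifted = []
        for idx in kept:
            shifted.append(idx - sum(1 for d in (tail, join) if d < idx))
        mol = _join_at(combo, tail, join)
        head, tail = shifted
    return _finish(mol, head, tail)


def combine(lib: FragmentLibrary, n: int, seed: int = 0,
            mode: str = "random", max_fragments: int = 4,
            max_attempts_factor: int = 200) -> list[str]:
    """Generate up to ``n`` hypothetical polymers from a fragment library.

    ``random`` mode samples fragment chains (1..max_fragments fragments,
    joined at BRICS-compatible link classes) with a seeded generator;
    ``enumerate`` mode walks fragment tuples in a fixed deterministic
    order.  Every output is a valid, canonical, unique PSMILES.
    """
    joinable = sorted(_joinable(lib), key=lambda f: f.canonical_key)
    if not joinable:
        raise PSMILESError("library has no fragments with >= 2 link points")
    out: list[str] = []
    seen: set[str] = set()
    seen_raw: set[str] = set()

    def emit(raw: str | None) -> None:
        # raw is an RDKit-canonical SMILES of the assembly; full polymer
        # canonicalization is only paid once per new raw structure
        if raw is None or raw in seen_raw:
            return
        seen_raw.add(raw)
        s = canonicalize(raw)
        if s not in seen:
            seen.add(s)
            out.append(s)

    if mode == "random":
        rng = np.random.default_rng(seed)
        weights = np.array([lib.counts[f.canonical_key] for f in joinable], float)
        weights /= weights.sum()
        choose = lambda opts: opts[rng.integers(len(opts))]
        attempts = 0
        while len(out) < n and attempts < n * max_attempts_factor:
            attempts += 1
            k = int(rng.integers(1, max_fragments + 1))
            idx = rng.choice(len(joinable), size=k, p=weights)
            emit(_assemble([joinable[int(i)] for i in idx], choose))
        if len(out) < n:
            logger.warning("combine: produced %d/%d polymers", len(out), n)
    elif mode == "enumerate":
        choose = lambda opts: opts[0]
        for k in range(1, max_fragments + 1):
            for tup in itertools.product(range(len(joinable)), repeat=k):
                if len(out) >= n:
                    return out
                emit(_assemble([joinable[i] for i in tup], choose))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def write_library(lib: FragmentLibrary, path: str) -> None:
    """Serialize a library as a text table: canonical_key, link classes
    (comma-joined), occurrence count."""
    with open(path, "w") as fh:
        fh.write(f"# fragment library\tprovenance={lib.provenance}\n")
        fh.write("canonical_key\tlink_types\tcount\n")
        for frag in lib.fragments:
            links = ",".join(str(t) for t in frag.link_types)
            fh.write(f"{frag.canonical_key}\t{links}\t{lib.counts[frag.canonical_key]}\n")


def read_library(path: str) -> FragmentLibrary:
    """Inverse of :func:`write_library` (fragments are reparsed from
    their canonical keys)."""
    lib = FragmentLibrary()
    with open(path) as fh:
        header = fh.readline()
        if header.startswith("#") and "provenance=" in header:
            lib.provenance = header.split("provenance=", 1)[1].strip()
        cols = fh.readline().rstrip("\n").split("\t")
        if cols != ["canonical_key", "link_types", "count"]:
            raise ValueError(f"{path}: not a fragment-library table")
        for line in fh:
            key, links, count = line.rstrip("\n").split("\t")
            mol = Chem.MolFromSmiles(key)
            if mol is None:
                raise ValueError(f"{path}: unparseable fragment {key!r}")
            frag = _as_fragment(mol)
            lib.fragments.append(frag)
            lib.counts[frag.canonical_key] = int(count)
    return lib
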