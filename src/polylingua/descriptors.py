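"""Reduced handcrafted descriptor fingerprint.

A small, fast baseline representation in the spirit of handcrafted
polymer fingerprints: counts and fractions computed directly from the
repeat-unit graph, plus a few standard physicochemical descriptors.
The first six components (heavy-atom count, aromatic-atom fraction,
oxygen/nitrogen/halogen counts, longest side chain) are deliberately
cheap graph quantities that require no learned model — the synthetic
property generator builds its ground truth from exactly these, so the
prediction stack can be tested against a known mapping.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .psmiles import _backbone, _mol

__all__ = ["GRAPH_DESCRIPTOR_NAMES", "DESCRIPTOR_NAMES",
           "graph_descriptors", "descriptor_fingerprint"]

GRAPH_DESCRIPTOR_NAMES = (
    "heavy_atoms", "aromatic_fraction", "n_oxygen", "n_nitrogen",
    "n_halogen", "longest_side_chain",
)

DESCRIPTOR_NAMES = GRAPH_DESCRIPTOR_NAMES + (
    "backbone_length", "n_rings", "mol_weight", "tpsa", "logp", "frac_csp3",
)

_HALOGENS = {9, 17, 35, 53}


def graph_descriptors(p: str) -> np.ndarray:
    """Cheap graph descriptors of a repeat unit (model-free)."""
    mol = _mol(p)
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 0]
    n = len(heavy)
    arom = sum(a.GetIsAromatic() for a in heavy) / max(1, n)
    n_o = sum(a.GetAtomicNum() == 8 for a in heavy)
    n_n = sum(a.GetAtomicNum() == 7 for a in heavy)
    n_hal = sum(a.GetAtomicNum() in _HALOGENS for a in heavy)
    bb = set(_backbone(mol))
    # longest side chain: graph distance from a backbone atom to the
    # farthest non-backbone atom reachable without re-entering the backbone
    longest = 0
    for start in bb:
        frontier = [(start, 0)]
        seen = {start}
        while frontier:
            a, d = frontier.pop()
            longest = max(longest, d)
            for nbr in mol.GetAtomWithIdx(a).GetNeighbors():
                i = nbr.GetIdx()
                if i in seen or i in bb or nbr.GetAtomicNum() == 0:
                    continue
                seen.add(i)
                frontier.append((i, d + 1))
    return np.array([n, arom, n_o, n_n, n_hal, longest], dtype=np.float64)


def descriptor_fingerprint(p: str) -> np.ndarray:
    """Graph descriptors plus standard physicochemical descriptors."""
    mol = _mol(p)
    extra = np.array([
        len(_backbone(mol)),
        rdMolDescriptors.CalcNumRings(mol),
        Descriptors.MolWt(mol),
        rdMolDescriptors.CalcTPSA(mol),
        Crippen.MolLogP(mol),
        rdMolDescriptors.CalcFractionCSP3(mol),
    ], dtype=np.float64)
    return np.concatenate([graph_descriptors(p), extra])
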