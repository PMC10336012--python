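"""Synthetic data generators: seed monomers, equivalent-rewriting
suites, and property tables with known structure.

Every other module is testable without downloads because (a) the seed
monomers are template-built valid PSMILES covering the common polymer
families (vinyls, ethers, esters, amides, aromatic backbones), (b) the
rewriting suite produces translations, multiples and atom-order
permutations of a unit that must all collapse to one canonical string,
and (c) the property generator draws values as linear functions of
cheap graph descriptors with shared latent weights — so ground truth
is exactly recomputable at zero noise, inter-property correlations are
induced by construction, and no learned model enters the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from . import psmiles as ps
from .descriptors import graph_descriptors
from .properties import PolymerRecord

__all__ = ["GeneratorConfig", "PROBE_POLYMERS", "seed_monomers",
           "rewriting_suite", "synth_properties"]

#: poly(but-1-ene), poly(pent-1-ene) and poly(4-vinylpyridine) — the
#: three probe polymers used for fingerprint-similarity sanity checks
PROBE_POLYMERS = ("[*]CC([*])CC", "[*]CC([*])CCC", "[*]CC([*])c1ccncc1")

_VINYL_R = ("C", "CC", "CCC", "CCCC", "c1ccccc1", "c1ccncc1", "Cl", "F",
            "C#N", "OC", "OC(C)=O", "C(=O)OC", "C(=O)OCC", "c1ccc(C)cc1",
            "CO", "C(C)C", "C(=O)N", "c1ccco1", "OCC", "C(=O)OCC(C)C")

_BACKBONES = (
    "[*]CCO[*]", "[*]CCCO[*]", "[*]CC(C)O[*]",
    "[*]CCC(=O)O[*]", "[*]CCCCC(=O)O[*]", "[*]CCOC(=O)CC[*]",
    "[*]CCCC(=O)N[*]", "[*]CCCCCC(=O)N[*]",
    "[*]c1ccc([*])cc1", "[*]Cc1ccc(C[*])cc1",
    "[*]COC(=O)c1ccc(C(=O)O[*])cc1",
    "[*]Oc1ccc(C(C)(C)c2ccc(OC(=O)[*])cc2)cc1",
    "[*]CCS[*]", "[*]CCCS[*]", "[*]CCN[*]",
)


def seed_monomers(n: int, seed: int = 0) -> list[str]:
    """Template-built seed corpus of ``n`` canonically distinct PSMILES.

    The three probe polymers come first; the rest are drawn (seeded)
    from vinyl, ether, ester, amide and aromatic templates, extended
    with growing alkyl side chains if the template pool is exhausted.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pool = ["[*]CC([*])" + r for r in _VINYL_R] + list(_BACKBONES)
    pool = [p for p in pool if ps.validate(p).valid]
    order = rng.permutation(len(pool))
    out, seen = [], set()
    for p in PROBE_POLYMERS:
        c = ps.canonicalize(p)
        if c not in seen:
            seen.add(c)
            out.append(p)
    for i in order:
        if len(out) >= n:
            break
        c = ps.canonicalize(pool[i])
        if c not in seen:
            seen.add(c)
            out.append(pool[i])
    k = 4
    while len(out) < n:  # unbounded fallback: longer alkyl vinyls
        p = "[*]CC([*])" + "C" * k
        c = ps.canonicalize(p)
        if c not in seen:
            seen.add(c)
            out.append(p)
        k += 1
    return out[:n]


def rewriting_suite(p: str, n: int, seed: int = 0) -> list[str]:
    """``n`` equivalent rewritings of ``p``: backbone translations,
    k-fold multiples (k <= 3) and random atom-order permutations, at
    least one of each class when n >= 3."""
    if not ps.validate(p).valid:
        raise ps.PSMILESError(f"invalid PSMILES {p!r}")
    rng = np.random.default_rng(seed)
    mol = Chem.MolFromSmiles(p)

    def permuted() -> str:
        perm = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
        return ps._bracket_stars(
            Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False))

    rotations = ps._rotations(p)
    out: list[str] = []
    cls = 0
    j, k = 1, 2
    while len(out) < n:
        if cls == 0 and rotations:
            out.append(rotations[j % len(rotations)])
            j += 1
        elif cls == 1:
            out.append(ps.multiply(p, 2 + (k % 2)))
            k += 1
        else:
            out.append(permuted())
        cls = (cls + 1) % 3
    return out[:n]


@dataclass
class GeneratorConfig:
    """Synthetic property-table generator.

    Values are ``w_p . d + intercept + noise`` on the (transformed)
    property scale, where ``d`` are the six cheap graph descriptors and
    the weights share a common latent direction ``u`` so that Tg and Tm
    are strongly correlated (the correlation multitask models exploit).
    Positive-only properties (here mu_CO2) are generated on the log10
    scale and exponentiated, so the log10(x+1) training transform
    exactly linearizes them.  ``sigma`` scales all noise standard
    deviations; at sigma=0 every value is an exact linear function of
    the descriptors.
    """

    seed: int = 0
    n_records: int = 2000
    copolymer_fraction: float = 0.3
    sigma: float = 1.0
    interaction_noise: float = 0.0  # extra copolymer mixing noise (native scale)
    symbols: tuple[str, ...] = ("Tg", "Tm", "Td", "rho", "mu_CO2")
    #: shared latent direction over the six graph descriptors
    latent: tuple[float, ...] = (6.0, 80.0, 12.0, 10.0, 8.0, -5.0)
    #: per-property (latent loading, own weights, intercept, noise sd,
    #: share of records); Tm is deliberately low-n and Tg-correlated
    spec: dict[str, dict] = field(default_factory=lambda: {
        "Tg":     {"load": 1.0, "own": (0, 0, 6.0, 0, 0, 0), "b": 200.0,
                   "sd": 8.0, "share": 0.38},
        "Tm":     {"load": 1.2, "own": (0, 0, 0, 5.0, 0, 0), "b": 280.0,
                   "sd": 8.0, "share": 0.06},
        "Td":     {"load": 0.8, "own": (2.0, 0, 0, 0, 0, 3.0), "b": 500.0,
                   "sd": 12.0, "share": 0.22},
        "rho":    {"load": 0.002, "own": (0.003, 0.2, 0.01, 0, 0.05, -0.004),
                   "b": 0.9, "sd": 0.02, "share": 0.17},
        "mu_CO2": {"load": 0.0015, "own": (0.01, -0.4, 0.02, 0, 0, 0.03),
                   "b": 1.2, "sd": 0.05, "share": 0.17},
    })


def _raw_value(symbol: str, d: np.ndarray, cfg: GeneratorConfig) -> float:
    s = cfg.spec[symbol]
    u = np.array(cfg.latent)
    w = s["load"] * u * _SCALE.get(symbol, 1.0) + np.array(s["own"], float)
    return float(w @ d + s["b"])


# latent loadings live on very different native scales
_SCALE = {"Tg": 1.0, "Tm": 1.0, "Td": 1.0, "rho": 0.001, "mu_CO2": 0.002}


def synth_properties(polymers: list[str],
                     cfg: GeneratorConfig | None = None) -> list[PolymerRecord]:
    """Generate a synthetic property table over a polymer list.

    Homopolymer values are linear in the graph descriptors (plus seeded
    Gaussian noise on the transformed scale); copolymer records mix two
    monomer values by composition.  Per-property record counts follow
    ``share`` of ``n_records``, emulating sparse per-property coverage.
    """
    cfg = cfg or GeneratorConfig()
    if not polymers:
        raise ValueError("no polymers")
    rng = np.random.default_rng(cfg.seed)
    desc = {p: graph_descriptors(p) for p in polymers}
    records: list[PolymerRecord] = []
    for symbol in cfg.symbols:
        if symbol not in cfg.spec:
            raise KeyError(f"generator config lacks weights for {symbol!r}")
        n_p = max(5, int(round(cfg.spec[symbol]["share"] * cfg.n_records)))
        sd = cfg.spec[symbol]["sd"] * cfg.sigma
        for _ in range(n_p):
            if rng.random() < cfg.copolymer_fraction and len(polymers) > 1:
                i, j = rng.choice(len(polymers), size=2, replace=False)
                c1 = float(np.round(rng.uniform(0.1, 0.9), 2))
                pair = ((polymers[int(i)], c1), (polymers[int(j)], 1.0 - c1))
            else:
                i = int(rng.integers(len(polymers)))
                pair = ((polymers[i], 1.0),)
            vals = []
            for p, _c in pair:
                raw = _raw_value(symbol, desc[p], cfg) + rng.normal(0.0, sd)
                vals.append(raw)
            mixed = sum(c * v for (_p, c), v in zip(pair, vals))
            if cfg.interaction_noise and len(pair) > 1:
                mixed += rng.normal(0.0, cfg.interaction_noise)
            if symbol == "mu_CO2":
                # generated on the log10 scale; publish in native units
                mixed = float(np.power(10.0, np.clip(mixed, 0.0, 4.0)) - 1.0)
            records.append(PolymerRecord(pair, symbol, float(mixed)))
    return records
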