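# polylingua

A polymer informatics toolkit that treats polymer chemical structure
as a language.  It is aimed at polymer/materials researchers who need
machine-readable polymer representations and fast property predictors
for screening large candidate spaces.

The pipeline has four stages:

1. **PSMILES canonicalization** — a polymer repeat unit written as a
   SMILES string with two `[*]` endpoint markers (e.g. `[*]CC[*]` for
   polyethylene) has infinitely many equivalent writings: translated
   repeat-unit windows, k-fold multiples, and atom-order permutations.
   `canonicalize` reduces all of them to one unique string by finding
   the shortest repeat unit, closing it into a periodic molecule,
   ranking atoms canonically, and re-opening the ring at a
   deterministic backbone bond.
2. **Hypothetical polymer generation** — repeat units are decomposed
   at BRICS retrosynthetic bonds into a deduplicated fragment library;
   recombining fragments at compatible link classes (and capping the
   two chain ends with `[*]`) generates unlimited novel, chemically
   valid polymers.
3. **Masked-language-model fingerprints** — a transformer encoder is
   trained on canonical PSMILES with the fill-in-the-blanks objective
   (15% of tokens masked).  The polymer fingerprint **F** is the
   sentence average of the last encoder layer — dense, fixed-length,
   identical for every rewriting of the same polymer.  Copolymer
   fingerprints are composition-weighted sums, F = Σᵢ cᵢ Fᵢ.
4. **Multitask property prediction** — selector-conditioned multitask
   networks map fingerprints to many properties at once (exploiting
   inter-property correlation such as T_g with T_m); five
   cross-validation fold models are consolidated by a stacking meta
   learner; R² and RMSE are reported per property, per category and
   overall, with log₁₀(x+1) transforms for gas permeabilities and
   elongation at break.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

```python
from polylingua import (canonicalize, are_same_polymer, build_library,
                        combine, seed_monomers)

# one polymer, three writings
print(canonicalize("[*]CCOCCO[*]"))   # [*]CCO[*]
print(canonicalize("[*]COC[*]"))      # [*]CCO[*]
print(are_same_polymer("[*]CCCCCC(=O)N[*]",
                       "[*]CCCCCC(=O)NCCCCCC(=O)N[*]"))  # True (Nylon 6)

# generate hypothetical polymers from a 20-monomer seed corpus
lib = build_library(seed_monomers(20, seed=1))
hypo = combine(lib, 5, seed=17)
for p in hypo:
    print(p)
```

which prints `[*]CCO[*]` twice (one polymer, two writings), `True`,
and five valid, canonical, deduplicated hypothetical polymers:

```
[*]CCC(CC)CCCN[*]
[*]CCC(C)C[*]
[*]CC(C)CCCC([*])Cl
[*]CCCCNC(Cc1ccc([*])cc1)C(C)C
[*]CCC(=O)CCN[*]
```

Training a fingerprint model and a property predictor from the shell:

```bash
polylingua --seed 1 fixtures --kind monomers --n 40 -o monomers.txt
polylingua --seed 1 generate --corpus monomers.txt --n 20000 -o corpus.txt
polylingua --seed 1 train-lm --corpus corpus.txt -o lmdir/
polylingua --seed 1 fixtures --kind properties --n 2000 -o props.csv
polylingua --seed 1 train-props --data props.csv -o run/
polylingua predict --run run/ --in monomers.txt --properties Tg,rho -o pred.csv
```

`train-lm` prints the held-out masked-token F1; `train-props` prints
the five-fold validation R² (mean ± σ) and the meta learner's
validation R²; `predict` writes per-polymer predictions in native
units and prints a min/mean/max summary per property for screening.

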