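"""Shared fixtures.

The expensive objects (generated corpus, trained mini encoder) are
session-scoped so the language-model checks share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from polylingua import (TrainConfig, build_library, build_vocab, combine,
                        seed_monomers, train_mlm)

# a spread of chemistries: vinyls, ethers, esters, amides, aromatic
# backbones, halogens, nitriles, fused side groups
FIXTURE_POLYMERS = [
    "[*]C[*]", "[*]CC[*]", "[*]CCO[*]", "[*]COC[*]",
    "[*]CC([*])C", "[*]CC([*])CC", "[*]CC([*])CCC",
    "[*]CC([*])c1ccccc1", "[*]CC([*])c1ccncc1", "[*]CC([*])Cl",
    "[*]CC([*])C#N", "[*]CC([*])C(=O)OC", "[*]CC([*])OC(C)=O",
    "[*]CCCCCC(=O)N[*]", "[*]CCCC(=O)N[*]", "[*]CCC(=O)O[*]",
    "[*]CCCCC(=O)O[*]", "[*]c1ccc([*])cc1", "[*]Cc1ccc(C[*])cc1",
    "[*]COC(=O)c1ccc(C(=O)O[*])cc1",
    "[*]Oc1ccc(C(C)(C)c2ccc(OC(=O)[*])cc2)cc1",
    "[*]CCS[*]", "[*]CCN[*]", "[*]CC(C)O[*]", "[*]CC([*])c1ccc(C)cc1",
]


@pytest.fixture(scope="session")
def fixture_polymers():
    return list(FIXTURE_POLYMERS)


@pytest.fixture(scope="session")
def vocab():
    return build_vocab()


@pytest.fixture(scope="session")
def small_corpus():
    """~3000 generated hypothetical polymers for quick LM training."""
    lib = build_library(seed_monomers(40, seed=1))
    return combine(lib, 3000, seed=5)


@pytest.fixture(scope="session")
def mini_lm(small_corpus, vocab):
    """A briefly trained mini encoder shared across LM tests."""
    model, metrics = train_mlm(small_corpus,
                               TrainConfig(epochs=2, batch_size=64),
                               seed=11, vocab=vocab, assume_canonical=True)
    return model, vocab, metrics
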