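"""Deterministic PSMILES tokenizer.

The vocabulary covers every character class that can occur in a
canonical PSMILES string — the upper- and lowercase forms of the 118
element symbols, the digits used for ring closures, SMILES punctuation
including the ``[*]`` endpoint marker — plus the auxiliary tokens of
BERT-style encoders ([CLS], [SEP], [MASK], [PAD], [UNK] and the
word-start marker ``_``).  Segmentation is greedy longest-match, so
two-character element symbols such as ``Cl`` or ``Br`` tokenize as one
token.  Joining the interior tokens of a sequence reproduces the input
string exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = ["Vocabulary", "TokenSequence", "build_vocab", "tokenize",
           "detokenize", "mask_tokens"]

PAD, UNK, CLS, SEP, MASK, WORD_START = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]", "_"
AUX_TOKENS = (PAD, UNK, CLS, SEP, MASK, WORD_START)

_PUNCTUATION = list("()[]=#-+/\\@%.:*$")


@dataclass(frozen=True)
class Vocabulary:
    tokens: tuple[str, ...]
    ids: dict[str, int] = field(hash=False, compare=False, default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "ids", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    def id(self, token: str) -> int:
        return self.ids.get(token, self.ids[UNK])

    def token(self, idx: int) -> str:
        return self.tokens[idx]

    @property
    def aux_ids(self) -> frozenset[int]:
        return frozenset(self.ids[t] for t in AUX_TOKENS)


@dataclass
class TokenSequence:
    """Integer token ids starting ``[CLS] _`` and ending ``[SEP]``, with
    a binary attention mask marking non-padding positions."""

    ids: np.ndarray
    attention_mask: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.attention_mask = np.asarray(self.attention_mask, dtype=np.int64)
        if self.ids.shape != self.attention_mask.shape:
            raise ValueError("ids and attention_mask lengths differ")

    def __len__(self) -> int:
        return len(self.ids)


def build_vocab() -> Vocabulary:
    """Deterministic vocabulary over the PSMILES character classes."""
    tokens: list[str] = list(AUX_TOKENS)
    tokens.append("[*]")
    tokens.extend(_PUNCTUATION)
    tokens.extend(str(d) for d in range(10))
    table = Chem.GetPeriodicTable()
    seen = set(tokens)
    for z in range(1, 119):
        sym = table.GetElementSymbol(z)
        for form in (sym, sym.lower()):
            if form not in seen:
                seen.add(form)
                tokens.append(form)
    return Vocabulary(tuple(tokens))


def tokenize(vocab: Vocabulary, p: str, max_len: int | None = None) -> TokenSequence:
    """Greedy longest-match segmentation wrapped in ``[CLS] _ ... [SEP]``.

    Characters outside the vocabulary map to ``[UNK]`` (logged by the
    caller's validation; cannot occur for canonical PSMILES).
    """
    max_tok = 3  # longest token is "[*]"
    toks: list[str] = [CLS, WORD_START]
    i = 0
    while i < len(p):
        for width in range(min(max_tok, len(p) - i), 0, -1):
            cand = p[i:i + width]
            if cand in vocab.ids and cand not in AUX_TOKENS:
                toks.append(cand)
                i += width
                break
        else:
            toks.append(UNK)
            i += 1
    toks.append(SEP)
    if max_len is not None and len(toks) > max_len:
        toks = toks[:max_len - 1] + [SEP]
    ids = np.array([vocab.id(t) for t in toks], dtype=np.int64)
    return TokenSequence(ids, np.ones_like(ids))


def detokenize(vocab: Vocabulary, seq: TokenSequence) -> str:
    """Inverse of :func:`tokenize` on the interior tokens."""
    out = []
    for idx, m in zip(seq.ids, seq.attention_mask):
        tok = vocab.token(int(idx))
        if m and tok not in AUX_TOKENS:
            out.append(tok)
    return "".join(out)


def mask_tokens(seq: TokenSequence, vocab: Vocabulary, rate: float = 0.15,
                seed: int = 0,
                rng: np.random.Generator | None = None) -> tuple[TokenSequence, np.ndarray, np.ndarray]:
    """Select ``ceil(rate * interior)`` non-auxiliary positions for the
    fill-in-the-blanks task.

    Of the selected positions 80% become ``[MASK]``, 10% a random
    non-auxiliary vocabulary token and 10% stay unchanged.  Returns the
    masked sequence, the selected positions, and the original ids.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    aux = vocab.aux_ids
    maskable = np.array([i for i, (t, m) in enumerate(zip(seq.ids, seq.attention_mask))
                         if m and int(t) not in aux], dtype=np.int64)
    if maskable.size == 0:
        raise ValueError("sequence has no maskable positions")
    n_sel = max(1, math.ceil(rate * maskable.size))
    sel = rng.choice(maskable, size=min(n_sel, maskable.size), replace=False)
    sel.sort()
    labels = seq.ids[sel].copy()
    new_ids = seq.ids.copy()
    draw = rng.random(sel.size)
    non_aux = np.array([i for i in range(len(vocab)) if i not in aux])
    for j, pos in enumerate(sel):
        if draw[j] < 0.8:
            new_ids[pos] = vocab.ids[MASK]
        elif draw[j] < 0.9:
            new_ids[pos] = int(rng.choice(non_aux))
        # else: unchanged
    return TokenSequence(new_ids, seq.attention_mask.copy()), sel, labels
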