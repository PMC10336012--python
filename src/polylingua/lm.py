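"""Masked-language-model training and polymer fingerprinting.

The encoder is trained on canonical PSMILES strings with the
fill-in-the-blanks objective: 15% of the non-auxiliary tokens are
hidden (80% ``[MASK]``, 10% random token, 10% unchanged) and the model
predicts them from the surrounding context.  The polymer fingerprint is
the sentence average — the mean over non-padding token positions of the
last encoder layer's latents — so its length equals the model width D
and it is identical for every rewriting of a polymer, because
canonicalization precedes tokenization.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF

from . import vocab as V
from .psmiles import canonicalize
from .transformer import Adam, EncoderConfig, EncoderModel, MINI

logger = logging.getLogger(__name__)

__all__ = ["MLMetrics", "TrainConfig", "train_mlm", "fingerprint",
           "fingerprint_many", "attention_summary", "ffn_activation_nmf",
           "save_lm", "load_lm", "PRETRAIN_CORPUS", "pretrain_config",
           "pretrain_corpus", "pretrain", "ambiguity_ceiling"]


@dataclass
class MLMetrics:
    """Masked-token micro-averaged F1 (equal to accuracy for single-label
    prediction) and the mean cross-entropy, on held-out data."""

    f1: float
    cross_entropy: float

    def __post_init__(self):
        if not 0.0 <= self.f1 <= 1.0:
            raise ValueError("F1 must lie in [0, 1]")


@dataclass
class TrainConfig:
    epochs: int = 3
    batch_size: int = 64
    lr: float = 1e-3
    lr_final: float | None = None  # cosine-decay floor; None disables decay
    adam_beta2: float = 0.999
    mask_rate: float = 0.15
    val_fraction: float = 0.2  # 80/20 train/validation split
    warmup_steps: int = 100
    encoder: EncoderConfig | None = None  # default: MINI geometry
    log_every: int = 200
    eval_each_epoch: bool = False  # log validation F1 after every epoch


def _encode_corpus(corpus, vocab, max_len):
    seqs = [V.tokenize(vocab, p, max_len=max_len) for p in corpus]
    return seqs


def _batches(seqs, idx, batch_size):
    """Length-bucketed batches (sorting keeps padding waste low)."""
    order = sorted(idx, key=lambda i: len(seqs[i]))
    for start in range(0, len(order), batch_size):
        chunk = order[start:start + batch_size]
        T = max(len(seqs[i]) for i in chunk)
        ids = np.zeros((len(chunk), T), dtype=np.int64)
        mask = np.zeros((len(chunk), T), dtype=np.int64)
        for r, i in enumerate(chunk):
            s = seqs[i]
            ids[r, :len(s)] = s.ids
            mask[r, :len(s)] = s.attention_mask
        yield chunk, ids, mask


def _mask_batch(ids, mask, vocab, rate, rng):
    """Vectorized 80/10/10 masking of a padded batch."""
    aux = np.array(sorted(vocab.aux_ids))
    maskable = mask.astype(bool) & ~np.isin(ids, aux)
    B, T = ids.shape
    label_pos = np.zeros((B, T), dtype=bool)
    for b in range(B):
        cand = np.flatnonzero(maskable[b])
        n_sel = max(1, math.ceil(rate * cand.size))
        label_pos[b, rng.choice(cand, size=n_sel, replace=False)] = True
    labels = ids[label_pos]
    new_ids = ids.copy()
    draw = rng.random(int(label_pos.sum()))
    non_aux = np.array([i for i in range(len(vocab)) if i not in vocab.aux_ids])
    repl = np.where(draw < 0.8, vocab.ids[V.MASK],
                    np.where(draw < 0.9, rng.choice(non_aux, size=draw.size),
                             labels))
    new_ids[label_pos] = repl
    return new_ids, label_pos, labels


def train_mlm(corpus, config: TrainConfig | None = None, seed: int = 0,
              vocab: V.Vocabulary | None = None,
              assume_canonical: bool = False) -> tuple[EncoderModel, MLMetrics]:
    """Train the encoder on the fill-in-the-blanks task.

    The corpus is split 80/20 into training and validation; the reported
    metrics are measured on the validation part with a fixed masking
    seed.  One global seed drives initialization, shuffling and masking.
    """
    if not corpus:
        raise ValueError("empty corpus")
    config = config or TrainConfig()
    vocab = vocab or V.build_vocab()
    enc_cfg = config.encoder or MINI(len(vocab))
    if enc_cfg.vocab_size != len(vocab):
        raise ValueError("encoder vocab_size does not match vocabulary")
    if not assume_canonical:
        corpus = [canonicalize(p) for p in corpus]
    seqs = _encode_corpus(corpus, vocab, enc_cfg.max_len)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(seqs))
    n_val = max(1, int(round(config.val_fraction * len(seqs))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        train_idx = val_idx

    model = EncoderModel(enc_cfg, seed=seed)
    opt = Adam(model.params, lr=config.lr, beta2=config.adam_beta2,
               warmup=config.warmup_steps)
    steps_per_epoch = max(1, -(-train_idx.size // config.batch_size))
    total_steps = steps_per_epoch * config.epochs
    step = 0
    for epoch in range(config.epochs):
        epoch_order = rng.permutation(train_idx)
        losses = []
        for _, ids, mask in _batches(seqs, list(epoch_order), config.batch_size):
            if config.lr_final is not None:
                frac = min(1.0, step / max(1, total_steps))
                opt.lr = config.lr_final + 0.5 * (config.lr - config.lr_final) * (
                    1.0 + math.cos(math.pi * frac))
            mids, label_pos, labels = _mask_batch(ids, mask, vocab,
                                                  config.mask_rate, rng)
            loss, grads = model.loss_and_grads(mids, mask, label_pos, labels)
            opt.step(model.params, grads)
            losses.append(loss)
            step += 1
            if step % config.log_every == 0:
                logger.info("mlm step %d epoch %d loss %.4f", step, epoch,
                            float(np.mean(losses[-config.log_every:])))
        logger.info("mlm epoch %d mean loss %.4f", epoch, float(np.mean(losses)))
        if config.eval_each_epoch:
            sub = [seqs[i] for i in val_idx[:1000]]
            em = evaluate_mlm(model, sub, vocab, rate=config.mask_rate,
                              seed=seed + 1, batch_size=config.batch_size)
            logger.info("mlm epoch %d val F1 %.4f ce %.4f", epoch, em.f1,
                        em.cross_entropy)
    model.trained = True
    metrics = evaluate_mlm(model, [seqs[i] for i in val_idx], vocab,
                           rate=config.mask_rate, seed=seed + 1,
                           batch_size=config.batch_size)
    logger.info("mlm validation F1 %.4f ce %.4f", metrics.f1, metrics.cross_entropy)
    return model, metrics


def evaluate_mlm(model, seqs, vocab, rate=0.15, seed=1, batch_size=64) -> MLMetrics:
    """Masked-token F1 and cross-entropy on a held-out token-sequence set."""
    rng = np.random.default_rng(seed)
    correct = total = 0
    ce_sum = 0.0
    for _, ids, mask in _batches(seqs, list(range(len(seqs))), batch_size):
        mids, label_pos, labels = _mask_batch(ids, mask, vocab, rate, rng)
        logits = model.forward(mids, mask)["logits"]
        sel = logits[label_pos]
        pred = sel.argmax(-1)
        correct += int((pred == labels).sum())
        z = sel - sel.max(-1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(-1, keepdims=True))
        ce_sum += float(-logp[np.arange(labels.size), labels].sum())
        total += labels.size
    return MLMetrics(correct / total, ce_sum / total)


def _forward_single(model, vocab, p, collect=False):
    can = canonicalize(p)
    seq = V.tokenize(vocab, can, max_len=model.config.max_len)
    out = model.forward(seq.ids[None, :], seq.attention_mask[None, :],
                        collect=collect)
    return can, seq, out


def fingerprint(model: EncoderModel, vocab: V.Vocabulary, p: str) -> np.ndarray:
    """Sentence-average fingerprint: canonicalize, tokenize, encode, and
    average the last-layer latents over non-padding tokens (auxiliary
    tokens included, per the sentence-average pooling convention)."""
    _, seq, out = _forward_single(model, vocab, p)
    h = out["hidden"][0]
    w = seq.attention_mask.astype(h.dtype)
    return (h * w[:, None]).sum(0) / w.sum()


def fingerprint_many(model, vocab, polymers, batch_size=64) -> np.ndarray:
    """Vectorized :func:`fingerprint` over a list of PSMILES."""
    seqs = [V.tokenize(vocab, canonicalize(p), max_len=model.config.max_len)
            for p in polymers]
    out = np.zeros((len(seqs), model.config.d_model), dtype=np.float64)
    for chunk, ids, mask in _batches(seqs, list(range(len(seqs))), batch_size):
        h = model.forward(ids, mask)["hidden"]
        w = mask.astype(h.dtype)
        fp = (h * w[:, :, None]).sum(1) / w.sum(1, keepdims=True)
        for r, i in enumerate(chunk):
            out[i] = fp[r]
    return out


def attention_summary(model: EncoderModel, vocab: V.Vocabulary, p: str) -> np.ndarray:
    """Token-by-token attention map summed over every head of every
    encoder layer and normalized to a maximum of 1."""
    _, seq, out = _forward_single(model, vocab, p, collect=True)
    total = sum(a[0].sum(0) for a in out["attn"])  # sum heads, then layers
    return total / total.max()


def ffn_activation_nmf(model: EncoderModel, vocab: V.Vocabulary, p: str,
                       k: int = 4, seed: int = 0):
    """Rank-``k`` non-negative factorization of the (token x neuron)
    feed-forward activation matrix (post-ReLU, hence non-negative;
    clipped at zero defensively).  Returns (loadings, components) with
    loadings (T, k) and components (k, neurons)."""
    _, seq, out = _forward_single(model, vocab, p, collect=True)
    acts = np.concatenate([f[0] for f in out["ffn"]], axis=1)  # (T, L*F)
    acts = np.clip(acts, 0.0, None)
    if k > min(acts.shape):
        raise ValueError(f"k={k} exceeds activation matrix rank bound {min(acts.shape)}")
    nmf = NMF(n_components=k, init="nndsvda", random_state=seed, max_iter=500)
    W = nmf.fit_transform(acts)
    return W, nmf.components_


def save_lm(model: EncoderModel, vocab: V.Vocabulary, path: str) -> None:
    """Persist weights, config and vocabulary to a model directory."""
    model.save(path)
    with open(os.path.join(path, "vocab.json"), "w") as fh:
        json.dump(list(vocab.tokens), fh)


def load_lm(path: str) -> tuple[EncoderModel, V.Vocabulary]:
    if not os.path.isdir(path):
        raise FileNotFoundError(f"no model directory at {path}")
    model = EncoderModel.load(path)
    with open(os.path.join(path, "vocab.json")) as fh:
        vocab = V.Vocabulary(tuple(json.load(fh)))
    return model, vocab


# ---------------------------------------------------------------- pretraining
#: study conditions of the desk-scale pretraining run: a 20,000-string
#: corpus of hypothetical polymers recombined from 40 seed monomers with
#: chains of up to 8 BRICS fragments (longer chains carry more context
#: per masked token, which is what makes near-perfect fill-in-the-blanks
#: achievable at this corpus size)
PRETRAIN_CORPUS = {"n_monomers": 40, "monomer_seed": 1, "n_strings": 20_000,
                   "max_fragments": 8, "corpus_seed": 5}


def pretrain_config(vocab_size: int, epochs: int = 16) -> TrainConfig:
    """Training schedule of the desk-scale pretraining run."""
    from .transformer import EncoderConfig

    return TrainConfig(epochs=epochs, batch_size=128, lr=2e-3, lr_final=1e-4,
                       warmup_steps=100,
                       encoder=EncoderConfig(vocab_size, n_layers=2,
                                             n_heads=4, d_model=96,
                                             d_ff=192, max_len=96))


def pretrain_corpus(seed_offset: int = 0) -> list[str]:
    """Generate the pretraining corpus under the standard conditions."""
    from .fixtures import seed_monomers
    from .fragments import build_library, combine

    cc = PRETRAIN_CORPUS
    monomers = seed_monomers(cc["n_monomers"], seed=cc["monomer_seed"])
    lib = build_library(monomers)
    return combine(lib, cc["n_strings"], seed=cc["corpus_seed"] + seed_offset,
                   max_fragments=cc["max_fragments"])


def pretrain(seed: int = 7, epochs: int = 16,
             corpus: list[str] | None = None) -> tuple[EncoderModel, V.Vocabulary, MLMetrics]:
    """Run the full desk-scale pretraining (corpus generation + MLM)."""
    vocab = V.build_vocab()
    if corpus is None:
        corpus = pretrain_corpus()
    model, metrics = train_mlm(corpus, pretrain_config(len(vocab), epochs),
                               seed=seed, vocab=vocab, assume_canonical=True)
    return model, vocab, metrics


def ambiguity_ceiling(corpus: list[str], vocab: V.Vocabulary | None = None,
                      rate: float = 0.15, n_trials: int = 1000,
                      seed: int = 0, max_len: int = 96) -> float:
    """Upper bound on achievable masked-token F1 for a corpus.

    Masked-token prediction cannot beat the corpus's intrinsic
    ambiguity: whenever the visible context of a masked string is
    consistent with more than one corpus string, the differing masked
    positions cannot all be recovered.  This estimates, by Monte Carlo
    over mask draws, the fraction of masked tokens whose value is not
    determined by the context (assuming an even split among the
    alternatives, hence a bound, not an exact value).  Short repeat
    units with interchangeable alkyl runs are the dominant source of
    ambiguity; the bound rises toward 1 as chains grow longer.
    """
    from collections import defaultdict

    vocab = vocab or V.build_vocab()
    rng = np.random.default_rng(seed)
    seqs = [V.tokenize(vocab, p, max_len=max_len).ids for p in corpus]
    by_len = defaultdict(list)
    for s in seqs:
        by_len[len(s)].append(s)
    by_len = {L: np.array(v) for L, v in by_len.items()}
    aux = vocab.aux_ids
    n_tok = n_tok_amb = 0
    picks = rng.choice(len(seqs), size=min(n_trials, len(seqs)), replace=False)
    for i in picks:
        s = seqs[i]
        maskable = [j for j, t in enumerate(s) if int(t) not in aux]
        k = max(1, math.ceil(rate * len(maskable)))
        sel = rng.choice(maskable, size=k, replace=False)
        visible = np.ones(len(s), dtype=bool)
        visible[sel] = False
        group = by_len[len(s)]
        labels = group[(group[:, visible] == s[visible]).all(axis=1)][:, sel]
        variants = np.unique(labels, axis=0)
        n_tok += k
        if len(variants) > 1:
            n_tok_amb += int((variants != variants[0]).any(axis=0).sum())
    return 1.0 - 0.5 * n_tok_amb / n_tok
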