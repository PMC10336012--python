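"""Language-model training, fingerprints and introspection.

The session-scoped ``mini_lm`` fixture trains one small encoder on a
generated corpus; the checks here probe the contracts that do not need
a fully converged model (convergence itself is exercised in the
acceptance suite).
"""

from __future__ import annotations

import numpy as np
import pytest

from polylingua import (TrainConfig, attention_summary, canonicalize,
                        ffn_activation_nmf, fingerprint, fingerprint_many,
                        load_lm, rewriting_suite, save_lm, train_mlm)
from polylingua.transformer import EncoderConfig
from polylingua.vocab import tokenize


class TestTraining:
    def test_loss_decreases_on_toy_corpus(self, small_corpus, vocab):
        cfg = TrainConfig(epochs=3, batch_size=32, warmup_steps=10,
                          encoder=EncoderConfig(len(vocab), n_layers=1,
                                                n_heads=2, d_model=32,
                                                d_ff=64, max_len=96))
        model, metrics = train_mlm(small_corpus[:1000], cfg, seed=0,
                                   vocab=vocab, assume_canonical=True)
        # an untrained model is at chance (cross-entropy ~ log V = 5.6);
        # a few epochs of a deliberately small model must beat it clearly
        assert metrics.cross_entropy < 3.0
        assert model.trained

    def test_memorizes_tiny_corpus(self, small_corpus, vocab):
        """Capacity exceeds data on a tiny corpus: training F1
        approaches 1 given enough passes (each pass only masks 15%)."""
        corpus = small_corpus[:20]
        cfg = TrainConfig(epochs=300, batch_size=20, lr=2e-3, warmup_steps=30,
                          val_fraction=0.05,
                          encoder=EncoderConfig(len(vocab), n_layers=2,
                                                n_heads=4, d_model=64,
                                                d_ff=128, max_len=96))
        model, _ = train_mlm(corpus, cfg, seed=1, vocab=vocab,
                             assume_canonical=True)
        from polylingua.lm import evaluate_mlm

        seqs = [tokenize(vocab, p) for p in corpus]
        train_metrics = evaluate_mlm(model, seqs, vocab, seed=2)
        assert train_metrics.f1 > 0.95

    def test_empty_corpus_rejected(self, vocab):
        with pytest.raises(ValueError):
            train_mlm([], seed=0, vocab=vocab)

    def test_ambiguity_ceiling_rises_with_chain_length(self, vocab):
        """Masked-token prediction has an intrinsic ceiling set by how
        often the visible context is consistent with several corpus
        strings; longer fragment chains carry more context and push
        the ceiling up."""
        from polylingua import build_library, combine, seed_monomers
        from polylingua.lm import ambiguity_ceiling

        lib = build_library(seed_monomers(15, seed=2))
        short = combine(lib, 1500, seed=4, max_fragments=2)
        long_ = combine(lib, 1500, seed=4, max_fragments=8)
        c_short = ambiguity_ceiling(short, vocab, n_trials=400, seed=0)
        c_long = ambiguity_ceiling(long_, vocab, n_trials=400, seed=0)
        assert c_short <= c_long
        assert c_long <= 1.0


class TestFingerprint:
    def test_length_equals_model_width(self, mini_lm):
        model, vocab, _ = mini_lm
        fp = fingerprint(model, vocab, "[*]CC([*])CC")
        assert fp.shape == (model.config.d_model,)
        assert np.isfinite(fp).all()

    def test_identical_across_rewritings(self, mini_lm):
        model, vocab, _ = mini_lm
        p = "[*]CC([*])c1ccncc1"
        ref = fingerprint(model, vocab, p)
        for v in rewriting_suite(p, 6, seed=3):
            assert np.array_equal(fingerprint(model, vocab, v), ref)

    def test_deterministic_across_calls(self, mini_lm):
        model, vocab, _ = mini_lm
        a = fingerprint(model, vocab, "[*]CCO[*]")
        b = fingerprint(model, vocab, "[*]CCO[*]")
        assert np.array_equal(a, b)

    def test_batched_matches_single(self, mini_lm):
        model, vocab, _ = mini_lm
        polys = ["[*]CC([*])CC", "[*]CCO[*]", "[*]CC([*])c1ccccc1"]
        many = fingerprint_many(model, vocab, polys)
        for i, p in enumerate(polys):
            assert np.allclose(many[i], fingerprint(model, vocab, p), atol=1e-5)

    def test_fully_dense_over_generated_polymers(self, mini_lm, small_corpus):
        model, vocab, _ = mini_lm
        fps = fingerprint_many(model, vocab, small_corpus[:100])
        assert (fps == 0.0).sum() == 0


class TestIntrospection:
    def test_attention_summary_shape_and_range(self, mini_lm):
        model, vocab, _ = mini_lm
        p = canonicalize("[*]CC([*])CC")
        seq = tokenize(vocab, p)
        m = attention_summary(model, vocab, p)
        assert m.shape == (len(seq), len(seq))
        assert m.max() == pytest.approx(1.0)
        assert m.min() >= 0.0

    def test_nmf_factors_nonnegative_and_k_matches(self, mini_lm):
        model, vocab, _ = mini_lm
        W, H = ffn_activation_nmf(model, vocab, "[*]CC([*])c1ccncc1", k=4)
        assert W.shape[1] == 4 and H.shape[0] == 4
        assert (W >= 0).all() and (H >= 0).all()

    def test_nmf_error_non_increasing_in_k(self, mini_lm):
        model, vocab, _ = mini_lm
        from sklearn.decomposition import NMF
        from polylingua.lm import _forward_single

        _, _, out = _forward_single(model, vocab, "[*]CC([*])c1ccccc1",
                                    collect=True)
        acts = np.clip(np.concatenate([f[0] for f in out["ffn"]], axis=1), 0, None)
        errs = []
        for k in (1, 2, 4):
            nmf = NMF(n_components=k, init="nndsvda", random_state=0,
                      max_iter=500)
            W = nmf.fit_transform(acts)
            errs.append(np.linalg.norm(acts - W @ nmf.components_))
        assert errs[0] >= errs[1] >= errs[2]

    def test_nmf_k_exceeding_rank_bound_rejected(self, mini_lm):
        model, vocab, _ = mini_lm
        with pytest.raises(ValueError):
            ffn_activation_nmf(model, vocab, "[*]C[*]", k=50)


class TestPersistence:
    def test_save_load_reproduces_fingerprints_bitwise(self, mini_lm, tmp_path):
        model, vocab, _ = mini_lm
        path = str(tmp_path / "lm")
        save_lm(model, vocab, path)
        clone, vocab2 = load_lm(path)
        assert vocab2.tokens == vocab.tokens
        p = "[*]CC([*])C(=O)OC"
        assert np.array_equal(fingerprint(model, vocab, p),
                              fingerprint(clone, vocab2, p))

    def test_missing_directory_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_lm(str(tmp_path / "nope"))
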