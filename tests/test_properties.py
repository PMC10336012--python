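"""Copolymer fingerprints, target transforms, splits, the CV ensemble,
the meta learner and the evaluation metrics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polylingua import (GeneratorConfig, PolymerRecord, PredictorConfig,
                        REGISTRY, combine_fingerprints, evaluate,
                        inverse_transform, make_splits, predict,
                        seed_monomers, synth_properties, train_ensemble,
                        train_meta, transform_target)
from polylingua.descriptors import descriptor_fingerprint
from polylingua.properties import _rows


class TestRegistry:
    def test_29_properties_with_dielectric_frequency_family(self):
        # the dielectric constant k_f counts once though 9 frequencies
        # are registered individually
        n_kf = sum(1 for s in REGISTRY if s.startswith("k") and s[1:2].isdigit())
        assert n_kf == 9
        assert len(REGISTRY) - (n_kf - 1) == 29

    def test_log_transform_flags(self):
        flagged = {s for s, p in REGISTRY.items() if p.log_transform}
        assert flagged == {"eps_b", "mu_O2", "mu_CO2", "mu_N2", "mu_H2",
                           "mu_He", "mu_CH4"}


class TestCombineFingerprints:
    def test_single_part_identity(self):
        f = np.arange(5.0)
        assert np.array_equal(combine_fingerprints([(f, 1.0)]), f)

    def test_order_invariance(self):
        a, b = np.arange(5.0), np.ones(5)
        x = combine_fingerprints([(a, 0.3), (b, 0.7)])
        y = combine_fingerprints([(b, 0.7), (a, 0.3)])
        assert np.allclose(x, y)

    def test_convexity_of_equal_parts(self):
        f = np.array([1.0, -2.0, 3.0])
        assert np.allclose(combine_fingerprints([(f, 0.5), (f, 0.5)]), f)

    def test_bad_fractions_and_lengths_error(self):
        with pytest.raises(ValueError):
            combine_fingerprints([(np.ones(3), 0.5), (np.ones(3), 0.4)])
        with pytest.raises(ValueError):
            combine_fingerprints([(np.ones(3), 0.5), (np.ones(4), 0.5)])


class TestTransforms:
    def test_log_values(self):
        assert transform_target("mu_O2", 0.0) == 0.0
        assert transform_target("mu_CO2", 999.0) == pytest.approx(3.0)
        assert transform_target("Tg", 450.0) == 450.0

    def test_roundtrip_exact(self):
        rng = np.random.default_rng(0)
        for s in ("mu_CH4", "eps_b", "Tm"):
            x = rng.uniform(0, 1e3, 50)
            assert np.allclose(inverse_transform(s, transform_target(s, x)), x)

    def test_negative_input_rejected_for_log_properties(self):
        with pytest.raises(ValueError):
            transform_target("mu_He", -1.0)


@pytest.fixture(scope="module")
def synthetic():
    mono = seed_monomers(30, seed=1)
    records = synth_properties(mono, GeneratorConfig(seed=2, n_records=1500))
    fpd = {p: descriptor_fingerprint(p) for p in mono}
    fps = np.array([combine_fingerprints([(fpd[p], c) for p, c in r.comonomers])
                    for r in records])
    mu, sd = fps.mean(0), fps.std(0)
    sd[sd < 1e-12] = 1.0
    return records, (fps - mu) / sd


class TestSplits:
    def test_proportions_and_partition(self, synthetic):
        records, fps = synthetic
        plan = make_splits(records, seed=3)
        n = len(records)
        assert abs(len(plan.meta_train) / n - 0.2) < 0.02
        all_cv = np.concatenate(plan.folds)
        assert len(set(all_cv.tolist())) == all_cv.size
        assert not set(all_cv.tolist()) & set(plan.meta_train.tolist())
        assert all_cv.size + plan.meta_train.size == n

    def test_deterministic_under_seed(self, synthetic):
        records, _ = synthetic
        a = make_splits(records, seed=5)
        b = make_splits(records, seed=5)
        assert np.array_equal(a.meta_train, b.meta_train)
        for fa, fb in zip(a.folds, b.folds):
            assert np.array_equal(fa, fb)

    def test_stratification_spreads_values_over_folds(self, synthetic):
        records, _ = synthetic
        plan = make_splits(records, seed=3)
        tg = [r.value for r in records if r.symbol == "Tg"]
        lo, hi = np.quantile(tg, [0.25, 0.75])
        for fold in plan.folds:
            vals = [records[i].value for i in fold if records[i].symbol == "Tg"]
            assert min(vals) < lo and max(vals) > hi


@pytest.fixture(scope="module")
def trained(synthetic):
    records, fps = synthetic
    plan = make_splits(records, seed=3)
    ens = train_ensemble(plan, fps, records, seed=4)
    meta = train_meta(ens, plan, fps, records, seed=4)
    return records, fps, plan, ens, meta


class TestEnsembleAndMeta:
    def test_five_fold_models(self, trained):
        _, _, _, ens, _ = trained
        assert len(ens.models) == 5

    def test_every_model_predicts_every_property(self, trained):
        records, fps, _, ens, _ = trained
        preds = ens.fold_predictions(fps[:7], ["Tg"] * 7)
        assert preds.shape == (7, 5)
        for s in ens.symbols:
            assert np.isfinite(ens.fold_predictions(fps[:3], [s] * 3)).all()

    def test_meta_inference_deterministic(self, trained):
        records, fps, _, ens, meta = trained
        p1 = meta.predict(ens.fold_predictions(fps[:10], ["Tm"] * 10), ["Tm"] * 10)
        p2 = meta.predict(ens.fold_predictions(fps[:10], ["Tm"] * 10), ["Tm"] * 10)
        assert np.array_equal(p1, p2)

    def test_predict_shape_units_and_summary(self, trained):
        records, fps, _, ens, meta = trained
        out, stats = predict(meta, ens, fps[:6], ["Tg", "mu_CO2"], summary=True)
        assert out.shape == (6, 2)
        # log-transformed property returned in native units (can exceed
        # the transformed scale's range)
        assert set(stats["Tg"]) == {"min", "mean", "max"}
        assert np.isfinite(out).all()

    def test_noiseless_recovery(self):
        """With zero noise the generator's mapping is linear in the
        descriptors, so folds and meta should be near-perfect."""
        mono = seed_monomers(25, seed=1)
        records = synth_properties(mono, GeneratorConfig(seed=6, n_records=900,
                                                         sigma=0.0))
        fpd = {p: descriptor_fingerprint(p) for p in mono}
        fps = np.array([combine_fingerprints([(fpd[p], c) for p, c in r.comonomers])
                        for r in records])
        mu, sd = fps.mean(0), fps.std(0)
        sd[sd < 1e-12] = 1.0
        fps = (fps - mu) / sd
        plan = make_splits(records, seed=7)
        ens = train_ensemble(plan, fps, records, seed=7)
        meta = train_meta(ens, plan, fps, records, seed=7)
        assert np.mean(ens.fold_val_r2) > 0.99
        assert meta.validation_r2 > 0.99

    def test_linear_meta_option(self, synthetic):
        records, fps = synthetic
        plan = make_splits(records, seed=3)
        cfg = PredictorConfig(meta="linear")
        ens = train_ensemble(plan, fps, records, cfg, seed=4)
        meta = train_meta(ens, plan, fps, records, cfg, seed=4)
        assert meta.validation_r2 > 0.8


class TestEvaluate:
    def test_perfect_and_mean_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        rep = evaluate(y, y, ["Tg"] * 3)
        assert rep.per_property["Tg"]["r2"] == pytest.approx(1.0)
        assert rep.per_property["Tg"]["rmse"] == pytest.approx(0.0)
        rep = evaluate(np.full(3, 2.0), y, ["Tg"] * 3)
        assert rep.per_property["Tg"]["r2"] == pytest.approx(0.0)

    def test_three_point_worked_example(self):
        rep = evaluate(np.array([1.0, 2.0, 4.0]), np.array([1.0, 2.0, 3.0]),
                       ["Tg"] * 3)
        assert rep.per_property["Tg"]["r2"] == pytest.approx(0.5)
        assert rep.per_property["Tg"]["rmse"] == pytest.approx(1 / np.sqrt(3))

    def test_category_averages_are_member_means(self):
        pred = np.array([1.0, 2.0, 4.0, 1.0, 2.0, 3.0])
        truth = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        rep = evaluate(pred, truth, ["Tg", "Tg", "Tg", "rho", "rho", "rho"])
        t = REGISTRY["Tg"].category
        p = REGISTRY["rho"].category
        assert rep.per_category[t] == pytest.approx(0.5)
        assert rep.per_category[p] == pytest.approx(1.0)
        assert rep.overall_r2 == pytest.approx(0.75)

    def test_empty_or_mismatched_errors(self):
        with pytest.raises(ValueError):
            evaluate(np.array([]), np.array([]), [])


class TestRecordValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PolymerRecord((("[*]CC[*]", 0.5), ("[*]CCO[*]", 0.4)), "Tg", 300.0)

    def test_unregistered_symbol_rejected(self):
        with pytest.raises(KeyError):
            PolymerRecord((("[*]CC[*]", 1.0),), "nope", 1.0)


class TestHypothesisInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1e6, allow_nan=False))
    def test_log_transform_roundtrip_over_domain(self, x):
        y = transform_target("mu_N2", x)
        assert inverse_transform("mu_N2", y) == pytest.approx(x, rel=1e-9,
                                                              abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(0.05, 0.95), st.integers(0, 2 ** 31 - 1))
    def test_copolymer_mixture_is_convex_combination(self, c1, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=6), rng.normal(size=6)
        mixed = combine_fingerprints([(a, c1), (b, 1.0 - c1)])
        lo = np.minimum(a, b) - 1e-9
        hi = np.maximum(a, b) + 1e-9
        assert ((mixed >= lo) & (mixed <= hi)).all()
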