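"""Multitask property prediction on polymer fingerprints.

One selector-conditioned network predicts every registered property:
the input is the polymer fingerprint concatenated with a one-hot
property selector, the output a single scalar on the (optionally
log-transformed) standardized property scale.  Training follows the
stacked five-fold protocol: after a seeded, stratified shuffle, 20% of
the records train a meta learner and 80% are split into five folds;
each fold model trains on the other four folds, and the meta learner
maps the five fold predictions (plus selector) to the final value.

Copolymer fingerprints are composition-weighted sums of the comonomer
fingerprints, F = sum_i c_i F_i, which makes them invariant to comonomer
order and reduces to the homopolymer fingerprint at c = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.neural_network import MLPRegressor

logger = logging.getLogger(__name__)

__all__ = ["PropertyInfo", "REGISTRY", "PolymerRecord", "SplitPlan",
           "PredictorConfig", "MultitaskEnsemble", "MetaLearner",
           "EvaluationReport", "combine_fingerprints", "transform_target",
           "inverse_transform", "make_splits", "train_ensemble", "train_meta",
           "predict", "evaluate"]


@dataclass(frozen=True)
class PropertyInfo:
    symbol: str
    unit: str
    category: str
    log_transform: bool = False  # x -> log10(x + 1)


def _registry() -> dict[str, PropertyInfo]:
    entries: list[PropertyInfo] = []
    T, P = "thermal", "thermodynamic & physical"
    EL, O = "electronic", "optical & dielectric"
    M, G = "mechanical", "permeability"
    entries += [PropertyInfo("Tg", "K", T), PropertyInfo("Tm", "K", T),
                PropertyInfo("Td", "K", T)]
    entries += [PropertyInfo("cp", "J g-1 K-1", P),
                PropertyInfo("Eat", "eV atom-1", P),
                PropertyInfo("Oi", "%", P), PropertyInfo("Xc", "%", P),
                PropertyInfo("Xe", "%", P), PropertyInfo("rho", "g cm-3", P)]
    entries += [PropertyInfo(s, "eV", EL) for s in ("Egc", "Egb", "Eea", "Ei", "Eib")]
    entries += [PropertyInfo("delta", "cal cm-3", EL)]
    entries += [PropertyInfo("nc", "", O), PropertyInfo("ne", "", O),
                PropertyInfo("kc", "", O)]
    entries += [PropertyInfo(f"k{f}", "", O)
                for f in ("1.78", "2", "3", "4", "5", "6", "7", "9", "15")]
    entries += [PropertyInfo("E", "MPa", M), PropertyInfo("sigma_y", "MPa", M),
                PropertyInfo("sigma_b", "MPa", M),
                PropertyInfo("eps_b", "", M, log_transform=True)]
    entries += [PropertyInfo(f"mu_{g}", "barrer", G, log_transform=True)
                for g in ("O2", "CO2", "N2", "H2", "He", "CH4")]
    return {e.symbol: e for e in entries}


#: property registry: glass transition temperature Tg ... gas
#: permeabilities mu_x; permeabilities and elongation at break carry the
#: log10(x+1) training transform
REGISTRY: dict[str, PropertyInfo] = _registry()


@dataclass
class PolymerRecord:
    """One property observation for a homo- or copolymer."""

    comonomers: tuple[tuple[str, float], ...]
    symbol: str
    value: float

    def __post_init__(self):
        fracs = np.array([c for _, c in self.comonomers], dtype=float)
        if len(fracs) < 1 or (fracs <= 0).any() or abs(fracs.sum() - 1.0) > 1e-8:
            raise ValueError("comonomer fractions must be positive and sum to 1")
        if self.symbol not in REGISTRY:
            raise KeyError(f"unregistered property symbol {self.symbol!r}")


def combine_fingerprints(parts: list[tuple[np.ndarray, float]]) -> np.ndarray:
    """Composition-weighted copolymer fingerprint F = sum_i c_i F_i."""
    fracs = np.array([c for _, c in parts], dtype=float)
    if (fracs <= 0).any() or abs(fracs.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must be positive and sum to 1")
    vecs = [np.asarray(f, dtype=float) for f, _ in parts]
    if len({v.shape for v in vecs}) != 1:
        raise ValueError("fingerprint lengths differ")
    return sum(c * v for v, c in zip(vecs, fracs))


def transform_target(symbol: str, x: float | np.ndarray):
    """Apply the property's training transform (log10(x+1) where flagged)."""
    if REGISTRY[symbol].log_transform:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError(f"{symbol} requires x >= 0 for log10(x+1)")
        return np.log10(x + 1.0)
    return np.asarray(x, dtype=float)


def inverse_transform(symbol: str, y: float | np.ndarray):
    if REGISTRY[symbol].log_transform:
        return np.power(10.0, np.asarray(y, dtype=float)) - 1.0
    return np.asarray(y, dtype=float)


@dataclass
class SplitPlan:
    meta_train: np.ndarray          # 20%, trains the meta learner
    folds: list[np.ndarray]         # 5 disjoint folds over the 80% CV part
    strata: dict[int, tuple[str, int]] = field(default_factory=dict)

    @property
    def cv(self) -> np.ndarray:
        return np.concatenate(self.folds)


def make_splits(records: list[PolymerRecord], seed: int = 0, n_folds: int = 5,
                meta_fraction: float = 0.2, n_bins: int = 10) -> SplitPlan:
    """Seeded, property-stratified split into meta-train and CV folds.

    Within each property the records are binned into value quantiles;
    each bin is shuffled and dealt round-robin over (meta, fold 0..4),
    so every fold sees the full value range of every property.
    """
    if not records:
        raise ValueError("no records")
    rng = np.random.default_rng(seed)
    meta, folds = [], [[] for _ in range(n_folds)]
    strata: dict[int, tuple[str, int]] = {}
    per_cycle = int(round(1 / meta_fraction))  # meta gets 1 of every 5 slots
    by_symbol: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_symbol.setdefault(r.symbol, []).append(i)
    for symbol, idx in sorted(by_symbol.items()):
        idx = np.array(idx)
        if idx.size < n_folds:
            logger.warning("property %s has %d records (< %d folds)",
                           symbol, idx.size, n_folds)
        values = np.array([records[i].value for i in idx])
        bins = min(n_bins, max(1, idx.size // n_folds))
        edges = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
        labels = np.searchsorted(edges, values)
        slot = int(rng.integers(per_cycle))  # rotate which slot is meta
        fold_cycle = 0
        for b in range(bins):
            members = idx[labels == b]
            members = members[rng.permutation(members.size)]
            for i in members:
                strata[int(i)] = (symbol, b)
                if slot == 0:
                    meta.append(int(i))
                else:
                    folds[fold_cycle % n_folds].append(int(i))
                    fold_cycle += 1
                slot = (slot + 1) % per_cycle
    return SplitPlan(np.array(sorted(meta)),
                     [np.array(sorted(f)) for f in folds], strata)


@dataclass
class PredictorConfig:
    hidden: tuple[int, ...] = (64, 64)
    activation: str = "relu"
    max_iter: int = 500
    learning_rate_init: float = 1e-3
    alpha: float = 1e-4
    meta: str = "mlp"               # "mlp" or "linear" stacking
    meta_hidden: tuple[int, ...] = (32,)
    meta_max_iter: int = 500


@dataclass
class MultitaskEnsemble:
    models: list            # five fold models
    scalers: list[dict[str, tuple[float, float]]]
    symbols: tuple[str, ...]
    fold_val_r2: list[float]

    def _features(self, fps: np.ndarray, symbols: list[str]) -> np.ndarray:
        onehot = np.zeros((len(symbols), len(self.symbols)))
        lookup = {s: j for j, s in enumerate(self.symbols)}
        for i, s in enumerate(symbols):
            if s not in lookup:
                raise KeyError(f"unregistered property symbol {s!r}")
            onehot[i, lookup[s]] = 1.0
        return np.hstack([fps, onehot])

    def fold_predictions(self, fps: np.ndarray, symbols: list[str]) -> np.ndarray:
        """(n, 5) predictions on the transformed (unstandardized) scale."""
        X = self._features(fps, symbols)
        out = np.zeros((len(symbols), len(self.models)))
        for f, (model, scaler) in enumerate(zip(self.models, self.scalers)):
            y = model.predict(X)
            mu = np.array([scaler[s][0] for s in symbols])
            sd = np.array([scaler[s][1] for s in symbols])
            out[:, f] = y * sd + mu
        return out


@dataclass
class MetaLearner:
    model: object
    symbols: tuple[str, ...]
    validation_r2: float | None = None

    def predict(self, fold_preds: np.ndarray, symbols: list[str]) -> np.ndarray:
        onehot = np.zeros((len(symbols), len(self.symbols)))
        lookup = {s: j for j, s in enumerate(self.symbols)}
        for i, s in enumerate(symbols):
            onehot[i, lookup[s]] = 1.0
        return self.model.predict(np.hstack([fold_preds, onehot]))


def _rows(records, fps, idx, symbols):
    symlist = [records[i].symbol for i in idx]
    y = np.array([transform_target(records[i].symbol, records[i].value)
                  for i in idx], dtype=float)
    return fps[idx], symlist, y


def _fit_scaler(symlist, y):
    scaler = {}
    for s in set(symlist):
        vals = y[[i for i, t in enumerate(symlist) if t == s]]
        sd = float(vals.std())
        scaler[s] = (float(vals.mean()), sd if sd > 1e-12 else 1.0)
    return scaler


def train_ensemble(plan: SplitPlan, fps: np.ndarray, records: list[PolymerRecord],
                   config: PredictorConfig | None = None,
                   seed: int = 0) -> MultitaskEnsemble:
    """Fit one multitask network per CV fold on the other four folds.

    Targets are transformed and standardized per property with statistics
    from the training folds only; fold validation R2 (on the transformed
    scale, pooled over properties) is recorded per fold.
    """
    config = config or PredictorConfig()
    symbols = tuple(sorted({r.symbol for r in records}))
    ens = MultitaskEnsemble([], [], symbols, [])
    for f in range(len(plan.folds)):
        train_idx = np.concatenate([plan.folds[g]
                                    for g in range(len(plan.folds)) if g != f])
        Xf, symlist, y = _rows(records, fps, train_idx, symbols)
        scaler = _fit_scaler(symlist, y)
        for s in symbols:
            scaler.setdefault(s, (0.0, 1.0))
        ys = np.array([(v - scaler[s][0]) / scaler[s][1]
                       for v, s in zip(y, symlist)])
        model = MLPRegressor(hidden_layer_sizes=config.hidden,
                             activation=config.activation,
                             alpha=config.alpha,
                             learning_rate_init=config.learning_rate_init,
                             max_iter=config.max_iter,
                             random_state=seed + f)
        feats = ens._features(Xf, symlist)
        model.fit(feats, ys)
        ens.models.append(model)
        ens.scalers.append(scaler)
        # fold validation on the held-out fold, transformed scale
        Xv, symv, yv = _rows(records, fps, plan.folds[f], symbols)
        pred = model.predict(ens._features(Xv, symv))
        mu = np.array([scaler[s][0] for s in symv])
        sd = np.array([scaler[s][1] for s in symv])
        ens.fold_val_r2.append(float(r2_score(yv, pred * sd + mu)))
    logger.info("fold validation R2: %s",
                ", ".join(f"{v:.3f}" for v in ens.fold_val_r2))
    return ens


def train_meta(ensemble: MultitaskEnsemble, plan: SplitPlan, fps: np.ndarray,
               records: list[PolymerRecord],
               config: PredictorConfig | None = None,
               seed: int = 0) -> MetaLearner:
    """Fit the stacking model on the 20% meta-train records and validate
    it on the 80% CV portion."""
    if not ensemble.models:
        raise ValueError("ensemble is not trained")
    config = config or PredictorConfig()
    Xm, symm, ym = _rows(records, fps, plan.meta_train, ensemble.symbols)
    fold_preds = ensemble.fold_predictions(Xm, symm)
    if config.meta == "linear":
        model = Ridge(alpha=1e-3)
    else:
        model = MLPRegressor(hidden_layer_sizes=config.meta_hidden,
                             max_iter=config.meta_max_iter,
                             random_state=seed + 100)
    meta = MetaLearner(model, ensemble.symbols)
    X = np.hstack([fold_preds, _onehot(symm, ensemble.symbols)])
    model.fit(X, ym)
    Xc, symc, yc = _rows(records, fps, plan.cv, ensemble.symbols)
    pred = meta.predict(ensemble.fold_predictions(Xc, symc), symc)
    meta.validation_r2 = float(r2_score(yc, pred))
    logger.info("meta validation R2 %.3f", meta.validation_r2)
    return meta


def _onehot(symlist, symbols):
    out = np.zeros((len(symlist), len(symbols)))
    lookup = {s: j for j, s in enumerate(symbols)}
    for i, s in enumerate(symlist):
        out[i, lookup[s]] = 1.0
    return out


def predict(meta: MetaLearner, ensemble: MultitaskEnsemble, fps: np.ndarray,
            symbols: list[str], summary: bool = False):
    """Final predictions in native units for every polymer x property.

    Returns an (n_polymers, n_symbols) array; with ``summary=True`` also
    a per-property min/mean/max dict for screening runs.
    """
    n = fps.shape[0]
    out = np.zeros((n, len(symbols)))
    for j, s in enumerate(symbols):
        fp_ = ensemble.fold_predictions(fps, [s] * n)
        yt = meta.predict(fp_, [s] * n)
        out[:, j] = inverse_transform(s, yt)
    if summary:
        stats = {s: {"min": float(out[:, j].min()), "mean": float(out[:, j].mean()),
                     "max": float(out[:, j].max())} for j, s in enumerate(symbols)}
        return out, stats
    return out


@dataclass
class EvaluationReport:
    per_property: dict[str, dict[str, float]]
    per_category: dict[str, float]
    overall_r2: float
    cv_mean: float | None = None
    cv_std: float | None = None


def evaluate(predictions: np.ndarray, truth: np.ndarray, symbols: list[str],
             ensemble: MultitaskEnsemble | None = None) -> EvaluationReport:
    """Per-property R2 and RMSE (transformed scale for flagged
    properties), category and overall averages, and the CV mean +/- 1
    sigma when an ensemble is supplied."""
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.size == 0 or predictions.shape != truth.shape:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    per_property: dict[str, dict[str, float]] = {}
    for s in sorted(set(symbols)):
        sel = [i for i, t in enumerate(symbols) if t == s]
        yt = transform_target(s, truth[sel])
        yp = transform_target(s, np.maximum(predictions[sel], 0.0)
                              if REGISTRY[s].log_transform else predictions[sel])
        per_property[s] = {
            "r2": float(r2_score(yt, yp)),
            "rmse": float(np.sqrt(mean_squared_error(yt, yp))),
            "n": len(sel),
        }
    per_category: dict[str, list[float]] = {}
    for s, stats in per_property.items():
        per_category.setdefault(REGISTRY[s].category, []).append(stats["r2"])
    cat = {c: float(np.mean(v)) for c, v in per_category.items()}
    overall = float(np.mean([v["r2"] for v in per_property.values()]))
    cv_mean = cv_std = None
    if ensemble is not None and ensemble.fold_val_r2:
        cv_mean = float(np.mean(ensemble.fold_val_r2))
        cv_std = float(np.std(ensemble.fold_val_r2))
    return EvaluationReport(per_property, cat, overall, cv_mean, cv_std)
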