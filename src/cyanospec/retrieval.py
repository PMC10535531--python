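"""Neural-network retrieval of water-quality products from channel reflectances.

The retrieval maps instrument-channel reflectances to one product at a time
(chl_a, pc, or car) with a five-hidden-layer, 100-unit ReLU network trained
on mean absolute error.  Channel reflectances are log10-transformed (with a
small floor) and standardized on the training rows only; pigment targets are
log10-transformed while the cyanobacteria:algae ratio is fit untransformed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.model_selection import KFold, train_test_split

from ._mlp import MLPRegressor
from .instrument import BandConfig, apply_srf
from .metrics import MetricsReport, mape, r_squared, rmsele
from .synth import SpectralDataset

__all__ = [
    "PRODUCTS",
    "TransformRecord",
    "TrainConfig",
    "RetrievalModel",
    "make_features",
    "train_model",
    "predict",
    "evaluate",
    "EvalResult",
    "save_model",
    "load_model",
]

PRODUCTS = ("chl_a", "pc", "car")

#: Floor added to channel reflectances before the log10 transform.
REFLECTANCE_FLOOR = 1e-6

#: Floor applied to pigment targets before log10 (pc may be exactly zero).
TARGET_FLOOR = 1e-6


@dataclass
class TransformRecord:
    """Exact feature/target transforms needed to invert predictions."""

    input_log: bool
    input_means: np.ndarray
    input_scales: np.ndarray
    target_log: bool
    reflectance_floor: float = REFLECTANCE_FLOOR

    def __post_init__(self):
        if np.any(self.input_scales <= 0):
            raise ValueError("feature scales must be > 0")

    def transform_inputs(self, channels: np.ndarray) -> np.ndarray:
        x = np.asarray(channels, dtype=float)
        if self.input_log:
            x = np.log10(x + self.reflectance_floor)
        return (x - self.input_means) / self.input_scales

    def transform_target(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return np.log10(np.clip(y, TARGET_FLOOR, None)) if self.target_log else y

    def inverse_target(self, y_t: np.ndarray) -> np.ndarray:
        y_t = np.asarray(y_t, dtype=float)
        return 10.0 ** y_t if self.target_log else y_t


@dataclass
class TrainConfig:
    """Training hyperparameters (the published description omits these)."""

    batch_size: int = 256
    max_epochs: int = 200
    early_stop_patience: int = 10
    learning_rate: float = 1e-3
    inner_val_fraction: float = 0.1

    def __post_init__(self):
        for name in ("batch_size", "max_epochs", "early_stop_patience",
                     "learning_rate", "inner_val_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RetrievalModel:
    """A trained network plus everything needed to invert its predictions."""

    net: MLPRegressor
    transform: TransformRecord
    product: str
    train_seed: int
    config_name: str = ""

    @property
    def hidden_layer_sizes(self) -> tuple:
        return self.net.hidden_layer_sizes

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Network output in the (possibly log) training-target space."""
        return self.net.predict(X)


def make_features(dataset: SpectralDataset, product: str, config: BandConfig,
                  train_idx: Optional[np.ndarray] = None):
    """Resample spectra to channels and build (X, y, TransformRecord).

    X is log10(channel + floor), standardized per feature with mean/scale
    fit on `train_idx` rows only (all rows if None).  y is log10 of the
    label for the pigments and the raw label for car.
    """
    if product not in PRODUCTS:
        raise ValueError(f"unknown product {product!r}; valid: {PRODUCTS}")
    if not dataset.records:
        raise ValueError("dataset is empty")
    dtypes = {r.data_type for r in dataset.records}
    if len(dtypes) != 1:
        raise ValueError(f"dataset mixes data types {sorted(dtypes)}; filter first")
    channels = apply_srf(dataset.spectra(), config)
    logged = np.log10(channels + REFLECTANCE_FLOOR)
    fit_rows = logged if train_idx is None else logged[train_idx]
    means = fit_rows.mean(axis=0)
    scales = fit_rows.std(axis=0)
    scales[scales == 0] = 1.0
    transform = TransformRecord(input_log=True, input_means=means,
                                input_scales=scales,
                                target_log=product in ("chl_a", "pc"))
    X = (logged - means) / scales
    y_phys = np.array([getattr(r.labels, product) for r in dataset.records])
    return X, transform.transform_target(y_phys), transform


def train_model(X: np.ndarray, y: np.ndarray, train_cfg: TrainConfig, seed: int,
                transform: Optional[TransformRecord] = None,
                product: str = "", config_name: str = "") -> RetrievalModel:
    """Train the five-hidden-layer retrieval network (MAE loss, Adam)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 100:
        raise ValueError("need at least 100 training rows")
    net = MLPRegressor(
        hidden_layer_sizes=(100,) * 5,
        learning_rate=train_cfg.learning_rate,
        batch_size=train_cfg.batch_size,
        max_epochs=train_cfg.max_epochs,
        patience=train_cfg.early_stop_patience,
        validation_fraction=train_cfg.inner_val_fraction,
        seed=seed,
    )
    net.fit(X, y)
    if transform is None:
        transform = TransformRecord(input_log=False,
                                    input_means=np.zeros(X.shape[1]),
                                    input_scales=np.ones(X.shape[1]),
                                    target_log=False)
    return RetrievalModel(net=net, transform=transform, product=product,
                          train_seed=int(seed), config_name=config_name)


def predict(model: RetrievalModel, X: np.ndarray) -> np.ndarray:
    """Predictions in physical units (10^output for log-target products)."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.net.weights_[0].shape[0]:
        raise ValueError(
            f"feature count {X.shape[-1]} does not match the model's "
            f"{model.net.weights_[0].shape[0]} inputs")
    out = model.transform.inverse_target(model.net.predict(X))
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite predictions")
    return out


@dataclass
class EvalResult:
    """Outcome of one evaluation run (report plus reusable artifacts)."""

    report: MetricsReport
    model: RetrievalModel
    X_test: np.ndarray
    y_test: np.ndarray        # transformed (training-target) space
    y_test_phys: np.ndarray
    test_idx: np.ndarray


def _score(product, y_phys, pred_phys, y_t, pred_t):
    r2 = r_squared(y_t, pred_t)
    if product == "car":
        mask = y_phys > 0.01   # MAPE undefined at zero CAR
        mape_val = mape(y_phys[mask], pred_phys[mask])
    else:
        mape_val = mape(y_phys, pred_phys)
    return r2, mape_val, rmsele(y_phys, pred_phys)


def evaluate(dataset: SpectralDataset, product: str, config: BandConfig,
             train_cfg: Optional[TrainConfig] = None, seed: int = 0,
             cv_folds: int = 5, run_cv: bool = True) -> EvalResult:
    """Outer 80/20 holdout plus optional 5-fold CV over the training split.

    The final model is trained once on the full 80% (this is also the model
    used downstream for attribution); the headline metrics are computed on
    the untouched 20% only.  Fold metrics are reported as mean +/- sd.
    """
    train_cfg = train_cfg or TrainConfig()
    n = len(dataset.records)
    if n < 500:
        raise ValueError("evaluate requires >= 500 records")
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(idx, test_size=0.2, random_state=seed)
    if len(train_idx) < cv_folds:
        raise ValueError("fewer training records than CV folds")
    X, y_t, transform = make_features(dataset, product, config, train_idx=train_idx)
    y_phys = np.array([getattr(r.labels, product) for r in dataset.records])

    cv_means, cv_sds = {}, {}
    if run_cv:
        fold_scores = {"r2": [], "mape_percent": [], "rmsele": []}
        for k, (tr, te) in enumerate(
                KFold(cv_folds, shuffle=True, random_state=seed).split(train_idx)):
            tr_rows, te_rows = train_idx[tr], train_idx[te]
            m = train_model(X[tr_rows], y_t[tr_rows], train_cfg, seed=seed + 1 + k,
                            transform=transform, product=product)
            pred_t = m.predict(X[te_rows])
            r2, mp, rl = _score(product, y_phys[te_rows],
                                transform.inverse_target(pred_t),
                                y_t[te_rows], pred_t)
            for key, val in (("r2", r2), ("mape_percent", mp), ("rmsele", rl)):
                fold_scores[key].append(val)
        cv_means = {k: float(np.mean(v)) for k, v in fold_scores.items()}
        cv_sds = {k: float(np.std(v)) for k, v in fold_scores.items()}

    model = train_model(X[train_idx], y_t[train_idx], train_cfg, seed=seed,
                        transform=transform, product=product,
                        config_name=config.name)
    pred_t = model.predict(X[test_idx])
    r2, mp, rl = _score(product, y_phys[test_idx],
                        transform.inverse_target(pred_t),
                        y_t[test_idx], pred_t)
    report = MetricsReport(product=product, data_type=dataset.records[0].data_type,
                           config_name=config.name or f"{config.n_channels}ch",
                           n_test=len(test_idx), r2=r2, mape_percent=mp,
                           rmsele=rl, seed=int(seed),
                           cv_fold_means=cv_means, cv_fold_sds=cv_sds)
    return EvalResult(report=report, model=model, X_test=X[test_idx],
                      y_test=y_t[test_idx], y_test_phys=y_phys[test_idx],
                      test_idx=test_idx)


def save_model(model: RetrievalModel, path) -> None:
    """Weights to .npz plus a JSON sidecar with the transform record."""
    path = Path(path)
    arrays = {}
    for i, (W, b) in enumerate(zip(model.net.weights_, model.net.biases_)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(path, **arrays)
    sidecar = {
        "product": model.product,
        "train_seed": model.train_seed,
        "config_name": model.config_name,
        "hidden_layer_sizes": list(model.hidden_layer_sizes),
        "transform": {
            "input_log": model.transform.input_log,
            "input_means": model.transform.input_means.tolist(),
            "input_scales": model.transform.input_scales.tolist(),
            "target_log": model.transform.target_log,
            "reflectance_floor": model.transform.reflectance_floor,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_model(path) -> RetrievalModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    data = np.load(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    net = MLPRegressor(hidden_layer_sizes=tuple(sidecar["hidden_layer_sizes"]))
    n_layers = len(sidecar["hidden_layer_sizes"]) + 1
    net.weights_ = [data[f"W{i}"] for i in range(n_layers)]
    net.biases_ = [data[f"b{i}"] for i in range(n_layers)]
    t = sidecar["transform"]
    transform = TransformRecord(
        input_log=t["input_log"],
        input_means=np.asarray(t["input_means"]),
        input_scales=np.asarray(t["input_scales"]),
        target_log=t["target_log"],
        reflectance_floor=t["reflectance_floor"],
    )
    return RetrievalModel(net=net, transform=transform,
                          product=sidecar["product"],
                          train_seed=sidecar["train_seed"],
                          config_name=sidecar["config_name"])
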