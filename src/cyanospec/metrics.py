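"""Retrieval performance statistics: R^2, MAPE and RMSELE."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["r_squared", "mape", "rmsele", "MetricsReport", "append_metrics_csv"]

#: Additive floor applied before the log transform in RMSELE, so that
#: zero-containing quantities (the cyanobacteria:algae ratio) stay defined.
RMSELE_FLOOR = 1e-3


def _paired(obs, pred):
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("obs and pred must be equal-length arrays of >= 2 values")
    return obs, pred


def r_squared(obs, pred) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    obs, pred = _paired(obs, pred)
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observations have zero variance")
    return float(1.0 - np.sum((obs - pred) ** 2) / ss_tot)


def mape(obs, pred) -> float:
    """Mean absolute percentage error, in percent.

    Observations must be strictly positive; callers evaluate the
    cyanobacteria:algae ratio only on obs > 0.01.
    """
    obs, pred = _paired(obs, pred)
    if np.any(obs <= 0):
        raise ValueError("mape requires strictly positive observations")
    return float(100.0 * np.mean(np.abs(pred - obs) / obs))


def rmsele(obs, pred, floor: float = RMSELE_FLOOR) -> float:
    """Root-mean-square error of log10-transformed values (floored).

    Values below -floor (e.g. slightly negative regression estimates of a
    zero-bounded quantity) are clipped to the floor itself before the log.
    """
    obs, pred = _paired(obs, pred)
    diff = (np.log10(np.clip(pred + floor, floor, None))
            - np.log10(np.clip(obs + floor, floor, None)))
    return float(np.sqrt(np.mean(diff ** 2)))


@dataclass
class MetricsReport:
    """Held-out performance of one (product, data type, band config) run.

    r2 is computed on the model's native target scale (log10 for the
    pigments, raw for the cyanobacteria:algae ratio); mape_percent and
    rmsele on physical units.  cv_fold_means/sds summarize the inner
    5-fold cross-validation over the training split; the headline metrics
    come from the untouched outer test split of n_test records.
    """

    product: str
    data_type: str
    config_name: str
    n_test: int
    r2: float
    mape_percent: float
    rmsele: float
    seed: int
    cv_fold_means: dict = field(default_factory=dict)
    cv_fold_sds: dict = field(default_factory=dict)
    held_out_only: bool = True

    def __post_init__(self):
        if self.r2 > 1.0 + 1e-12:
            raise ValueError("r2 cannot exceed 1")
        if self.mape_percent < 0 or self.rmsele < 0:
            raise ValueError("error metrics must be >= 0")

    def rows(self):
        """Tidy rows (product, data_type, config, metric, value)."""
        base = dict(product=self.product, data_type=self.data_type,
                    config=self.config_name)
        return [dict(base, metric=m, value=v) for m, v in
                (("r2", self.r2), ("mape_percent", self.mape_percent),
                 ("rmsele", self.rmsele))]


def append_metrics_csv(reports, path) -> pd.DataFrame:
    """Append tidy metric rows to a CSV (created if absent)."""
    rows = [row for rep in reports for row in rep.rows()]
    frame = pd.DataFrame(rows)
    path = Path(path)
    if path.exists():
        frame = pd.concat([pd.read_csv(path), frame], ignore_index=True)
    frame.to_csv(path, index=False)
    return frame
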