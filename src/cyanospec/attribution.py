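"""Permutation feature importance over spectral channels.

For a trained retrieval model f and held-out (X, y), the baseline error is
e_orig = L(y, f(X)) with L = 1 - R^2.  Each channel column is then shuffled
(a within-column permutation, breaking its relationship with the target)
and the importance of channel j is FI_j = mean(e_perm) - e_orig over
n_repeats independent permutations.  Larger FI means the channel carries
more information for the retrieval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import r_squared

__all__ = ["AttributionProfile", "permutation_importance"]


@dataclass
class AttributionProfile:
    """Per-channel permutation importances for one (product, data type, model)."""

    channel_centers: np.ndarray
    fi: np.ndarray
    metric: str
    n_repeats: int
    e_orig: float
    seed: int
    product: str = ""
    data_type: str = ""

    def __post_init__(self):
        if len(self.channel_centers) != len(self.fi):
            raise ValueError("centers and fi must have equal length")

    def sorted_view(self):
        """(center, fi) pairs by descending importance; ties -> lower wavelength."""
        order = np.lexsort((self.channel_centers, -self.fi))
        return list(zip(self.channel_centers[order], self.fi[order]))

    def to_csv(self, path) -> None:
        path = Path(path)
        pd.DataFrame({"center_nm": self.channel_centers, "fi": self.fi}
                     ).to_csv(path, index=False)
        meta = {"metric": self.metric, "n_repeats": self.n_repeats,
                "e_orig": self.e_orig, "seed": self.seed,
                "product": self.product, "data_type": self.data_type}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path) -> "AttributionProfile":
        path = Path(path)
        frame = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(channel_centers=frame["center_nm"].to_numpy(dtype=float),
                   fi=frame["fi"].to_numpy(dtype=float), **meta)


def permutation_importance(model, X, y, channel_centers, n_repeats: int = 5,
                           seed: int = 0, product: str = "",
                           data_type: str = "") -> AttributionProfile:
    """Permutation importances of every column of X for the given model.

    `model` is anything with a predict(X) method operating in the same
    target space as y (the held-out test partition of a model trained on
    disjoint rows).  A column with identical values in every row has FI = 0
    exactly, since any permutation leaves it unchanged.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    centers = np.asarray(channel_centers, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one target per row")
    if X.shape[1] != len(centers):
        raise ValueError("one channel center per feature column is required")
    rng = np.random.default_rng(seed)
    e_orig = 1.0 - r_squared(y, model.predict(X))
    fi = np.zeros(X.shape[1])
    X_work = X.copy()
    for j in range(X.shape[1]):
        column = X[:, j].copy()
        e_perm = np.empty(n_repeats)
        for r in range(n_repeats):
            X_work[:, j] = column[rng.permutation(len(column))]
            e_perm[r] = 1.0 - r_squared(y, model.predict(X_work))
        X_work[:, j] = column
        fi[j] = e_perm.mean() - e_orig
    return AttributionProfile(channel_centers=centers, fi=fi,
                              metric="1-R2", n_repeats=int(n_repeats),
                              e_orig=float(e_orig), seed=int(seed),
                              product=product, data_type=data_type)
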