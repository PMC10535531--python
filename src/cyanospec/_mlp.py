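"""Minimal feed-forward network trained with Adam on mean absolute error.

scikit-learn's multilayer perceptron only offers a squared-error objective,
so the MAE-trained network used for pigment retrieval is implemented here
directly on numpy: ReLU hidden layers, Adam updates, mini-batches, early
stopping on an inner validation split with best-weight restoration, and
plateau-triggered learning-rate halving (the validation MAE of an
MAE-trained network is noisy near convergence; reducing the step on a
stall prevents spuriously early stops).  Fully deterministic for a fixed
seed and BLAS configuration.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLPRegressor"]


class MLPRegressor:
    """ReLU network with a single linear output, MAE loss and Adam.

    Parameters mirror the usual estimator conventions; `validation_fraction`
    rows are split off (seeded) for early stopping, and the weights from the
    best validation epoch are restored after training.
    """

    def __init__(self, hidden_layer_sizes=(100, 100, 100, 100, 100),
                 learning_rate: float = 1e-3, batch_size: int = 256,
                 max_epochs: int = 200, patience: int = 10,
                 validation_fraction: float = 0.1, seed: int = 0,
                 min_delta: float = 1e-5):
        self.hidden_layer_sizes = tuple(int(h) for h in hidden_layer_sizes)
        self.learning_rate = float(learning_rate)
        self.batch_size = int(batch_size)
        self.max_epochs = int(max_epochs)
        self.patience = int(patience)
        self.validation_fraction = float(validation_fraction)
        self.seed = int(seed)
        self.min_delta = float(min_delta)

    # -- internals ---------------------------------------------------------

    def _init_params(self, n_features: int, rng: np.random.Generator):
        sizes = (n_features, *self.hidden_layer_sizes, 1)
        self.weights_ = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]),
                                    size=(sizes[i], sizes[i + 1]))
                         for i in range(len(sizes) - 1)]
        self.biases_ = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def _forward(self, X):
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            h = h @ W + b
            if i < len(self.weights_) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return acts

    def _backward(self, acts, y):
        n = y.shape[0]
        grads_w, grads_b = [], []
        # MAE loss: d loss / d output = sign(pred - y) / n
        delta = np.sign(acts[-1][:, 0] - y)[:, None] / n
        for i in range(len(self.weights_) - 1, -1, -1):
            grads_w.append(acts[i].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.weights_[i].T) * (acts[i] > 0)
        return grads_w[::-1], grads_b[::-1]

    # -- public API --------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one target per row")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in training data")
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        n_val = max(1, int(round(self.validation_fraction * n)))
        order = rng.permutation(n)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        X_tr, y_tr, X_val, y_val = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

        self._init_params(X.shape[1], rng)
        m_w = [np.zeros_like(W) for W in self.weights_]
        v_w = [np.zeros_like(W) for W in self.weights_]
        m_b = [np.zeros_like(b) for b in self.biases_]
        v_b = [np.zeros_like(b) for b in self.biases_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_params = None
        stall = 0
        lr = self.learning_rate
        lr_patience = max(2, self.patience // 2)
        self.loss_curve_ = []
        for epoch in range(self.max_epochs):
            perm = rng.permutation(len(X_tr))
            for start in range(0, len(X_tr), self.batch_size):
                idx = perm[start:start + self.batch_size]
                acts = self._forward(X_tr[idx])
                gw, gb = self._backward(acts, y_tr[idx])
                step += 1
                corr1 = 1.0 - beta1 ** step
                corr2 = 1.0 - beta2 ** step
                for i in range(len(self.weights_)):
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * gw[i]
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * gw[i] ** 2
                    self.weights_[i] -= (lr * (m_w[i] / corr1)
                                         / (np.sqrt(v_w[i] / corr2) + eps))
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * gb[i]
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * gb[i] ** 2
                    self.biases_[i] -= (lr * (m_b[i] / corr1)
                                        / (np.sqrt(v_b[i] / corr2) + eps))
            val_mae = float(np.mean(np.abs(self.predict(X_val) - y_val)))
            self.loss_curve_.append(val_mae)
            if val_mae < best_val - self.min_delta:
                best_val = val_mae
                best_params = ([W.copy() for W in self.weights_],
                               [b.copy() for b in self.biases_])
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
                if stall % lr_patience == 0:
                    lr = max(lr * 0.5, 1e-5)
        if best_params is not None:
            self.weights_, self.biases_ = best_params
        self.best_validation_mae_ = float(best_val)
        self.n_epochs_ = len(self.loss_curve_)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self._forward(X)[-1][:, 0]
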