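"""Feed-forward neural network on dummy-coded code indicators.

Architecture: two fully-connected hidden layers with relu (default
widths 1,024 then 256), one dropout layer (rate 0.3) before a two-unit
softmax output, trained with Adam at learning rate 0.0002 on categorical
cross-entropy, with early stopping on validation loss. Inputs are the
binary code indicators (1 if the code is present in the record, 0
otherwise) plus z-scored age and sex, as a sparse matrix.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .base import HospitalAssignment, InputError, RiskModel, _check_probabilities
from .nn import Adam, Dropout, he_init, relu, softmax, softmax_xent

__all__ = ["FFNNModel", "fit_ffnn"]


class FFNNModel(RiskModel):
    model_kind = "FFNN"
    has_hospital_effect = False

    def __init__(self, params: dict[str, np.ndarray], history: list[float]):
        self.params = params
        self.history = history

    def predict(self, inputs, assignment=HospitalAssignment.ACTUAL) -> np.ndarray:
        """Probability of readmission (second softmax unit). The hospital
        assignment is ignored: this model has no hospital effect."""
        X = inputs
        P = self.params
        h1 = relu(X @ P["W1"] + P["b1"])
        h2 = relu(h1 @ P["W2"] + P["b2"])
        p = softmax(h2 @ P["W3"] + P["b3"])
        return _check_probabilities(p[:, 1])

    def predict_classes_proba(self, X) -> np.ndarray:
        """Both softmax units (rows sum to 1)."""
        P = self.params
        h1 = relu(X @ P["W1"] + P["b1"])
        h2 = relu(h1 @ P["W2"] + P["b2"])
        return softmax(h2 @ P["W3"] + P["b3"])


def fit_ffnn(X_train, y_train, X_val, y_val,
             hidden: tuple[int, int] = (1024, 256),
             dropout: float = 0.3,
             learning_rate: float = 0.0002,
             batch_size: int = 256,
             max_epochs: int = 50,
             patience: int = 5,
             seed: int = 0) -> FFNNModel:
    """Train the feed-forward network with early stopping.

    ``X_*`` may be dense or CSR; ``y_*`` are 0/1 labels. The best
    parameters (lowest validation loss) are restored at the end.
    """
    if X_train.shape[0] == 0 or X_train.shape[1] == 0:
        raise InputError("empty feature matrix")
    rng = np.random.default_rng(seed)
    d = X_train.shape[1]
    h1, h2 = hidden
    params = {
        "W1": he_init(rng, d, h1), "b1": np.zeros(h1),
        "W2": he_init(rng, h1, h2), "b2": np.zeros(h2),
        "W3": he_init(rng, h2, 2), "b3": np.zeros(2),
    }
    opt = Adam(params, learning_rate)
    drop = Dropout(dropout, rng)
    y_train = np.asarray(y_train).astype(np.int64)
    y_val = np.asarray(y_val).astype(np.int64)
    n = X_train.shape[0]
    is_sp = sparse.issparse(X_train)

    def val_loss() -> float:
        logits = (relu(relu(X_val @ params["W1"] + params["b1"])
                       @ params["W2"] + params["b2"])
                  @ params["W3"] + params["b3"])
        loss, _ = softmax_xent(logits, y_val)
        return loss

    best = {k: v.copy() for k, v in params.items()}
    best_loss = val_loss()
    history = [best_loss]
    bad = 0
    for _ in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            Xb = X_train[idx]
            yb = y_train[idx]
            a1 = Xb @ params["W1"] + params["b1"]
            z1 = relu(a1)
            a2 = z1 @ params["W2"] + params["b2"]
            z2 = relu(a2)
            z2d = drop.forward(z2, train=True)
            logits = z2d @ params["W3"] + params["b3"]
            _, gl = softmax_xent(logits, yb)
            gW3 = z2d.T @ gl
            gb3 = gl.sum(axis=0)
            gz2 = drop.backward(gl @ params["W3"].T) * (a2 > 0)
            gW2 = z1.T @ gz2
            gb2 = gz2.sum(axis=0)
            gz1 = (gz2 @ params["W2"].T) * (a1 > 0)
            gW1 = (Xb.T @ gz1) if is_sp else Xb.T @ gz1
            gb1 = gz1.sum(axis=0)
            opt.step({"W1": np.asarray(gW1), "b1": gb1,
                      "W2": gW2, "b2": gb2, "W3": gW3, "b3": gb3})
        vl = val_loss()
        history.append(vl)
        if not np.isfinite(vl):
            raise RuntimeError("FFNN training diverged (non-finite loss)")
        if vl < best_loss - 1e-6:
            best_loss = vl
            best = {k: v.copy() for k, v in params.items()}
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                break
    return FFNNModel(best, history)
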