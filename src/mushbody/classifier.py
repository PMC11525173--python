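"""Virtual-fly resampling and the multiclass hinge-loss odour decoder.

Because each real fly contributes recordings of only one cell type,
population response vectors are assembled for *virtual flies*: for each
cell type one real fly is drawn at random and its odour-evoked responses
are concatenated, giving up to ``12^5`` distinct DAN populations.  A
linear classifier ``f(x', W) = W x'`` (bias folded into the last column)
is trained with a margin-1 multiclass hinge loss, L2 penalty
``lambda = 1e-4``, Adam updates at learning rate ``5e-4``, minibatches of
200 responses drawn without replacement, for ten epochs.  Controls
shuffle the response-to-odour assignment within each virtual fly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VirtualFlyDataset", "ClassifierModel", "response_array",
    "build_virtual_flies", "shuffle_control", "hinge_loss", "train",
    "predict", "evaluate", "EvaluationReport",
]


def response_array(table: pd.DataFrame, cell_class: str = "DAN"):
    """Pivot a tidy response table into (cell_types, responses[ct, fly, odour])."""
    sub = table[table["cell_class"] == cell_class]
    cts = sorted(sub["cell_type"].unique())
    flies = sorted(sub["fly"].unique())
    odours = sorted(sub["odour"].unique())
    arr = np.empty((len(cts), len(flies), len(odours)))
    piv = sub.pivot_table(index=["cell_type", "fly"], columns="odour",
                          values="delta_rate_hz")
    for i, ct in enumerate(cts):
        for j, fly in enumerate(flies):
            arr[i, j] = piv.loc[(ct, fly)].to_numpy()
    if np.any(~np.isfinite(arr)):
        raise ValueError("response table is incomplete")
    return cts, arr


@dataclass
class VirtualFlyDataset:
    """Responses ``x[fly, odour, cell]`` with per-fly train/val/test splits."""

    x: np.ndarray                   # (n_flies, n_odours, n_cells)
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    cell_types: tuple = ()

    @property
    def n_odours(self) -> int:
        return self.x.shape[1]

    def samples(self, idx) -> tuple[np.ndarray, np.ndarray]:
        """Flatten flies x odours into (X with bias column, labels)."""
        x = self.x[idx]                       # (n, odours, cells)
        n, k, c = x.shape
        X = x.reshape(n * k, c)
        X = np.hstack([X, np.ones((X.shape[0], 1))])
        y = np.tile(np.arange(k), n)
        return X, y


def build_virtual_flies(table: pd.DataFrame, n: int = 12 ** 5,
                        cell_class: str = "DAN", seed: int = 0,
                        splits=(0.90, 0.05, 0.05)) -> VirtualFlyDataset:
    """Assemble ``n`` virtual flies by drawing one real fly per cell type.

    Each virtual fly contributes one response vector per odour.  Flies are
    split (by virtual fly, not by sample) into train/validation/test
    fractions, 90/5/5 by default.
    """
    cts, arr = response_array(table, cell_class)
    n_ct, n_flies, n_od = arr.shape
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, n_flies, size=(n, n_ct))
    # x[v, o, c] = response of cell type c (from picked fly) to odour o
    x = arr[np.arange(n_ct)[None, :], picks, :]      # (n, n_ct, n_od)
    x = np.swapaxes(x, 1, 2)                          # (n, n_od, n_ct)
    order = rng.permutation(n)
    n_train = int(round(splits[0] * n))
    n_val = int(round(splits[1] * n))
    return VirtualFlyDataset(x=x, train_idx=order[:n_train],
                             val_idx=order[n_train:n_train + n_val],
                             test_idx=order[n_train + n_val:],
                             cell_types=tuple(cts))


def shuffle_control(dataset: VirtualFlyDataset, seed: int = 0
                    ) -> VirtualFlyDataset:
    """Permute each virtual fly's response vectors across the odour labels.

    Destroys the response-odour association while preserving every
    per-cell marginal distribution.
    """
    rng = np.random.default_rng(seed)
    x = dataset.x.copy()
    for i in range(x.shape[0]):
        x[i] = x[i, rng.permutation(x.shape[1])]
    return VirtualFlyDataset(x=x, train_idx=dataset.train_idx,
                             val_idx=dataset.val_idx,
                             test_idx=dataset.test_idx,
                             cell_types=dataset.cell_types)


@dataclass
class ClassifierModel:
    """Linear decoder W of shape (n_odours, n_cells + 1)."""

    W: np.ndarray
    loss_history: tuple = ()
    meta: dict = field(default_factory=dict)


def hinge_loss(W: np.ndarray, X: np.ndarray, y: np.ndarray,
               l2: float = 1e-4) -> float:
    """Mean margin-1 multiclass hinge loss plus the L2 penalty."""
    scores = X @ W.T
    true = scores[np.arange(y.size), y]
    margins = np.maximum(0.0, scores - true[:, None] + 1.0)
    margins[np.arange(y.size), y] = 0.0
    return float(margins.sum(axis=1).mean() + l2 * np.sum(W ** 2))


def _hinge_grad(W, X, y, l2):
    n = y.size
    scores = X @ W.T
    true = scores[np.arange(n), y]
    viol = (scores - true[:, None] + 1.0 > 0).astype(float)
    viol[np.arange(n), y] = 0.0
    viol[np.arange(n), y] = -viol.sum(axis=1)
    return (viol.T @ X) / n + 2 * l2 * W


def train(dataset: VirtualFlyDataset, l2: float = 1e-4, lr: float = 5e-4,
          batch_size: int = 200, epochs: int = 10, seed: int = 0
          ) -> ClassifierModel:
    """Train the linear decoder with Adam on minibatched hinge loss.

    Adam uses its standard moment parameters (beta1 = 0.9, beta2 = 0.999,
    eps = 1e-8); batches are drawn without replacement within each of the
    ten passes over the training responses.  Deterministic given ``seed``.
    """
    X, y = dataset.samples(dataset.train_idx)
    if X.shape[0] == 0:
        raise ValueError("training split is empty")
    k = dataset.n_odours
    rng = np.random.default_rng(seed)
    W = np.zeros((k, X.shape[1]))
    m = np.zeros_like(W)
    v = np.zeros_like(W)
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = []
    for _ in range(epochs):
        order = rng.permutation(X.shape[0])
        for s in range(0, order.size, batch_size):
            idx = order[s:s + batch_size]
            g = _hinge_grad(W, X[idx], y[idx], l2)
            t += 1
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g ** 2
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            W = W - lr * mhat / (np.sqrt(vhat) + eps)
        history.append(hinge_loss(W, X, y, l2))
    return ClassifierModel(W=W, loss_history=tuple(history),
                           meta={"l2": l2, "lr": lr, "epochs": epochs,
                                 "batch_size": batch_size, "seed": seed})


def predict(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """argmax_j f(x', W)_j; ties broken towards the lowest odour index."""
    return np.argmax(X @ model.W.T, axis=1)


@dataclass
class EvaluationReport:
    accuracies: np.ndarray          # one accuracy per sub-testing set
    subset_size: int
    n_odours: int
    reused_flies: bool              # True if subsets had to overlap

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())


def evaluate(model: ClassifierModel, dataset: VirtualFlyDataset,
             n_subsets: int = 120, subset_size: int = 200,
             seed: int = 0) -> EvaluationReport:
    """Accuracy distribution over sub-testing sets of virtual flies.

    The test split is divided into ``n_subsets`` groups of ``subset_size``
    flies; per subset the accuracy is correct / (subset_size * n_odours)
    (1,000 at the defaults).  If the split is too small for disjoint
    subsets, flies are drawn without replacement until exhausted and then
    re-drawn with replacement, and the report flags the reuse.
    """
    test = dataset.test_idx
    if test.size == 0:
        raise ValueError("test split is empty")
    rng = np.random.default_rng(seed)
    need = n_subsets * subset_size
    pool = rng.permutation(test)
    reused = need > pool.size
    if reused:
        extra = rng.choice(test, size=need - pool.size, replace=True)
        pool = np.concatenate([pool, extra])
    accs = []
    for i in range(n_subsets):
        idx = pool[i * subset_size:(i + 1) * subset_size]
        X, y = dataset.samples(idx)
        accs.append(float(np.mean(predict(model, X) == y)))
    return EvaluationReport(accuracies=np.array(accs),
                            subset_size=subset_size,
                            n_odours=dataset.n_odours, reused_flies=reused)
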