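"""Six-class tissue-pattern classifier.

A small fully connected network maps the 28-long radiomic feature vector to
six per-class sigmoid scores: input -> dense(128) -> ReLU -> dense(128) ->
dense(6) -> sigmoid. Class imbalance is handled in the loss, a weighted
cross-entropy whose per-class weights are inverse class frequencies
normalized to sum one, so rare patterns (typically pulmonary embolism)
contribute as much gradient as abundant ones.

The network is implemented in numpy as a scikit-learn compatible estimator
(`TissuePatternNet`): it supports ``fit`` / ``predict`` / ``predict_proba``,
``get_params`` / ``set_params``, clones cleanly, and exposes fitted state
through trailing-underscore attributes, so it composes with sklearn model
selection. Note that ``predict_proba`` returns the raw per-class sigmoid
scores, which deliberately need not sum to one.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .preprocess import NormalizationMode
from .volume_io import TissueClass

logger = logging.getLogger(__name__)

__all__ = [
    "ClassWeights",
    "compute_class_weights",
    "weighted_cross_entropy",
    "TissuePatternNet",
    "ModelConfig",
    "DEFAULT_CONFIGS",
    "train_classifier",
    "predict",
    "PredictionResult",
]

_SCORE_EPS = 1e-12


@dataclass
class ClassWeights:
    """Normalized per-class loss weights with their provenance counts."""

    classes: np.ndarray  # class codes, sorted
    w: np.ndarray
    rho: np.ndarray
    n_samp: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        if abs(self.w.sum() - 1.0) > 1e-12:
            raise ValueError("class weights must sum to 1")
        if np.any(self.w <= 0):
            raise ValueError("class weights must be positive")

    def weight_of(self, cls: int) -> float:
        idx = np.searchsorted(self.classes, cls)
        if idx >= len(self.classes) or self.classes[idx] != cls:
            raise KeyError(f"class {cls} not in weights")
        return float(self.w[idx])


def compute_class_weights(
    counts: dict[int, int] | np.ndarray, inverse: bool = True
) -> ClassWeights:
    """Per-class loss weights from sample counts.

    Default (``inverse=True``): w_i proportional to the inverse class
    frequency 1/rho_i, normalized to sum one — the imbalance correction.
    ``inverse=False`` gives direct-frequency weights w_i = rho_i (which sum
    to one already); kept selectable because the two conventions coexist in
    the literature.
    """
    if isinstance(counts, dict):
        classes = np.array(sorted(counts), dtype=int)
        n = np.array([counts[c] for c in classes], dtype=float)
    else:
        n = np.asarray(counts, dtype=float)
        classes = np.arange(1, len(n) + 1)
    zero = classes[n <= 0]
    if len(zero):
        raise ValueError(f"zero sample count for class(es) {zero.tolist()}")
    n_total = int(n.sum())
    rho = n / n_total
    raw = 1.0 / rho if inverse else rho
    w = raw / raw.sum()
    return ClassWeights(classes=classes, w=w, rho=rho, n_samp=n.astype(int), n_total=n_total)


def weighted_cross_entropy(
    scores: np.ndarray,
    targets: np.ndarray,
    weights: ClassWeights,
    normalize: bool = False,
) -> float:
    """Class-weighted cross-entropy of a batch.

    ``scores`` is (n, k) with entries in (0, 1); ``targets`` is either a
    one-hot (n, k) array or an integer vector of class codes matching
    ``weights.classes``. Loss_i is the mean natural-log cross-entropy
    ``-ln s_true`` over the samples of true class i; the total is
    ``sum_i w_i Loss_i``, with absent classes contributing zero.

    With ``normalize=True`` scores are first scaled to sum one per sample
    (the form used as the training objective, where unnormalized per-class
    sigmoids would give no gradient to non-target classes).
    """
    scores = np.asarray(scores, dtype=float)
    if targets_is_onehot := (np.ndim(targets) == 2):
        target_idx = np.argmax(targets, axis=1)
    else:
        codes = np.asarray(targets)
        target_idx = np.searchsorted(weights.classes, codes)
        if np.any(weights.classes[target_idx] != codes):
            raise ValueError("target class code not covered by weights")
    if normalize:
        scores = scores / scores.sum(axis=1, keepdims=True)
    s_true = scores[np.arange(len(scores)), target_idx]
    if np.any(s_true <= 0) or np.any(s_true >= 1 + 1e-9):
        logger.debug("clamping scores at the true class into (eps, 1)")
    s_true = np.clip(s_true, _SCORE_EPS, 1.0)
    ce = -np.log(s_true)
    total = 0.0
    for k, w in enumerate(weights.w):
        in_class = target_idx == k
        if in_class.any():
            total += w * float(ce[in_class].mean())
    return total


@dataclass
class PredictionResult:
    """Per-sample scores and the hard label (argmax, ties to lowest code)."""

    scores: np.ndarray  # aligned with the model's classes_
    label: TissueClass


class TissuePatternNet(BaseEstimator, ClassifierMixin):
    """Fully connected six-class network with weighted cross-entropy loss.

    Parameters
    ----------
    hidden_units : width of the two fully connected hidden layers.
    learning_rate, batch_size, max_epochs : Adam optimizer settings.
    patience : early-stopping patience (epochs without improvement of the
        validation loss on a ``val_fraction`` stratified hold-out split).
    inverse_frequency_weights : use inverse-frequency class weights (the
        imbalance correction); ``False`` selects direct-frequency weights.
    random_state : seed controlling initialization, shuffling and the
        validation split; fits are bit-reproducible for a fixed seed.

    Attributes (after ``fit``)
    --------------------------
    classes_ : sorted class codes seen in training.
    coefs_, intercepts_ : learned layer weights/biases.
    feature_mean_, feature_scale_ : frozen z-scoring statistics.
    class_weights_ : the `ClassWeights` used by the loss.
    loss_curve_ : training loss per epoch.
    """

    def __init__(
        self,
        hidden_units: int = 128,
        learning_rate: float = 1e-3,
        batch_size: int = 256,
        max_epochs: int = 200,
        patience: int = 20,
        val_fraction: float = 0.1,
        inverse_frequency_weights: bool = True,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.inverse_frequency_weights = inverse_frequency_weights
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        w1, w2, w3 = self.coefs_
        b1, b2, b3 = self.intercepts_
        h1 = x @ w1 + b1
        a1 = np.maximum(h1, 0.0)
        h2 = a1 @ w2 + b2  # second dense layer, linear
        z = h2 @ w3 + b3
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))
        return s, (x, h1, a1, h2, z)

    def _batch_loss_grad(self, x, target_idx, sample_w):
        """Loss and parameter gradients for one batch (normalized-score CE)."""
        s, (x0, h1, a1, h2, z) = self._forward(x)
        n = len(x)
        # keep scores strictly inside (0, 1) so 1/sum and 1/s_true stay finite
        s = np.clip(s, _SCORE_EPS, 1.0 - _SCORE_EPS)
        ssum = s.sum(axis=1, keepdims=True)
        p_true = s[np.arange(n), target_idx] / ssum[:, 0]
        p_true = np.clip(p_true, _SCORE_EPS, 1.0)
        loss = float(np.sum(sample_w * -np.log(p_true)))
        # dL/ds = w * (1/sum(s) - delta/s_true)
        grad_s = np.repeat(1.0 / ssum, s.shape[1], axis=1)
        s_t = np.clip(s[np.arange(n), target_idx], _SCORE_EPS, None)
        grad_s[np.arange(n), target_idx] -= 1.0 / s_t
        grad_s *= sample_w[:, None]
        grad_z = grad_s * s * (1.0 - s)
        w1, w2, w3 = self.coefs_
        g_w3 = h2.T @ grad_z
        g_b3 = grad_z.sum(axis=0)
        grad_h2 = grad_z @ w3.T
        g_w2 = a1.T @ grad_h2
        g_b2 = grad_h2.sum(axis=0)
        grad_a1 = grad_h2 @ w2.T
        grad_h1 = grad_a1 * (h1 > 0)
        g_w1 = x0.T @ grad_h1
        g_b1 = grad_h1.sum(axis=0)
        return loss, [g_w1, g_w2, g_w3], [g_b1, g_b2, g_b3]

    def _epoch_loss(self, x, target_idx, class_w_vec):
        """Weighted CE over a full split (per-class means, spec form)."""
        s, _ = self._forward(x)
        ssum = s.sum(axis=1)
        p_true = np.clip(s[np.arange(len(x)), target_idx] / ssum, _SCORE_EPS, 1.0)
        ce = -np.log(p_true)
        total = 0.0
        for k, w in enumerate(class_w_vec):
            in_k = target_idx == k
            if in_k.any():
                total += w * float(ce[in_k].mean())
        return total

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        if not np.all(np.isfinite(X)):
            bad = np.nonzero(~np.isfinite(X).all(axis=1))[0]
            raise ValueError(f"non-finite features in rows {bad.tolist()[:20]}")
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("training table contains a single class")
        self.classes_ = classes.astype(int)
        counts = {int(c): int((y_idx == k).sum()) for k, c in enumerate(classes)}
        self.class_weights_ = compute_class_weights(
            counts, inverse=self.inverse_frequency_weights
        )
        self.n_features_in_ = X.shape[1]

        self.feature_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.feature_scale_ = scale
        Xz = (X - self.feature_mean_) / self.feature_scale_

        rng = np.random.default_rng(self.random_state)
        k_out = len(classes)
        d = X.shape[1]
        h = self.hidden_units

        def glorot(fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        self.coefs_ = [glorot(d, h), glorot(h, h), glorot(h, k_out)]
        self.intercepts_ = [np.zeros(h), np.zeros(h), np.zeros(k_out)]

        # stratified validation split for early stopping
        val_idx: list[int] = []
        if self.val_fraction > 0:
            for k in range(k_out):
                members = np.nonzero(y_idx == k)[0]
                n_val = int(round(self.val_fraction * len(members)))
                if n_val >= 1 and n_val < len(members):
                    val_idx.extend(rng.choice(members, size=n_val, replace=False))
        val_idx = np.array(sorted(val_idx), dtype=int)
        train_mask = np.ones(len(Xz), dtype=bool)
        train_mask[val_idx] = False
        Xtr, ytr = Xz[train_mask], y_idx[train_mask]
        Xval, yval = Xz[val_idx], y_idx[val_idx]
        monitor_val = len(val_idx) > 0

        w_vec = self.class_weights_.w
        # per-sample weights: w_class / n_class(train), scaled so one pass over
        # the data computes the spec's per-class-mean weighted loss
        cls_n = np.array([(ytr == k).sum() for k in range(k_out)], dtype=float)
        cls_n[cls_n == 0] = 1.0
        samp_w_full = w_vec[ytr] / cls_n[ytr]

        m = [np.zeros_like(p) for p in self.coefs_ + self.intercepts_]
        v = [np.zeros_like(p) for p in self.coefs_ + self.intercepts_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t_step = 0

        best_loss = np.inf
        best_params = None
        best_epoch = 0
        self.loss_curve_ = []
        n_tr = len(Xtr)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n_tr)
            epoch_loss = 0.0
            for start in range(0, n_tr, self.batch_size):
                sel = order[start : start + self.batch_size]
                loss, g_w, g_b = self._batch_loss_grad(
                    Xtr[sel], ytr[sel], samp_w_full[sel]
                )
                epoch_loss += loss
                t_step += 1
                params = self.coefs_ + self.intercepts_
                grads = g_w + g_b
                for i, (p, g) in enumerate(zip(params, grads)):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mhat = m[i] / (1 - beta1**t_step)
                    vhat = v[i] / (1 - beta2**t_step)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            self.loss_curve_.append(epoch_loss)

            monitor = (
                self._epoch_loss(Xval, yval, w_vec) if monitor_val else epoch_loss
            )
            if monitor < best_loss - 1e-9:
                best_loss = monitor
                best_params = (
                    [p.copy() for p in self.coefs_],
                    [p.copy() for p in self.intercepts_],
                )
                best_epoch = epoch
            elif epoch - best_epoch >= self.patience:
                break
        if best_params is not None:
            self.coefs_, self.intercepts_ = best_params
        self.n_epochs_ = len(self.loss_curve_)
        return self

    def predict_proba(self, X):
        """Per-class sigmoid scores in [0, 1] (need not sum to 1)."""
        check_is_fitted(self, "coefs_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        Xz = (X - self.feature_mean_) / self.feature_scale_
        s, _ = self._forward(Xz)
        return s

    def predict(self, X):
        """Hard labels: argmax score, ties broken by the lowest class code."""
        s = self.predict_proba(X)
        return self.classes_[np.argmax(s, axis=1)]

    def predict_results(self, X) -> list[PredictionResult]:
        s = self.predict_proba(X)
        labels = self.classes_[np.argmax(s, axis=1)]
        return [
            PredictionResult(scores=s[i], label=TissueClass(int(labels[i])))
            for i in range(len(s))
        ]

    def save(self, path: str | Path) -> None:
        """Serialize the fitted model (weights + scaling + config + seed)."""
        check_is_fitted(self, "coefs_")
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TissuePatternNet":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TissuePatternNet):
            raise TypeError(f"{path} does not hold a TissuePatternNet")
        return model


@dataclass
class ModelConfig:
    """One of the four experiment configurations (window size x normalization)."""

    window_side: int
    normalization: NormalizationMode
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_side not in (3, 5):
            raise ValueError(f"window_side must be 3 or 5, got {self.window_side}")
        self.normalization = NormalizationMode(self.normalization)

    @property
    def label(self) -> str:
        norm = "Mx" if self.normalization is NormalizationMode.MAX else "Prct"
        return f"Model{norm}{self.window_side}"

    def make_estimator(self, seed: int | None = None) -> TissuePatternNet:
        return TissuePatternNet(
            random_state=self.seed if seed is None else seed, **self.hyperparameters
        )


#: the four standard configurations
DEFAULT_CONFIGS = (
    ModelConfig(3, NormalizationMode.MAX),
    ModelConfig(3, NormalizationMode.PERCENTILE99),
    ModelConfig(5, NormalizationMode.MAX),
    ModelConfig(5, NormalizationMode.PERCENTILE99),
)


def train_classifier(train_table, config: ModelConfig) -> TissuePatternNet:
    """Fit a `TissuePatternNet` on a sample table (thin wrapper)."""
    from .volume_io import feature_columns

    cols = feature_columns(train_table)
    X = train_table[cols].to_numpy(dtype=float)
    y = train_table["label"].to_numpy(dtype=int)
    model = config.make_estimator()
    return model.fit(X, y)


def predict(model: TissuePatternNet, features: np.ndarray) -> list[PredictionResult]:
    """Batch prediction (thin wrapper over ``predict_results``)."""
    return model.predict_results(features)
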