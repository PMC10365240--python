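"""scikit-learn estimator wrapping the connectome-convolution network.

:class:`SMFCNetClassifier` consumes stacks of sparsified connectivity
matrices — an array of shape ``(n_subjects, d, N, N)`` as produced by
:class:`~smfcnet.fcn.GuidedFCNTransform` or
:class:`~smfcnet.fcn.HardThresholdTransform` — and predicts a binary
diagnostic label. With ``d = 1`` (a single connectivity matrix per subject)
the same architecture is the single-sparsity variant.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._network import FCConvNetwork

__all__ = ["ModelConfig", "SMFCNetClassifier"]


@dataclass
class ModelConfig:
    """Published training configuration of the classifier.

    H and V are the channel counts of the regional-connectivity and
    spatial-integration convolutions; D1/D2 the dense-layer widths. The L2
    penalty applies to the convolution kernels only.
    """

    H: int = 64
    V: int = 32
    D1: int = 128
    D2: int = 64
    dropout: float = 0.2
    l2_coeff: float = 1e-5
    lr: float = 1e-3
    batch_size: int = 20
    epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        for name in ("H", "V", "D1", "D2", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.lr <= 0 or self.l2_coeff < 0:
            raise ValueError("lr must be positive and l2_coeff nonnegative")


class SMFCNetClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier over stacks of sparsified connectivity matrices.

    Parameters mirror :class:`ModelConfig`. ``fit`` expects
    ``X`` of shape ``(n_subjects, d, N, N)`` (a 3-D ``(n, N, N)`` input is
    promoted to ``d = 1``) and binary ``y``; training runs a fixed number of
    epochs of mini-batch Adam with no early stopping. All randomness
    (weight init, shuffling, dropout) derives from ``seed``, so a fixed
    seed and fixed data reproduce training bit-for-bit.

    Attributes
    ----------
    network_ : FCConvNetwork
        The trained network.
    history_ : list of float
        Mean training loss per epoch (length ``epochs``).
    classes_ : ndarray
        The two class labels, sorted.
    """

    def __init__(self, H: int = 64, V: int = 32, D1: int = 128, D2: int = 64,
                 dropout: float = 0.2, l2_coeff: float = 1e-5, lr: float = 1e-3,
                 batch_size: int = 20, epochs: int = 200, seed: int = 0):
        self.H = H
        self.V = V
        self.D1 = D1
        self.D2 = D2
        self.dropout = dropout
        self.l2_coeff = l2_coeff
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    # -- helpers ------------------------------------------------------------

    def _config(self) -> ModelConfig:
        return ModelConfig(**{k: getattr(self, k) for k in ModelConfig.__dataclass_fields__})

    @staticmethod
    def _validate_stacks(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[:, None, :, :]
        if X.ndim != 4 or X.shape[2] != X.shape[3]:
            raise ValueError(
                f"expected stacks of shape (n, d, N, N), got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("stacks contain non-finite values")
        return X

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        cfg = self._config()
        X = self._validate_stacks(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y disagree on the number of subjects")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"need exactly 2 classes in the training set, got {self.classes_.size}")
        counts = [(y == c).sum() for c in self.classes_]
        if min(counts) < 2:
            raise ValueError("need at least 2 subjects per class")
        y_idx = np.searchsorted(self.classes_, y)
        _, d, N, _ = X.shape
        self.n_branches_ = d
        self.n_rois_ = N
        self.network_ = FCConvNetwork(
            n_rois=N, n_branches=d, H=cfg.H, V=cfg.V, D1=cfg.D1, D2=cfg.D2,
            dropout=cfg.dropout, l2_coeff=cfg.l2_coeff, lr=cfg.lr, seed=cfg.seed)
        self.history_ = self.network_.fit(
            X, y_idx, epochs=cfg.epochs, batch_size=cfg.batch_size)
        self.config_ = asdict(cfg)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._validate_stacks(X)
        if X.shape[1] != self.n_branches_ or X.shape[2] != self.n_rois_:
            raise ValueError(
                f"stack shape {X.shape[1:]} does not match fitted "
                f"(d={self.n_branches_}, N={self.n_rois_})")
        return self.network_.forward(X, train=False)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
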