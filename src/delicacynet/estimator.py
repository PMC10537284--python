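"""Scikit-learn style estimator facade over the training engine.

``DelicacyNetRegressor`` follows the sklearn estimator contract
(``fit``/``predict``/``get_params``/``set_params``, fitted attributes with a
trailing underscore), so it composes with sklearn model selection utilities.
``X`` is an array of images — (n, H, W, 3), or flattened (n, H*W*3) rows as
produced by sklearn pipelines, reshaped back using ``image_shape`` — and
``y`` holds the nutrient fraction rows (n, 7).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .model import DelicacyNet, ModelConfig
from .train import RunRecord, evaluate, train

__all__ = ["DelicacyNetRegressor"]


class DelicacyNetRegressor(RegressorMixin, BaseEstimator):
    """Nutrient-fraction regressor on food images.

    Parameters
    ----------
    config : ModelConfig or None
        Architecture; ``None`` uses the CPU-scale default ``ModelConfig.small()``.
    epochs, batch_size, lr, val_frac : training-loop settings.
    seed : master seed for data order, dropout and token sleeping.
    image_shape : (H, W, 3) used to un-flatten 2-D ``X``; ``None`` requires
        4-D input.
    """

    def __init__(self, config: ModelConfig | None = None, epochs: int = 30,
                 batch_size: int = 32, lr: float = 1e-3, val_frac: float = 0.2,
                 seed: int = 0, image_shape: tuple[int, int, int] | None = None):
        self.config = config
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.val_frac = val_frac
        self.seed = seed
        self.image_shape = image_shape

    def _images(self, X) -> list[np.ndarray]:
        X = np.asarray(X)
        if X.ndim == 4:
            return list(X)
        if X.ndim == 2:
            if self.image_shape is None:
                raise ValueError("flattened X requires image_shape")
            return [row.reshape(self.image_shape) for row in X]
        raise ValueError(f"X must be (n,H,W,3) or flattened (n,d), got ndim={X.ndim}")

    def fit(self, X, y) -> "DelicacyNetRegressor":
        images = self._images(X)
        y = np.asarray(y, dtype=np.float64)
        if y.ndim != 2 or len(images) != y.shape[0]:
            raise ValueError("y must be (n_samples, n_classes) aligned with X")
        cfg = self.config if self.config is not None else ModelConfig.small(seed=self.seed)
        model, record = train(
            list(zip(images, y)), cfg, epochs=self.epochs, seed=self.seed,
            batch_size=self.batch_size, lr=self.lr, val_frac=self.val_frac,
        )
        self.model_: DelicacyNet = model
        self.run_record_: RunRecord = record
        self.n_features_in_ = int(np.prod(np.asarray(X).shape[1:]))
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")
        return self.model_.predict(self._images(X))

    def score_report(self, X, y) -> dict:
        """Domain metrics (Top-1/Top-5 regression accuracy, WMAE)."""
        images = self._images(X)
        y = np.asarray(y, dtype=np.float64)
        return evaluate(list(zip(images, y)), self.model_)
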