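"""scikit-learn style classifier wrapping the model family and the harness.

``CanopyClassifier`` composes with sklearn pipelines and model selection:
``fit(X, y)`` accepts uint8/float image stacks in channel-last (n, H, W, 3)
or channel-first (n, 3, H, W) layout, ``predict_proba`` returns softmax
scores.  Defaults are the CPU desk-scale profile (32 px inputs, short
schedule); the published profile is a ``set_params`` away
(``input_size=224, epochs=120, batch_size=112``).
"""

from __future__ import annotations

import numpy as np
from PIL import Image
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .architectures import build_model
from .harness import TrainConfig, predict_scores, train

# channel-wise standardisation constants for [0, 1] images
_NORM_MEAN = 0.45
_NORM_STD = 0.25


def images_to_tensor(X, input_size: int) -> np.ndarray:
    """uint8/float image stack -> standardised float32 (n, 3, S, S) tensor."""
    X = np.asarray(X)
    if X.ndim != 4:
        raise ValueError(f"expected a 4-D image stack, got shape {X.shape}")
    if X.shape[1] == 3 and X.shape[-1] != 3:
        X = np.moveaxis(X, 1, -1)
    if X.shape[-1] != 3:
        raise ValueError("images must have 3 colour channels")
    if X.dtype != np.uint8:
        X = (np.clip(X, 0.0, 1.0) * 255.0).astype(np.uint8)
    if X.shape[1] != input_size or X.shape[2] != input_size:
        X = np.stack([
            np.asarray(Image.fromarray(img).resize((input_size, input_size),
                                                   Image.BILINEAR))
            for img in X])
    t = X.astype(np.float32) / 255.0
    t = (t - _NORM_MEAN) / _NORM_STD
    return np.ascontiguousarray(np.moveaxis(t, -1, 1))


class CanopyClassifier(BaseEstimator, ClassifierMixin):
    """CNN classifier for canopy images with a fit/predict surface.

    Parameters
    ----------
    preset : architecture preset name (``g_ppw_vgg11`` by default).
    input_size : square input side in pixels; must be a multiple of 32.
    epochs, batch_size, lr, lr_decay, decay_every, weight_decay :
        the training schedule (AdamW + cross entropy + step decay).
    max_steps : optional cap on optimiser steps (desk-scale experiments).
    seed : drives weight init, shuffling and dropout.
    """

    def __init__(self, preset: str = "g_ppw_vgg11", input_size: int = 32,
                 epochs: int = 20, batch_size: int = 32, lr: float = 0.005,
                 lr_decay: float = 0.5, decay_every: int = 8,
                 weight_decay: float = 0.01, max_steps: int | None = None,
                 seed: int = 0):
        self.preset = preset
        self.input_size = input_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_decay = lr_decay
        self.decay_every = decay_every
        self.weight_decay = weight_decay
        self.max_steps = max_steps
        self.seed = seed

    def _train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, lr_decay=self.lr_decay,
                           decay_every=self.decay_every,
                           batch_size=self.batch_size, epochs=self.epochs,
                           weight_decay=self.weight_decay,
                           max_steps=self.max_steps, seed=self.seed)

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to fit")
        Xt = images_to_tensor(X, self.input_size)
        self.model_ = build_model(self.preset, seed=self.seed,
                                  num_classes=len(self.classes_),
                                  input_size=self.input_size)
        log = train(self.model_, Xt, y_enc, self._train_config())
        self.loss_curve_ = log.epoch_losses
        self.n_iter_ = log.steps
        self.model_.eval()
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        Xt = images_to_tensor(X, self.input_size)
        return predict_scores(self.model_, Xt)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
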