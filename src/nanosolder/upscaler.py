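"""The x4 thermal-map upscaling network.

A small fully convolutional network maps a low-resolution thermal image
(e.g. the 5x5 fiber-bundle measurement) to a x4-resolution reconstruction
(20x20): four 3x3 convolutions (channel widths 1-64-64-32-1) with PReLU
activations, and nearest-neighbor x2 upsampling between layers 2-3 and 3-4.
Training minimizes 1 - SSIM on images affine-normalized over a fixed
20-90 degC range (so the absolute temperature scale is preserved), with
Adam at learning rate 1e-3.

:class:`ThermalUpscaler` follows the fit/predict estimator idiom
(constructor hyperparameters, ``get_params``/``set_params``, fitted
attributes with trailing underscores); the module-level functions are thin
wrappers over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .dataset import TEMP_NORM_RANGE_C, DatasetSample, normalize_temperature, upsample_nearest
from .errors import ConfigurationError, NotFittedError, ParameterError
from .nn import Adam, Conv2D, PReLU, UpsampleNearest2x, ssim_loss_and_grad

__all__ = [
    "UpscalerSpec",
    "TrainingConfig",
    "ThermalUpscaler",
    "build_upscaler",
    "train_upscaler",
    "reconstruct",
    "evaluate_upscaler",
    "split_dataset",
    "save_checkpoint",
    "load_checkpoint",
]

#: Reconstruction clamp range in degC.
CLAMP_RANGE_C = (15.0, 100.0)


@dataclass(frozen=True)
class UpscalerSpec:
    """Architecture description; two x2 upsampling stages give the x4 factor."""

    channels: tuple[int, int, int] = (64, 64, 32)
    kernel_size: int = 3
    prelu_init: float = 0.25

    def __post_init__(self):
        if len(self.channels) != 3:
            raise ConfigurationError("expected three hidden channel widths")
        if self.kernel_size % 2 != 1:
            raise ConfigurationError("kernel_size must be odd for 'same' padding")


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters.

    Defaults are the desk-scale profile (100 epochs, batch 256); the
    full-scale profile (300 epochs, batch 500) is available via
    :meth:`full_scale`. A quarter of the dataset is held out for testing
    and the remainder split 80/20 into train/validation, all drawn once
    from ``seed``.
    """

    epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 1e-3
    test_fraction: float = 0.25
    val_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        for f in (self.test_fraction, self.val_fraction):
            if not 0.0 < f < 1.0:
                raise ConfigurationError("split fractions must be in (0, 1)")

    @classmethod
    def full_scale(cls, seed: int = 0) -> "TrainingConfig":
        return cls(epochs=300, batch_size=500, seed=seed)


class ThermalUpscaler:
    """Fully convolutional x4 upscaler with a fit/predict interface.

    Parameters
    ----------
    channels, kernel_size, prelu_init : architecture (see :class:`UpscalerSpec`)
    epochs, batch_size, learning_rate, val_fraction, seed : training profile

    Fitted attributes (set by :meth:`fit`): ``layers_``, ``history_``,
    ``n_epochs_``.
    """

    def __init__(
        self,
        channels: tuple[int, int, int] = (64, 64, 32),
        kernel_size: int = 3,
        prelu_init: float = 0.25,
        epochs: int = 100,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        val_fraction: float = 0.20,
        warmup_epochs: int = 2,
        seed: int = 0,
    ):
        self.channels = tuple(channels)
        self.kernel_size = kernel_size
        self.prelu_init = prelu_init
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.val_fraction = val_fraction
        self.warmup_epochs = warmup_epochs
        self.seed = seed

    # -- estimator plumbing -------------------------------------------------
    _param_names = (
        "channels", "kernel_size", "prelu_init", "epochs",
        "batch_size", "learning_rate", "val_fraction", "warmup_epochs", "seed",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "ThermalUpscaler":
        for k, v in params.items():
            if k not in self._param_names:
                raise ConfigurationError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- architecture -------------------------------------------------------
    def _build(self, rng: np.random.Generator) -> list:
        c1, c2, c3 = self.channels
        k = self.kernel_size
        layers = [
            Conv2D(1, c1, k, rng), PReLU(self.prelu_init),
            Conv2D(c1, c2, k, rng), PReLU(self.prelu_init),
            UpsampleNearest2x(),
            Conv2D(c2, c3, k, rng), PReLU(self.prelu_init),
            UpsampleNearest2x(),
            Conv2D(c3, 1, k, rng),  # linear head; clamping happens at inference
        ]
        # start the output at mid-range: SSIM is sign-ambiguous (an inverted,
        # negatively-correlated image scores positively through the product of
        # two negative terms), and a mid-range start keeps optimization in the
        # physically meaningful positive-correlation basin
        layers[-1].bias[:] = 0.5
        return layers

    def initialize(self) -> "ThermalUpscaler":
        """Deterministically initialize weights from ``seed`` without training."""
        UpscalerSpec(self.channels, self.kernel_size, self.prelu_init)  # validate
        rng = np.random.default_rng(self.seed)
        self.layers_ = self._build(rng)
        self.history_ = {"train_loss": [], "val_loss": [], "val_psnr": []}
        self.n_epochs_ = 0
        return self

    def _forward_norm(self, xn: np.ndarray, train: bool = False) -> np.ndarray:
        h = np.asarray(xn, dtype=np.float32)[..., None]  # channels-last
        for layer in self.layers_:
            h = layer.forward(h)
        return h[..., 0]

    def _backward(self, dgrad: np.ndarray) -> None:
        g = np.asarray(dgrad, dtype=np.float32)[..., None]
        for layer in reversed(self.layers_):
            g = layer.backward(g)

    def _check_fitted(self):
        if not hasattr(self, "layers_"):
            raise NotFittedError("upscaler is not initialized/trained; call fit() or initialize()")

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, X_val: np.ndarray | None = None, y_val: np.ndarray | None = None):
        """Train on degC image pairs ``X`` (n, h, w) -> ``y`` (n, 4h, 4w).

        When no validation set is given, ``val_fraction`` of the data is
        split off once using ``seed``. History records per-epoch mean train
        loss (1 - SSIM), validation loss and validation PSNR.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or y.ndim != 3 or X.shape[0] != y.shape[0]:
            raise ParameterError("X and y must be (n, h, w) with matching n")
        if X.shape[0] == 0:
            raise ParameterError("empty dataset")
        if y.shape[1] != 4 * X.shape[1] or y.shape[2] != 4 * X.shape[2]:
            raise ParameterError("targets must be exactly 4x the input resolution")

        UpscalerSpec(self.channels, self.kernel_size, self.prelu_init)  # validate
        rng = np.random.default_rng(self.seed)
        self.layers_ = self._build(rng)  # one seed-derived stream for init + splits + shuffles
        self.history_ = {"train_loss": [], "val_loss": [], "val_psnr": []}
        self.n_epochs_ = 0
        if X_val is None:
            n = X.shape[0]
            perm = rng.permutation(n)
            n_val = max(1, int(round(self.val_fraction * n))) if n > 1 else 0
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            if tr_idx.size == 0:
                tr_idx, val_idx = perm, perm[:0]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        if X.shape[0] < 2 * self.batch_size:
            import warnings

            warnings.warn(
                f"training set ({X.shape[0]}) smaller than 2 x batch_size ({self.batch_size})",
                stacklevel=2,
            )

        xn = normalize_temperature(X)
        yn = normalize_temperature(y)
        xvn = normalize_temperature(X_val) if X_val is not None and len(X_val) else None
        yvn = normalize_temperature(y_val) if xvn is not None else None

        params = [p for layer in self.layers_ for p in layer.params]
        opt = Adam(params, lr=self.learning_rate)
        n = xn.shape[0]
        for epoch in range(self.epochs):
            # SSIM is blind to a joint sign flip (an anti-correlated, mean-
            # mirrored image scores like the true one), so a short MSE warm-up
            # anchors optimization in the positive-correlation basin before
            # the structural objective takes over
            warmup = epoch < self.warmup_epochs
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                pred = self._forward_norm(xn[idx], train=True)
                loss, dpred = ssim_loss_and_grad(pred, yn[idx])
                if warmup:
                    dpred = (2.0 / pred.size) * (pred - yn[idx])
                self._backward(dpred)
                grads = [g for layer in self.layers_ for g in layer.grads]
                opt.step(grads)
                losses.append(loss)
            self.history_["train_loss"].append(float(np.mean(losses)))
            if xvn is not None:
                vpred = self._forward_norm(xvn)
                vloss, _ = ssim_loss_and_grad(vpred, yvn)
                mse = float(np.mean((vpred - yvn) ** 2))
                psnr = float("inf") if mse == 0 else 10.0 * np.log10(1.0 / mse)
                self.history_["val_loss"].append(vloss)
                self.history_["val_psnr"].append(psnr)
            self.n_epochs_ += 1
        return self

    # -- inference ----------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Reconstruct degC maps at 4x resolution, clamped to [15, 100] degC."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        if not np.all(np.isfinite(X)):
            raise ParameterError("input image must be finite")
        pred = self._forward_norm(normalize_temperature(X))
        lo, hi = TEMP_NORM_RANGE_C
        out = np.clip(pred * (hi - lo) + lo, *CLAMP_RANGE_C)
        return out[0] if single else out


# -- functional wrappers ----------------------------------------------------

def build_upscaler(spec: UpscalerSpec = UpscalerSpec(), seed: int = 0) -> ThermalUpscaler:
    """Untrained upscaler with deterministic seed-derived initialization."""
    model = ThermalUpscaler(
        channels=spec.channels, kernel_size=spec.kernel_size, prelu_init=spec.prelu_init, seed=seed
    )
    return model.initialize()


def split_dataset(
    n: int, config: TrainingConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seed-determined (train, val, test) index split: 25% test, then 80/20."""
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_test = int(round(config.test_fraction * n))
    test = perm[:n_test]
    rest = perm[n_test:]
    n_val = int(round(config.val_fraction * rest.size))
    return rest[n_val:], rest[:n_val], test


def _stack(samples: list[DatasetSample]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.stack([s.input_c for s in samples]),
        np.stack([s.target_c for s in samples]),
    )


def train_upscaler(
    samples: list[DatasetSample], config: TrainingConfig = TrainingConfig()
) -> tuple[ThermalUpscaler, list[DatasetSample]]:
    """Split the dataset per the config, train, and return (model, test set)."""
    if len(samples) == 0:
        raise ParameterError("empty dataset")
    X, y = _stack(samples)
    tr, va, te = split_dataset(len(samples), config)
    model = ThermalUpscaler(
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        val_fraction=config.val_fraction,
        seed=config.seed,
    )
    model.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
    return model, [samples[i] for i in te]


def reconstruct(model: ThermalUpscaler, low_res_c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct one low-res degC image; returns (map_degC, validity mask)."""
    out = model.predict(np.asarray(low_res_c, dtype=float))
    return out, np.ones_like(out, dtype=bool)


def evaluate_upscaler(model: ThermalUpscaler, samples: list[DatasetSample]) -> dict:
    """SSIM, PSNR (normalized images) and peak-temperature error per sample.

    Returns per-sample arrays plus mean/sd aggregates; ``delta_tmax_c`` is
    |max(target) - max(reconstruction)| in degC.
    """
    if len(samples) == 0:
        raise ParameterError("need at least one test sample")
    X, y = _stack(samples)
    pred = model.predict(X)
    ssim = np.empty(len(samples))
    psnr = np.empty(len(samples))
    dtmax = np.empty(len(samples))
    for i in range(len(samples)):
        pn = normalize_temperature(pred[i])
        tn = normalize_temperature(y[i])
        ssim[i] = structural_similarity(pn, tn, win_size=7, data_range=1.0)
        mse = float(np.mean((pn - tn) ** 2))
        psnr[i] = np.inf if mse == 0 else 10.0 * np.log10(1.0 / mse)
        dtmax[i] = abs(float(y[i].max()) - float(pred[i].max()))
    return {
        "ssim": ssim,
        "psnr": psnr,
        "delta_tmax_c": dtmax,
        "ssim_mean": float(ssim.mean()),
        "ssim_sd": float(ssim.std(ddof=1)) if len(samples) > 1 else 0.0,
        "psnr_mean": float(psnr.mean()),
        "psnr_sd": float(psnr.std(ddof=1)) if len(samples) > 1 else 0.0,
        "delta_tmax_mean_c": float(dtmax.mean()),
        "delta_tmax_sd_c": float(dtmax.std(ddof=1)) if len(samples) > 1 else 0.0,
        "n": len(samples),
    }


def baseline_nearest_ssim(samples: list[DatasetSample]) -> float:
    """Mean SSIM of plain nearest-neighbor upsampling (the no-learning baseline)."""
    vals = []
    for s in samples:
        up = normalize_temperature(upsample_nearest(s.input_c, 4))
        tn = normalize_temperature(s.target_c)
        vals.append(structural_similarity(up, tn, win_size=7, data_range=1.0))
    return float(np.mean(vals))


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(model: ThermalUpscaler, path, manifest: dict | None = None) -> None:
    """Single-file archive: weights + hyperparameters + training history."""
    model._check_fitted()
    arrays = {}
    for i, layer in enumerate(model.layers_):
        for j, p in enumerate(layer.params):
            arrays[f"layer{i}_p{j}"] = p
    meta = {
        "params": model.get_params(),
        "history": model.history_,
        "n_epochs": model.n_epochs_,
        "norm_range_c": TEMP_NORM_RANGE_C,
        "manifest": manifest or {},
    }
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> ThermalUpscaler:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        model = ThermalUpscaler(**{
            k: tuple(v) if k == "channels" else v for k, v in meta["params"].items()
        })
        model.initialize()
        for i, layer in enumerate(model.layers_):
            for j, p in enumerate(layer.params):
                p[...] = npz[f"layer{i}_p{j}"]  # in place: keeps dtype and bindings
        model.history_ = meta["history"]
        model.n_epochs_ = meta["n_epochs"]
    return model
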