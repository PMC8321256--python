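"""Dense and convolutional autoencoders for 192-feature pixel vectors.

The dense autoencoder (AE) maps 192 -> 128 -> 64 -> k and mirrors back; the
convolutional autoencoder (CAE) reads the vector as a 12-step sequence with
16 channels, applies three 1-D convolutions (32 -> 64 -> 64 channels, kernel
3, stride-2 downsampling on the first two) and collects the latents with a
single dense layer; its decoder mirrors the encoder with nearest-neighbour
upsampling.  Both minimise mean squared reconstruction error on z-scored
inputs with a 95/5 train/validation split, Adam, and early stopping.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from veglatent.compositing import N_FEATURES
from veglatent.encoders._nn import (
    Adam,
    Conv1D,
    Dense,
    Flatten,
    FromSequence,
    ReLU,
    Sequential,
    ToSequence,
    Unflatten,
    Upsample1D,
)

logger = logging.getLogger(__name__)

KINDS = ("ae", "cae")


@dataclass
class TrainConfig:
    """Hyper-parameters of autoencoder training; every field has a default."""

    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.05
    seed: int = 0
    ae_hidden: tuple[int, int] = (128, 64)
    cae_channels: tuple[int, int, int] = (32, 64, 64)
    kernel: int = 3


@dataclass
class Standardizer:
    """Per-feature z-scoring; zero-variance features pass through as constants."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        # mean round-off leaves a constant column with sd ~1e-17, never 0
        const = sd <= 1e-12 * np.maximum(np.abs(mean), 1.0)
        sd = np.where(const, 0.0, sd)
        n_const = int(np.count_nonzero(const))
        if n_const:
            warnings.warn(
                f"{n_const} zero-variance feature(s); they are standardized to 0 "
                "and reinserted as constants at decode",
                stacklevel=2,
            )
        return cls(mean=mean, sd=sd)

    @property
    def _safe_sd(self) -> np.ndarray:
        return np.where(self.sd > 0, self.sd, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self._safe_sd

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return Z * self._safe_sd + self.mean


@dataclass
class EncoderModel:
    """A fitted autoencoder: encoder/decoder networks plus preprocessing."""

    kind: str
    latent_dim: int
    encoder: Sequential
    decoder: Sequential
    standardizer: Standardizer
    history: dict = field(default_factory=dict)
    config: TrainConfig = field(default_factory=TrainConfig)
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"expected (n, {N_FEATURES}) feature matrix, got {X.shape}")
        return X

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Map raw (n, 192) features to (n, k) latent features."""
        Z = self.encoder.forward(self.standardizer.transform(self._check_width(X)))
        return Z

    def decode(self, latents: np.ndarray) -> np.ndarray:
        """Map (n, k) latents back to raw (n, 192) reconstructions."""
        latents = np.asarray(latents, dtype=np.float64)
        if latents.ndim != 2 or latents.shape[1] != self.latent_dim:
            raise ValueError(f"expected (n, {self.latent_dim}) latents, got {latents.shape}")
        return self.standardizer.inverse_transform(self.decoder.forward(latents))

    def reconstruct_standardized(self, X: np.ndarray) -> np.ndarray:
        Xs = self.standardizer.transform(self._check_width(X))
        return self.decoder.forward(self.encoder.forward(Xs))

    def save(self, path: str | Path) -> Path:
        """Persist to a single .npz file; load -> encode is bit-identical."""
        path = Path(path)
        arrays = {}
        for tag, net in (("enc", self.encoder), ("dec", self.decoder)):
            for i, p in enumerate(net.params):
                arrays[f"{tag}_{i}"] = p
        arrays["mean"] = self.standardizer.mean
        arrays["sd"] = self.standardizer.sd
        if self.train_idx is not None:
            arrays["train_idx"] = self.train_idx
            arrays["val_idx"] = self.val_idx
        meta = {
            "kind": self.kind,
            "latent_dim": self.latent_dim,
            "history": self.history,
            "config": asdict(self.config),
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        path.write_bytes(buf.getvalue())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "EncoderModel":
        with np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files}
        meta = json.loads(arrays.pop("meta").tobytes().decode())
        cfg_d = meta["config"]
        cfg_d["ae_hidden"] = tuple(cfg_d["ae_hidden"])
        cfg_d["cae_channels"] = tuple(cfg_d["cae_channels"])
        config = TrainConfig(**cfg_d)
        encoder, decoder = _build_networks(
            meta["kind"], meta["latent_dim"], config, np.random.default_rng(0)
        )
        encoder.set_weights([arrays[f"enc_{i}"] for i in range(len(encoder.params))])
        decoder.set_weights([arrays[f"dec_{i}"] for i in range(len(decoder.params))])
        return cls(
            kind=meta["kind"],
            latent_dim=meta["latent_dim"],
            encoder=encoder,
            decoder=decoder,
            standardizer=Standardizer(mean=arrays["mean"], sd=arrays["sd"]),
            history=meta["history"],
            config=config,
            train_idx=arrays.get("train_idx"),
            val_idx=arrays.get("val_idx"),
        )


def _build_networks(
    kind: str, k: int, cfg: TrainConfig, rng: np.random.Generator
) -> tuple[Sequential, Sequential]:
    if kind == "ae":
        h1, h2 = cfg.ae_hidden
        encoder = Sequential([
            Dense(N_FEATURES, h1, rng), ReLU(),
            Dense(h1, h2, rng), ReLU(),
            Dense(h2, k, rng),
        ])
        decoder = Sequential([
            Dense(k, h2, rng), ReLU(),
            Dense(h2, h1, rng), ReLU(),
            Dense(h1, N_FEATURES, rng),
        ])
        return encoder, decoder
    if kind == "cae":
        c1, c2, c3 = cfg.cae_channels
        ker = cfg.kernel
        # 12-step sequence, 16 channels: 12 -> 6 -> 3 along the month axis
        flat = c3 * 3
        encoder = Sequential([
            ToSequence(steps=12, channels=16),
            Conv1D(16, c1, rng, kernel=ker, stride=2), ReLU(),
            Conv1D(c1, c2, rng, kernel=ker, stride=2), ReLU(),
            Conv1D(c2, c3, rng, kernel=ker, stride=1), ReLU(),
            Flatten(),
            Dense(flat, k, rng),
        ])
        decoder = Sequential([
            Dense(k, flat, rng), ReLU(),
            Unflatten(channels=c3, length=3),
            Conv1D(c3, c2, rng, kernel=ker, stride=1), ReLU(),
            Upsample1D(2),
            Conv1D(c2, c1, rng, kernel=ker, stride=1), ReLU(),
            Upsample1D(2),
            Conv1D(c1, 16, rng, kernel=ker, stride=1),
            FromSequence(),
        ])
        return encoder, decoder
    raise ValueError(f"unknown autoencoder kind {kind!r}; expected one of {KINDS}")


def fit_autoencoder(
    X: np.ndarray,
    kind: str = "ae",
    latent_dim: int = 3,
    config: TrainConfig | None = None,
) -> EncoderModel:
    """Train an autoencoder on an (n_pixels, 192) feature matrix.

    Inputs are z-scored per feature; training minimises MSE on a random 95/5
    train/validation split with Adam and early stopping (best validation
    weights restored).  Fixed ``config.seed`` makes the fit reproducible.
    """
    cfg = config or TrainConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"expected (n, {N_FEATURES}) matrix, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values; run gap filling first")
    n = X.shape[0]
    if n < 100:
        raise ValueError(f"need at least 100 pixels to train, got {n}")
    if latent_dim >= N_FEATURES:
        raise ValueError(f"latent_dim must be < {N_FEATURES}, got {latent_dim}")
    if kind not in KINDS:
        raise ValueError(f"unknown autoencoder kind {kind!r}; expected one of {KINDS}")

    rng = np.random.default_rng(cfg.seed)
    std = Standardizer.fit(X)
    Xs = std.transform(X)

    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xtr, Xval = Xs[train_idx], Xs[val_idx]

    encoder, decoder = _build_networks(kind, latent_dim, cfg, rng)
    params = encoder.params + decoder.params
    grads = encoder.grads + decoder.grads
    opt = Adam(params, grads, lr=cfg.learning_rate)

    history: dict[str, list[float]] = {"train": [], "val": []}
    best_val = np.inf
    best_weights = None
    stale = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(Xtr))
        total, count = 0.0, 0
        for start in range(0, len(Xtr), cfg.batch_size):
            batch = Xtr[order[start:start + cfg.batch_size]]
            out = decoder.forward(encoder.forward(batch))
            resid = out - batch
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}; "
                    "reduce the learning rate or check the inputs"
                )
            dout = 2.0 * resid / resid.size
            encoder.backward(decoder.backward(dout))
            opt.step()
            total += loss * len(batch)
            count += len(batch)
        train_loss = total / count
        val_out = decoder.forward(encoder.forward(Xval))
        val_loss = float(np.mean((val_out - Xval) ** 2))
        history["train"].append(train_loss)
        history["val"].append(val_loss)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = (encoder.get_weights(), decoder.get_weights())
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                logger.info("early stopping at epoch %d (best val %.3g)", epoch + 1, best_val)
                break

    if best_weights is not None:
        encoder.set_weights(best_weights[0])
        decoder.set_weights(best_weights[1])

    return EncoderModel(
        kind=kind,
        latent_dim=latent_dim,
        encoder=encoder,
        decoder=decoder,
        standardizer=std,
        history=history,
        config=cfg,
        train_idx=train_idx,
        val_idx=val_idx,
    )


def encode(model: EncoderModel, X: np.ndarray) -> np.ndarray:
    """Deterministically map an (n, 192) matrix to (n, k) latent features."""
    return model.encode(X)


def reconstruction_report(model: EncoderModel, X: np.ndarray) -> dict:
    """Reconstruction quality summary on standardized scale.

    Returns overall MSE, train/validation MSE for the model's stored split
    (when ``X`` matches the training matrix length), and per-feature residual
    mean / RMS.
    """
    X = np.asarray(X, dtype=np.float64)
    Xs = model.standardizer.transform(X)
    out = model.reconstruct_standardized(X)
    resid = out - Xs
    report = {
        "mse": float(np.mean(resid**2)),
        "per_feature_residual_mean": resid.mean(axis=0),
        "per_feature_residual_rms": np.sqrt(np.mean(resid**2, axis=0)),
        "history": model.history,
    }
    if model.train_idx is not None and len(X) > max(
        model.train_idx.max(initial=-1), model.val_idx.max(initial=-1)
    ):
        report["train_mse"] = float(np.mean(resid[model.train_idx] ** 2))
        report["val_mse"] = float(np.mean(resid[model.val_idx] ** 2))
    return report
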