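"""Convolutional patch autoencoder.

Compresses a 128x128 RGB patch into a fixed-length latent vector (default
2048 numbers) by minimizing pixel reconstruction error, with no labels
involved.  The encoder is four stride-2 3x3 convolution blocks
(128 -> 64 -> 32 -> 16 -> 8 spatial, 32 channels), whose flattened
8x8x32 = 2048 feature map is linearly projected to the ``latent_dim``
bottleneck.  The decoder mirrors it: a dense layer back to the conv
feature size, then nearest-neighbour-upsample + stride-1 convolution
("resize-conv") blocks with a sigmoid output; pixels are scaled to [0, 1]
for the mean-squared loss and mapped back to 0-255 for display.

Training runs Adam on mini-batches; the seed controls both weight
initialization and batch shuffling, so identical config + data + seed
reproduce the run bit-for-bit on the same machine.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .tiling import Patch, patches_to_array

__all__ = ["PatchAutoencoder", "train_autoencoder", "encode", "decode"]

_DOWN = 16  # total spatial downscaling of the encoder (4 stride-2 blocks)


def _coerce_images(X) -> np.ndarray:
    """Accept Patch sequences or (n, h, w, 3) arrays; return uint8 array."""
    if isinstance(X, np.ndarray):
        arr = X
        if arr.ndim == 3:
            arr = arr[None]
    else:
        seq = list(X)
        if len(seq) == 0:
            raise ValueError("empty patch set")
        if isinstance(seq[0], Patch):
            arr = patches_to_array(seq)
        else:
            arr = np.stack([np.asarray(p) for p in seq])
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise ValueError(f"expected (n, h, w, 3) RGB patches, got shape {arr.shape}")
    if arr.shape[0] == 0:
        raise ValueError("empty patch set")
    if arr.dtype != np.uint8:
        raise ValueError(f"expected 8-bit patches, got dtype {arr.dtype}")
    return arr


class PatchAutoencoder(TransformerMixin, BaseEstimator):
    """Unsupervised encoder-decoder over fixed-size RGB patches.

    Parameters
    ----------
    latent_dim : int, default 2048
        Length of the bottleneck vector (any positive integer; the conv
        feature map is linearly projected down or up to this size).
    epochs : int, default 50
        Full passes over the training patches.
    batch_size : int, default 64
    learning_rate : float, default 1e-3
    random_state : int or None
        Seed for weight init and batch shuffling.

    Attributes
    ----------
    encoder_, decoder_ : lists of layers (internal).
    loss_curve_ : list of float, mean reconstruction MSE per epoch
        (pixels on the [0, 1] scale).
    input_shape_ : (h, w) of training patches.
    """

    def __init__(
        self,
        latent_dim: int = 2048,
        epochs: int = 50,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        random_state: Optional[int] = None,
    ):
        self.latent_dim = latent_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _build(self, h: int, w: int, rng: np.random.Generator):
        if h % _DOWN or w % _DOWN:
            raise ValueError(f"patch size ({h}x{w}) must be a multiple of {_DOWN}")
        if not isinstance(self.latent_dim, int) or self.latent_dim <= 0:
            raise ValueError(f"latent_dim must be a positive integer, got {self.latent_dim}")
        gh, gw_ = h // _DOWN, w // _DOWN
        feat = gh * gw_ * 32  # flattened conv feature (2048 for 128x128)
        self.encoder_ = [
            _nn.Conv2d(3, 8, 2, rng), _nn.ReLU(),
            _nn.Conv2d(8, 16, 2, rng), _nn.ReLU(),
            _nn.Conv2d(16, 32, 2, rng), _nn.ReLU(),
            _nn.Conv2d(32, 32, 2, rng), _nn.ReLU(),
            _nn.Flatten(),
            _nn.Dense(feat, self.latent_dim, rng, gain="linear"),
        ]
        self.decoder_ = [
            _nn.Dense(self.latent_dim, feat, rng, gain="relu"), _nn.ReLU(),
            _nn.Reshape((32, gh, gw_)),
            _nn.Upsample2x(), _nn.Conv2d(32, 32, 1, rng), _nn.ReLU(),
            _nn.Upsample2x(), _nn.Conv2d(32, 16, 1, rng), _nn.ReLU(),
            _nn.Upsample2x(), _nn.Conv2d(16, 8, 1, rng), _nn.ReLU(),
            _nn.Upsample2x(), _nn.Conv2d(8, 3, 1, rng, gain="linear"), _nn.Sigmoid(),
        ]

    def fit(self, X, y=None):
        """Train on patches (sequence of Patch or (n, h, w, 3) uint8 array)."""
        arr = _coerce_images(X)
        n, h, w, _ = arr.shape
        rng = np.random.default_rng(self.random_state)
        self._build(h, w, rng)
        self.input_shape_ = (h, w)
        data = (arr.astype(_nn.DTYPE) / 255.0).transpose(0, 3, 1, 2)
        opt = _nn.Adam(self.encoder_ + self.decoder_, lr=self.learning_rate)
        self.loss_curve_ = []
        bs = max(1, int(self.batch_size))
        for _ in range(int(self.epochs)):
            perm = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, bs):
                idx = perm[start : start + bs]
                x = data[idx]
                z = _nn.forward_chain(self.encoder_, x, train=True)
                y_hat = _nn.forward_chain(self.decoder_, z, train=True)
                diff = y_hat - x
                loss = float(np.mean(diff * diff))
                dout = (2.0 / diff.size) * diff
                dz = _nn.backward_chain(self.decoder_, dout)
                _nn.backward_chain(self.encoder_, dz)
                opt.step()
                epoch_loss += loss * len(idx)
                seen += len(idx)
            self.loss_curve_.append(epoch_loss / seen)
        self.n_epochs_ = int(self.epochs)
        return self

    # ------------------------------------------------------------------ #

    def transform(self, X) -> np.ndarray:
        """Encode patches into an (n, latent_dim) float array."""
        check_is_fitted(self, "encoder_")
        arr = _coerce_images(X)
        if arr.shape[1:3] != self.input_shape_:
            raise ValueError(
                f"patch shape {arr.shape[1:3]} does not match training shape "
                f"{self.input_shape_}"
            )
        data = (arr.astype(_nn.DTYPE) / 255.0).transpose(0, 3, 1, 2)
        out = []
        bs = max(1, int(self.batch_size))
        for start in range(0, len(data), bs):
            z = _nn.forward_chain(self.encoder_, data[start : start + bs])
            out.append(z.reshape(z.shape[0], -1).copy())  # layers reuse buffers
        latents = np.concatenate(out, axis=0)
        if not np.all(np.isfinite(latents)):
            raise FloatingPointError("non-finite values in latent encoding")
        return latents

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        """Decode (n, latent_dim) latents back to (n, h, w, 3) uint8 rasters."""
        check_is_fitted(self, "decoder_")
        Z = np.asarray(Z, dtype=_nn.DTYPE)
        if Z.ndim == 1:
            Z = Z[None]
        if Z.shape[1] != self.latent_dim:
            raise ValueError(
                f"latent length {Z.shape[1]} does not match latent_dim "
                f"{self.latent_dim}"
            )
        out = []
        bs = max(1, int(self.batch_size))
        for start in range(0, len(Z), bs):
            y = _nn.forward_chain(self.decoder_, Z[start : start + bs])
            out.append(y.copy())  # layers reuse buffers
        img = np.concatenate(out, axis=0).transpose(0, 2, 3, 1)
        return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)

    # ------------------------------------------------------------------ #

    def save(self, path: str) -> None:
        """Serialize weights + config; reload gives bit-identical encodings."""
        check_is_fitted(self, "encoder_")
        blobs = {}
        for tag, layers in (("enc", self.encoder_), ("dec", self.decoder_)):
            for i, layer in enumerate(layers):
                if hasattr(layer, "w"):
                    blobs[f"{tag}{i}_w"] = layer.w
                    blobs[f"{tag}{i}_b"] = layer.b
        meta = dict(
            params=self.get_params(),
            input_shape=list(self.input_shape_),
            loss_curve=self.loss_curve_,
        )
        np.savez_compressed(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **blobs)

    @classmethod
    def load(cls, path: str) -> "PatchAutoencoder":
        with np.load(path if str(path).endswith(".npz") else f"{path}.npz") as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(**meta["params"])
            h, w = meta["input_shape"]
            model._build(h, w, np.random.default_rng(0))
            model.input_shape_ = (h, w)
            model.loss_curve_ = list(meta["loss_curve"])
            model.n_epochs_ = len(model.loss_curve_)
            for tag, layers in (("enc", model.encoder_), ("dec", model.decoder_)):
                for i, layer in enumerate(layers):
                    if hasattr(layer, "w"):
                        layer.w[...] = data[f"{tag}{i}_w"]
                        layer.b[...] = data[f"{tag}{i}_b"]
        return model


# ---------------------------------------------------------------------- #
# functional wrappers

def train_autoencoder(
    patches: Sequence[Patch],
    latent_dim: int = 2048,
    epochs: int = 50,
    batch_size: int = 64,
    learning_rate: float = 1e-3,
    seed: Optional[int] = None,
) -> PatchAutoencoder:
    return PatchAutoencoder(
        latent_dim=latent_dim,
        epochs=epochs,
        batch_size=batch_size,
        learning_rate=learning_rate,
        random_state=seed,
    ).fit(patches)


def encode(model: PatchAutoencoder, patch: Union[Patch, np.ndarray]) -> np.ndarray:
    """Encode one patch into a 1-D latent vector of length ``latent_dim``."""
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    return model.transform(pixels[None])[0]


def decode(model: PatchAutoencoder, latent: np.ndarray) -> np.ndarray:
    """Decode one latent vector back to an (h, w, 3) uint8 raster."""
    return model.inverse_transform(np.asarray(latent)[None])[0]
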