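"""Image and structure encoders mapping both modalities into one
d-dimensional unit-norm embedding space.

The image encoder is a pre-activation residual network adapted to
multi-channel fluorescence input: a patchify convolution (non-overlapping
stride=kernel convolution whose first layer is widened to C input
channels) with learned positional embeddings, residual fully-connected
blocks on patch features, then a projection head that pools the patch
axis (concatenated mean + max) and maps linearly to the embedding sphere.
The structure encoder is a descriptor-based fully-connected network over
fingerprint bits — by default 4 hidden layers of 1024 units with ReLU
activations and batch normalization — with the same kind of head.

Both encoders expose penultimate (pre-head) features for linear probing —
the flattened last-stage patch grid for images, the last hidden layer for
structures — and are pure functions of (input, weights) in eval mode.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import (BatchNorm1d, Linear, Module, ResidualBlock, Tensor,
                 l2_normalize)
from .nn.autograd import cat, no_grad
from .records import EmbeddingMatrix

__all__ = ["EncoderConfig", "ImageEncoder", "StructureEncoder",
           "ContrastiveModel", "image_encode", "structure_encode",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class EncoderConfig:
    embed_dim: int = 512
    image_channels: int = 5
    image_backbone: str = "patch-resnet"
    image_depth: int = 2            # residual blocks after the patch stem
    image_width: int = 256          # patch feature width
    patch_size: int = 8
    image_hw: tuple[int, int] = (32, 32)
    fp_bits: int = 1024
    structure_hidden: tuple[int, ...] = (1024, 1024, 1024, 1024)
    activation: str = "relu"
    batch_norm: bool = True

    def __post_init__(self):
        if self.embed_dim <= 0:
            raise ValueError("embed_dim must be positive")
        if any(w <= 0 for w in self.structure_hidden):
            raise ValueError("hidden widths must be positive")
        if self.image_backbone != "patch-resnet":
            raise ValueError(f"unknown backbone: {self.image_backbone}")


class ImageEncoder(Module):
    def __init__(self, config: EncoderConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        p = config.patch_size
        self.stem = Linear(config.image_channels * p * p, config.image_width,
                           rng)
        n_patches = (config.image_hw[0] // p) * (config.image_hw[1] // p)
        # learned positional embedding: mean pooling would otherwise make
        # the representation blind to where in the field a structure sits
        self.pos_embed = Tensor(
            rng.normal(0.0, 0.02, (n_patches, config.image_width)),
            requires_grad=True)
        self.stem_bn = BatchNorm1d(config.image_width)
        self.blocks = [ResidualBlock(config.image_width, rng)
                       for _ in range(config.image_depth)]
        # mean + max pooling: the mean summarizes diffuse intensity, the max
        # keeps sharply localized responses (stained structures) that mean
        # pooling would wash out
        self.head = Linear(2 * config.image_width, config.embed_dim, rng)

    def _patchify(self, pixels: np.ndarray) -> np.ndarray:
        B, C, H, W = pixels.shape
        p = self.config.patch_size
        if H < p or W < p:
            raise ValueError(f"image {H}x{W} smaller than patch size {p}")
        H2, W2 = (H // p) * p, (W // p) * p
        top, left = (H - H2) // 2, (W - W2) // 2
        x = pixels[:, :, top:top + H2, left:left + W2]
        x = x.reshape(B, C, H2 // p, p, W2 // p, p)
        x = x.transpose(0, 2, 4, 1, 3, 5).reshape(B, -1, C * p * p)
        return x  # (B, n_patches, C*p*p)

    def forward(self, pixels: np.ndarray) -> tuple[Tensor, Tensor]:
        """Return (unit-norm embeddings, flattened patch-grid features)."""
        pixels = np.asarray(pixels, dtype=np.float64)
        if pixels.ndim == 3:
            pixels = pixels[None]
        if pixels.shape[1] != self.config.image_channels:
            raise ValueError(
                f"expected {self.config.image_channels} channels, "
                f"got {pixels.shape[1]}")
        patches = self._patchify(pixels)
        B, P, D = patches.shape
        if P != self.pos_embed.shape[0]:
            raise ValueError(
                f"image yields {P} patches but encoder was built for "
                f"{self.pos_embed.shape[0]} (config.image_hw)")
        x = Tensor(patches.reshape(B * P, D))
        x = self.stem(x).reshape(B, P, self.config.image_width)
        x = (x + self.pos_embed).reshape(B * P, self.config.image_width)
        # pre-activation residual trunk: no nonlinearity on the stem path,
        # ReLU lives inside the blocks, so the trunk carries a full linear
        # image of the input alongside learned nonlinear corrections
        x = self.stem_bn(x)
        for block in self.blocks:
            x = block(x)
        grid = x.reshape(B, P, self.config.image_width)
        # pooling belongs to the projection head; the penultimate
        # representation is the full last-stage feature map, flattened, so
        # downstream linear probes keep access to position-resolved signal
        pooled = cat([grid.mean(axis=1), grid.max(axis=1)], axis=1)
        emb = l2_normalize(self.head(pooled))
        penult = grid.reshape(B, P * self.config.image_width)
        return emb, penult


class StructureEncoder(Module):
    def __init__(self, config: EncoderConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        widths = [config.fp_bits, *config.structure_hidden]
        self.hidden = [Linear(widths[i], widths[i + 1], rng)
                       for i in range(len(widths) - 1)]
        self.norms = [BatchNorm1d(w) for w in config.structure_hidden] \
            if config.batch_norm else []
        self.head = Linear(config.structure_hidden[-1], config.embed_dim, rng)

    def forward(self, fingerprints: np.ndarray) -> tuple[Tensor, Tensor]:
        fingerprints = np.atleast_2d(np.asarray(fingerprints, dtype=np.float64))
        if fingerprints.shape[1] != self.config.fp_bits:
            raise ValueError(
                f"expected fingerprints of length {self.config.fp_bits}, "
                f"got {fingerprints.shape[1]}")
        x = Tensor(fingerprints)
        for i, layer in enumerate(self.hidden):
            x = layer(x)
            if self.config.batch_norm:
                x = self.norms[i](x)
            x = x.relu()
        emb = l2_normalize(self.head(x))
        return emb, x


class ContrastiveModel(Module):
    """Bundles the two encoders sharing one embedding space."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.image_encoder = ImageEncoder(config, seed=seed)
        self.structure_encoder = StructureEncoder(config, seed=seed + 1)


def _encode_chunked(encoder: Module, batch: np.ndarray, ids, chunk: int
                    ) -> tuple[EmbeddingMatrix, np.ndarray]:
    encoder.eval()
    embs, penults = [], []
    with no_grad():  # inference: no graph, flat memory
        for start in range(0, batch.shape[0], chunk):
            emb, penult = encoder(batch[start:start + chunk])
            embs.append(emb.data)
            penults.append(penult.data)
    vectors = np.concatenate(embs)
    n = vectors.shape[0]
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    return (EmbeddingMatrix(ids, vectors, normalized=True),
            np.concatenate(penults))


def image_encode(pixels: np.ndarray, encoder: ImageEncoder,
                 ids: list[str] | None = None, chunk: int = 256
                 ) -> tuple[EmbeddingMatrix, np.ndarray]:
    """Eval-mode encoding of an image batch to an EmbeddingMatrix plus the
    penultimate feature matrix (for linear probing)."""
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim == 3:
        pixels = pixels[None]
    return _encode_chunked(encoder, pixels, ids, chunk)


def structure_encode(fingerprints: np.ndarray, encoder: StructureEncoder,
                     ids: list[str] | None = None, chunk: int = 1024
                     ) -> tuple[EmbeddingMatrix, np.ndarray]:
    fingerprints = np.atleast_2d(np.asarray(fingerprints, dtype=np.float64))
    return _encode_chunked(encoder, fingerprints, ids, chunk)


def save_checkpoint(path, model: ContrastiveModel,
                    extra: dict | None = None) -> None:
    """Self-describing archive: config JSON plus every weight and buffer."""
    state = model.state_dict()
    meta = {"config": asdict(model.config), "extra": extra or {}}
    np.savez(Path(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> ContrastiveModel:
    with np.load(Path(path)) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = meta["config"]
    cfg["structure_hidden"] = tuple(cfg["structure_hidden"])
    cfg["image_hw"] = tuple(cfg["image_hw"])
    model = ContrastiveModel(EncoderConfig(**cfg))
    model.load_state_dict(state)
    return model
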