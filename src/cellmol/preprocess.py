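"""Image preprocessing: bit-depth conversion, normalization, crop policies,
and standardization of external feature tables.

The 16-to-8-bit conversion clips a tiny fraction of the hottest pixels per
channel (saturated debris and hot pixels dominate the upper tail of
fluorescence images) and linearly rescales the remaining range to 0..255.
Normalization statistics are computed on the training split only and applied
everywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "convert_16to8", "channel_stats", "normalize_images", "crop_policy",
    "standardize_feature_table", "DEFAULT_CLIP_FRACTION",
]

# fraction of highest-valued pixels removed during 16->8-bit conversion
DEFAULT_CLIP_FRACTION = 0.0028e-2


def convert_16to8(pixels: np.ndarray,
                  clip_fraction: float = DEFAULT_CLIP_FRACTION) -> np.ndarray:
    """Convert a (C, H, W) 16-bit image to 8-bit.

    Per channel, values above the (1 - clip_fraction) quantile are clipped
    to it, then the channel is linearly rescaled to [0, 255] and rounded.
    A zero-dynamic-range channel maps to full-scale 255 (shape-preserving
    convention for blank channels).
    """
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValueError("empty image")
    if not (0.0 <= clip_fraction < 1.0):
        raise ValueError("clip_fraction must be in [0, 1)")
    if pixels.ndim == 2:
        pixels = pixels[None]
    x = pixels.astype(np.float64)
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        ch = x[c]
        hi = np.quantile(ch, 1.0 - clip_fraction)
        lo = ch.min()
        ch = np.minimum(ch, hi)
        if hi == lo:
            out[c] = 255.0
        else:
            out[c] = (ch - lo) / (hi - lo) * 255.0
    return np.round(out).astype(np.uint8)


def channel_stats(images: list[np.ndarray] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and standard deviation over a stack of (C, H, W)
    images (the training split, per the normalization contract)."""
    stack = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    means = stack.mean(axis=(0, 2, 3))
    sds = stack.std(axis=(0, 2, 3))
    return means, sds


def normalize_images(pixels: np.ndarray, channel_means: np.ndarray,
                     channel_sds: np.ndarray) -> np.ndarray:
    """(x - mean) / sd per channel; accepts (C, H, W) or (N, C, H, W)."""
    pixels = np.asarray(pixels, dtype=np.float64)
    means = np.asarray(channel_means, dtype=np.float64)
    sds = np.asarray(channel_sds, dtype=np.float64)
    if np.any(sds == 0):
        raise ValueError("zero standard deviation channel; cannot normalize")
    shape = (-1, 1, 1)
    if pixels.ndim == 4:
        shape = (1, -1, 1, 1)
    return (pixels - means.reshape(shape)) / sds.reshape(shape)


def crop_policy(image: np.ndarray, mode: str, train: bool = False,
                rng: np.random.Generator | None = None,
                crop_size: int = 520, activity_size: int = 320) -> np.ndarray:
    """Crop (and for activity mode, rescale) a (C, H, W) image.

    retrieval: random (train) or centre (eval) ``crop_size`` square crop.
    activity: the same crop followed by rescaling to ``activity_size``.
    eval: alias for retrieval with a deterministic centre crop.
    """
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError("expected a (C, H, W) image")
    if mode not in ("retrieval", "activity", "eval"):
        raise ValueError(f"unknown crop mode: {mode}")
    C, H, W = image.shape
    if H < crop_size or W < crop_size:
        raise ValueError(
            f"image {H}x{W} smaller than crop size {crop_size}")
    if mode == "eval":
        train = False
    if train:
        rng = rng or np.random.default_rng()
        top = int(rng.integers(0, H - crop_size + 1))
        left = int(rng.integers(0, W - crop_size + 1))
    else:
        top = (H - crop_size) // 2
        left = (W - crop_size) // 2
    crop = image[:, top:top + crop_size, left:left + crop_size]
    if mode == "activity":
        zoom = activity_size / crop_size
        crop = ndimage.zoom(crop.astype(np.float64), (1.0, zoom, zoom),
                            order=1)
        # guard against off-by-one from spline zoom rounding
        crop = crop[:, :activity_size, :activity_size]
    return crop


def standardize_feature_table(table: pd.DataFrame,
                              train_ids: list[str]) -> pd.DataFrame:
    """Drop non-numeric and zero-variance columns, then standardize the rest
    by the training rows' mean and standard deviation.

    Mirrors the handling of externally computed morphological feature
    tables: degenerate descriptors (constant across all samples) and
    metadata strings carry no signal and break scaling.
    """
    numeric = table.select_dtypes(include=[np.number])
    sds_all = numeric.std(axis=0, ddof=0)
    kept = numeric.loc[:, sds_all > 0.0]
    if kept.shape[1] == 0:
        raise ValueError("all feature columns were degenerate")
    train = kept.loc[train_ids]
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = sd.replace(0.0, 1.0)  # constant-on-train columns pass through centred
    return (kept - mu) / sd
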