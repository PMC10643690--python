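"""Synthetic paired microscopy-image / fingerprint datasets.

The generator emulates the structure of a cell-painting-style screen: each
molecule has a latent phenotype vector; its binary fingerprint is a random
signed projection of that latent thresholded at zero, and each microscopy
view renders the latent as per-channel Gaussian blobs (centre and amplitude
affine in the latent) plus i.i.d. pixel noise.  Both modalities therefore
share a decodable latent signal whose strength is controlled by
``noise_sd``.  A single seed drives every random draw, so identical specs
produce bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .records import ImageRecord, MoleculeRecord

__all__ = [
    "SyntheticSpec", "SyntheticTruth", "generate_paired_dataset",
    "generate_label_matrix", "render_noiseless", "save_dataset",
]

_MAX16 = 65535


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic screen.

    ``noise_sd`` is the standard deviation of the per-pixel Gaussian noise
    on the [0, 1] intensity scale; 0 makes all views of a molecule
    identical, large values drive the image/fingerprint mutual information
    to zero.
    """

    n_molecules: int
    views_per_molecule: int = 4
    latent_dim: int = 16
    channels: int = 5
    height: int = 32
    width: int = 32
    fp_bits: int = 1024
    noise_sd: float = 0.3
    n_plates: int = 3
    n_moa_classes: int | None = None  # default: min(10, n_molecules)
    n_blobs_per_channel: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.views_per_molecule < 1:
            raise ValueError("views_per_molecule must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_moa_classes is None:
            object.__setattr__(self, "n_moa_classes",
                               min(10, self.n_molecules))
        if self.n_moa_classes > self.n_molecules:
            raise ValueError("n_moa_classes must not exceed n_molecules")
        if self.fp_bits < self.latent_dim:
            raise ValueError("fp_bits must be >= latent_dim")
        if min(self.latent_dim, self.channels, self.height, self.width,
               self.n_plates, self.n_blobs_per_channel) < 1:
            raise ValueError("all size fields must be positive")


@dataclass
class SyntheticTruth:
    """Generative parameters, kept for decoding oracles and label synthesis."""

    latents: np.ndarray        # (n_molecules, latent_dim)
    fp_projection: np.ndarray  # (fp_bits, latent_dim), entries +-1
    blob_readout: np.ndarray   # (channels, n_blobs, 3, latent_dim)
    moa_labels: np.ndarray     # (n_molecules,) cluster index of latent


def _make_truth(spec: SyntheticSpec, rng: np.random.Generator) -> SyntheticTruth:
    latents = rng.normal(0.0, 1.0, (spec.n_molecules, spec.latent_dim))
    fp_projection = rng.choice([-1.0, 1.0],
                               size=(spec.fp_bits, spec.latent_dim))
    # per channel/blob: rows map latent -> (amplitude, centre_x, centre_y)
    blob_readout = rng.normal(
        0.0, 1.0,
        (spec.channels, spec.n_blobs_per_channel, 3, spec.latent_dim))
    blob_readout /= np.sqrt(spec.latent_dim)
    if spec.n_moa_classes == spec.n_molecules:
        moa = np.arange(spec.n_molecules)
    else:
        km = KMeans(n_clusters=spec.n_moa_classes, n_init=4,
                    random_state=int(rng.integers(2 ** 31)))
        moa = km.fit_predict(latents)
    return SyntheticTruth(latents, fp_projection, blob_readout, moa)


def render_noiseless(spec: SyntheticSpec, truth: SyntheticTruth,
                     latent: np.ndarray) -> np.ndarray:
    """Deterministic (C, H, W) float image in [0, 1] for one latent vector.

    Blob amplitude and centre are affine readouts of the latent; centres are
    clipped to stay inside the field of view.
    """
    H, W = spec.height, spec.width
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    sigma = max(H, W) / 8.0
    img = np.full((spec.channels, H, W), 0.1)
    readout = truth.blob_readout @ latent  # (channels, n_blobs, 3)
    n_b = spec.n_blobs_per_channel
    for c in range(spec.channels):
        for b in range(n_b):
            amp, rx, ry = readout[c, b]
            # amplitude carries the bulk of the signal (affine in the
            # latent, hence linearly decodable); centre shifts stay small
            # so position coding perturbs rather than dominates
            amp = np.clip(0.42 + 0.3 * amp, 0.02, 0.88)
            bx = (b % 2 + 0.5) / 2.0          # blob home positions on a
            by = (b // 2 % 2 + 0.5) / 2.0     # 2x2 grid over the field
            cx = np.clip(W * (bx + 0.1 * rx), 0.05 * W, 0.95 * W)
            cy = np.clip(H * (by + 0.1 * ry), 0.05 * H, 0.95 * H)
            img[c] += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                                   / (2.0 * sigma ** 2))
    return np.clip(img, 0.0, 1.0)


def generate_paired_dataset(
    spec: SyntheticSpec,
) -> tuple[list[ImageRecord], list[MoleculeRecord], pd.DataFrame, SyntheticTruth]:
    """Generate matched image/molecule pairs.

    Returns image records (16-bit pixels), molecule records with
    deterministic thresholded-projection fingerprints, a pairing table
    (image_id, view_index, plate_id, molecule_id, moa_class) and the
    generative truth for oracles.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _make_truth(spec, rng)

    fp_real = truth.latents @ truth.fp_projection.T       # (n_mol, fp_bits)
    fps = (fp_real >= 0.0).astype(np.uint8)

    molecules, images, rows = [], [], []
    for m in range(spec.n_molecules):
        mol_id = f"mol{m:05d}"
        rec = MoleculeRecord(molecule_id=mol_id, smiles=f"SYN-{m:05d}")
        if spec.fp_bits == 1024:
            rec.fp_morgan = fps[m]
        rec.fp_custom = fps[m]  # always available, any fp_bits
        molecules.append(rec)

        clean = render_noiseless(spec, truth, truth.latents[m])
        for v in range(spec.views_per_molecule):
            noisy = clean
            if spec.noise_sd > 0:
                noisy = clean + rng.normal(0.0, spec.noise_sd, clean.shape)
            pixels = np.round(np.clip(noisy, 0.0, 1.0) * _MAX16).astype(np.uint16)
            # plate rotates with the view so same-molecule views span plates
            # while same-molecule/same-plate collisions occur when
            # views_per_molecule > n_plates
            plate = f"plate{(m + v) % spec.n_plates}"
            image_id = f"{mol_id}_v{v}"
            images.append(ImageRecord(
                image_id=image_id, pixels=pixels, bit_depth=16,
                plate_id=plate, well_id=f"well{m % 384:03d}", view_index=v,
                molecule_id=mol_id))
            rows.append({"image_id": image_id, "view_index": v,
                         "plate_id": plate, "molecule_id": mol_id,
                         "moa_class": int(truth.moa_labels[m])})
    pairing = pd.DataFrame(rows)
    return images, molecules, pairing, truth


def generate_label_matrix(
    molecules: list[MoleculeRecord],
    latents: np.ndarray,
    n_tasks: int,
    sparsity: float = 1.0,
    seed: int = 0,
    flip_prob: float = 0.1,
) -> pd.DataFrame:
    """Sparse binary activity labels derived from molecule latents.

    Each task is the sign of a random linear readout of the latent, with
    ``flip_prob`` label noise; entries are observed with probability
    ``sparsity`` (NaN marks missing), emulating a sparse assay label matrix.
    """
    if n_tasks < 1:
        raise ValueError("n_tasks must be >= 1")
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must be in (0, 1]")
    latents = np.asarray(latents)
    if latents.shape[0] != len(molecules):
        raise ValueError("latents rows must align with molecules")
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 1.0, (n_tasks, latents.shape[1]))
    labels = (latents @ w.T >= 0.0).astype(float)
    flips = rng.random(labels.shape) < flip_prob
    labels[flips] = 1.0 - labels[flips]
    if sparsity < 1.0:
        labels[rng.random(labels.shape) >= sparsity] = np.nan
    return pd.DataFrame(labels,
                        index=[m.molecule_id for m in molecules],
                        columns=[f"task{t:03d}" for t in range(n_tasks)])


def save_dataset(out_dir, images: list[ImageRecord],
                 molecules: list[MoleculeRecord], pairing: pd.DataFrame,
                 labels: pd.DataFrame | None = None,
                 image_format: str = "npz") -> None:
    """Write a generated dataset: images as per-view NPZ or multi-page TIFF,
    molecules as CSV (id, smiles placeholder, fingerprint hex), pairing and
    labels as CSV."""
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for rec in images:
        if image_format == "npz":
            np.savez(img_dir / f"{rec.image_id}.npz",
                     # channels-last at the file boundary
                     pixels=np.moveaxis(rec.pixels, 0, -1),
                     plate_id=rec.plate_id, well_id=rec.well_id,
                     view_index=rec.view_index,
                     molecule_id=rec.molecule_id or "")
        elif image_format == "tiff":
            import tifffile
            tifffile.imwrite(img_dir / f"{rec.image_id}.tiff", rec.pixels,
                             photometric="minisblack",
                             metadata={"plate_id": rec.plate_id,
                                       "molecule_id": rec.molecule_id})
        else:
            raise ValueError(f"unknown image format: {image_format}")
    mol_rows = []
    for m in molecules:
        fp = m.fp_morgan if m.fp_morgan is not None else getattr(m, "fp_custom", None)
        mol_rows.append({
            "molecule_id": m.molecule_id, "smiles": m.smiles,
            "fingerprint_hex": "" if fp is None else np.packbits(fp).tobytes().hex(),
            "fingerprint_bits": 0 if fp is None else int(fp.size),
        })
    pd.DataFrame(mol_rows).to_csv(out / "molecules.csv", index=False)
    pairing.to_csv(out / "pairing.csv", index=False)
    if labels is not None:
        labels.to_csv(out / "labels.csv")
    manifest = {"n_images": len(images), "n_molecules": len(molecules),
                "image_format": image_format}
    (out / "dataset.json").write_text(json.dumps(manifest, indent=2))


def spec_to_dict(spec: SyntheticSpec) -> dict:
    return asdict(spec)
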