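"""Core record types shared across the package.

An :class:`ImageRecord` is one microscopy view (channels-first pixel tensor
plus plate/well/view/molecule metadata); a :class:`MoleculeRecord` carries a
molecule's SMILES and fingerprint vectors; an :class:`EmbeddingMatrix` holds
N unit-norm d-dimensional embeddings aligned with record ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageRecord", "MoleculeRecord", "EmbeddingMatrix", "SplitAssignment"]


@dataclass
class ImageRecord:
    image_id: str
    pixels: np.ndarray  # (C, H, W)
    bit_depth: int = 16
    plate_id: str = ""
    well_id: str = ""
    view_index: int = 0
    molecule_id: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (C, H, W) tensor")
        if self.pixels.shape[0] < 1:
            raise ValueError("at least one channel required")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if np.issubdtype(self.pixels.dtype, np.integer):
            if self.pixels.max(initial=0) >= 2 ** self.bit_depth:
                raise ValueError(
                    f"pixel values exceed declared {self.bit_depth}-bit depth")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class MoleculeRecord:
    molecule_id: str
    smiles: str = ""
    fp_morgan: np.ndarray | None = None     # {0,1}^1024
    fp_combined: np.ndarray | None = None   # {0,1}^8192
    fp_custom: np.ndarray | None = None     # {0,1}^k, unconstrained length
    scaffold_key: str = ""

    def __post_init__(self):
        for name, fp, length in (("fp_morgan", self.fp_morgan, 1024),
                                 ("fp_combined", self.fp_combined, 8192)):
            if fp is None:
                continue
            fp = np.asarray(fp)
            if fp.shape != (length,):
                raise ValueError(f"{name} must have length {length}")
            if not np.isin(fp, (0, 1)).all():
                raise ValueError(f"{name} must be 0/1-valued")
            setattr(self, name, fp.astype(np.uint8))


@dataclass
class EmbeddingMatrix:
    ids: list[str]
    vectors: np.ndarray  # (N, d)
    normalized: bool = True

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be an (N, d) matrix")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("ids and vectors row count disagree")
        if self.normalized:
            norms = np.linalg.norm(self.vectors, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normalized=True but rows are not unit-norm")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class SplitAssignment:
    """Molecule-level train/valid/test assignment.

    Every image of a molecule inherits the molecule's split, so no molecular
    structure leaks across sets.
    """

    assignment: dict[str, str] = field(default_factory=dict)
    mode: str = "random_by_molecule"

    SETS = ("train", "valid", "test")

    def __post_init__(self):
        bad = set(self.assignment.values()) - set(self.SETS)
        if bad:
            raise ValueError(f"unknown split labels: {sorted(bad)}")

    def __getitem__(self, molecule_id: str) -> str:
        return self.assignment[molecule_id]

    def members(self, split: str) -> list[str]:
        return [m for m, s in self.assignment.items() if s == split]

    def split_of_image(self, record) -> str:
        if record.molecule_id is None:
            raise KeyError(f"image {record.image_id} has no molecule id")
        return self.assignment[record.molecule_id]
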