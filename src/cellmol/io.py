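"""Reading and writing the standard file formats around the pipeline:
multi-page TIFF and NPZ images, CSV/SDF molecule tables, label matrices,
split manifests and embedding exports.

Pixel tensors are channels-first in memory and channels-last at the file
boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .records import EmbeddingMatrix, ImageRecord, MoleculeRecord, SplitAssignment

__all__ = [
    "read_image_npz", "read_image_tiff", "write_image_npz",
    "read_molecules_csv", "read_molecules_sdf", "write_fingerprint_table",
    "read_label_matrix", "write_split_manifest", "read_split_manifest",
    "write_embeddings", "read_embeddings", "load_dataset",
]


def read_image_npz(path, image_id: str | None = None) -> ImageRecord:
    path = Path(path)
    with np.load(path, allow_pickle=False) as f:
        pixels = np.moveaxis(f["pixels"], -1, 0)  # channels-last on disk
        meta = {k: f[k][()] for k in f.files if k != "pixels"}
    bit_depth = 16 if pixels.dtype == np.uint16 else 8
    return ImageRecord(
        image_id=image_id or path.stem, pixels=pixels, bit_depth=bit_depth,
        plate_id=str(meta.get("plate_id", "")),
        well_id=str(meta.get("well_id", "")),
        view_index=int(meta.get("view_index", 0)),
        molecule_id=str(meta.get("molecule_id", "")) or None)


def read_image_tiff(path, image_id: str | None = None, **metadata) -> ImageRecord:
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None]
    bit_depth = 16 if pixels.dtype == np.uint16 else 8
    return ImageRecord(image_id=image_id or path.stem, pixels=pixels,
                       bit_depth=bit_depth, **metadata)


def write_image_npz(path, record: ImageRecord) -> None:
    np.savez(Path(path), pixels=np.moveaxis(record.pixels, 0, -1),
             plate_id=record.plate_id, well_id=record.well_id,
             view_index=record.view_index,
             molecule_id=record.molecule_id or "")


def read_molecules_csv(path, smiles_col: str = "smiles",
                       id_col: str = "molecule_id") -> list[MoleculeRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        rec = MoleculeRecord(molecule_id=str(row[id_col]),
                             smiles=str(row.get(smiles_col, "")))
        if "fingerprint_hex" in df.columns and isinstance(row["fingerprint_hex"], str) \
                and row["fingerprint_hex"]:
            nbits = int(row.get("fingerprint_bits", 0))
            bits = np.unpackbits(np.frombuffer(
                bytes.fromhex(row["fingerprint_hex"]), dtype=np.uint8))
            rec.fp_custom = bits[:nbits] if nbits else bits
        records.append(rec)
    return records


def read_molecules_sdf(path) -> list[MoleculeRecord]:
    from rdkit import Chem
    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf{i:05d}"
        records.append(MoleculeRecord(molecule_id=mol_id,
                                      smiles=Chem.MolToSmiles(mol)))
    return records


def write_fingerprint_table(path, molecules: list[MoleculeRecord],
                            which: str = "fp_morgan") -> None:
    rows = []
    for m in molecules:
        fp = getattr(m, which)
        if fp is None:
            continue
        rows.append({"molecule_id": m.molecule_id, "smiles": m.smiles,
                     "fingerprint_hex": np.packbits(fp).tobytes().hex(),
                     "fingerprint_bits": int(fp.size)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_label_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_split_manifest(path, split: SplitAssignment) -> None:
    Path(path).write_text(json.dumps(
        {"mode": split.mode, "assignment": split.assignment}, indent=2))


def read_split_manifest(path) -> SplitAssignment:
    data = json.loads(Path(path).read_text())
    return SplitAssignment(data["assignment"], mode=data["mode"])


def write_embeddings(path, embs: EmbeddingMatrix) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.DataFrame(embs.vectors,
                          index=pd.Index(embs.ids, name="id"))
        df.to_csv(path)
    else:
        np.savez(path, ids=np.array(embs.ids), vectors=embs.vectors,
                 normalized=embs.normalized)


def read_embeddings(path) -> EmbeddingMatrix:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, index_col=0)
        vec = df.to_numpy(dtype=np.float64)
        norms = np.linalg.norm(vec, axis=1)
        return EmbeddingMatrix(list(df.index.astype(str)), vec,
                               normalized=bool(np.allclose(norms, 1.0, atol=1e-6)))
    with np.load(path, allow_pickle=False) as f:
        return EmbeddingMatrix(list(f["ids"].astype(str)), f["vectors"],
                               normalized=bool(f["normalized"][()]))


def load_dataset(root) -> tuple[list[ImageRecord], list[MoleculeRecord],
                                pd.DataFrame, pd.DataFrame | None]:
    """Load a dataset written by :func:`cellmol.synthetic.save_dataset`."""
    root = Path(root)
    pairing = pd.read_csv(root / "pairing.csv")
    molecules = read_molecules_csv(root / "molecules.csv")
    images = []
    img_dir = root / "images"
    for row in pairing.itertuples():
        npz = img_dir / f"{row.image_id}.npz"
        tiff = img_dir / f"{row.image_id}.tiff"
        if npz.exists():
            images.append(read_image_npz(npz, image_id=row.image_id))
        else:
            images.append(read_image_tiff(
                tiff, image_id=row.image_id, plate_id=row.plate_id,
                view_index=int(row.view_index), molecule_id=row.molecule_id))
    labels = None
    if (root / "labels.csv").exists():
        labels = read_label_matrix(root / "labels.csv")
    return images, molecules, pairing, labels
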