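"""Molecule featurization: Morgan fingerprints and the 8192-bit combined
(Morgan max RDKit-count) fingerprint.

SMILES are canonicalized by the toolkit's sanitizer before hashing, so
kekulization variants of one molecule yield identical fingerprints.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = ["parse_smiles", "morgan_fingerprint", "combined_fingerprint",
           "bemis_murcko_scaffold"]


def parse_smiles(smiles: str, identifier: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = identifier or smiles
        raise ValueError(f"unparseable SMILES: {who!r}")
    return mol


def morgan_fingerprint(smiles: str, radius: int = 3, n_bits: int = 1024,
                       use_chirality: bool = True,
                       identifier: str | None = None) -> np.ndarray:
    """Binary circular (Morgan) fingerprint; radius 3, 1024 bits, chirality
    included by default."""
    mol = parse_smiles(smiles, identifier)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits, includeChirality=use_chirality)
    fp = gen.GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


def _rdkit_count_fingerprint(mol: Chem.Mol, n_bits: int) -> np.ndarray:
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    counts = gen.GetCountFingerprintAsNumPy(mol)
    return counts


def combined_fingerprint(smiles: str, n_bits: int = 8192,
                         radius: int = 3, use_chirality: bool = True,
                         identifier: str | None = None) -> np.ndarray:
    """Element-wise max of a Morgan fingerprint folded to ``n_bits`` and an
    RDKit count-based fingerprint folded to ``n_bits`` binarized at
    count >= 1.  Both sources share one hash space of length ``n_bits``."""
    mol = parse_smiles(smiles, identifier)
    morgan = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits,
        includeChirality=use_chirality).GetFingerprintAsNumPy(mol)
    rdk = (_rdkit_count_fingerprint(mol, n_bits) >= 1).astype(np.uint8)
    return np.maximum(morgan.astype(np.uint8), rdk)


def bemis_murcko_scaffold(smiles: str, identifier: str | None = None) -> str:
    """Canonical SMILES of the Bemis-Murcko scaffold, used as the grouping
    key for scaffold splits; empty string for acyclic molecules."""
    from rdkit.Chem.Scaffolds import MurckoScaffold
    mol = parse_smiles(smiles, identifier)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)
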