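"""Morgan (circular) fingerprints and Tanimoto similarity helpers.

Two fingerprint flavours are used throughout the package:

* radius 2 — similarity work: neighbor counts, nearest-neighbor spatial
  statistics and ML features;
* radius 3 — Taylor-Butina clustering of the dataset.

Both are hashed binary fingerprints (2048 bits by default).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "mol_from_smiles",
    "morgan_fingerprints",
    "tanimoto_matrix",
    "fingerprint_array",
]


def mol_from_smiles(smiles: str, *, context: str = "") -> Chem.Mol:
    """Parse a SMILES string, raising ``ValueError`` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() < 1:
        where = f" ({context})" if context else ""
        raise ValueError(f"unparsable or empty SMILES{where}: {smiles!r}")
    return mol


def morgan_fingerprints(
    smiles: Sequence[str], *, radius: int = 2, n_bits: int = 2048
) -> list:
    """Hashed binary Morgan fingerprints (RDKit bit vectors) for a SMILES list."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps = []
    for i, smi in enumerate(smiles):
        mol = mol_from_smiles(smi, context=f"record #{i}")
        fps.append(gen.GetFingerprint(mol))
    return fps


def tanimoto_matrix(fps_a: Sequence, fps_b: Sequence | None = None) -> np.ndarray:
    """Pairwise Tanimoto similarity matrix.

    With one argument returns the symmetric ``len(fps_a) x len(fps_a)`` matrix;
    with two, the rectangular ``len(fps_a) x len(fps_b)`` matrix.
    """
    if fps_b is None:
        n = len(fps_a)
        sim = np.ones((n, n))
        for i in range(1, n):
            row = DataStructs.BulkTanimotoSimilarity(fps_a[i], list(fps_a[:i]))
            sim[i, :i] = row
            sim[:i, i] = row
        return sim
    sim = np.empty((len(fps_a), len(fps_b)))
    fps_b = list(fps_b)
    for i, fp in enumerate(fps_a):
        sim[i] = DataStructs.BulkTanimotoSimilarity(fp, fps_b)
    return sim


def fingerprint_array(smiles: Sequence[str], *, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Fingerprints as a dense uint8 matrix (rows = molecules), for ML features."""
    fps = morgan_fingerprints(smiles, radius=radius, n_bits=n_bits)
    out = np.zeros((len(fps), n_bits), dtype=np.uint8)
    for i, fp in enumerate(fps):
        DataStructs.ConvertToNumpyArray(fp, arr := np.zeros(n_bits, dtype=np.int8))
        out[i] = arr
    return out
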