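"""Synthetic-accessibility (SA) score, 1 (easy) to 10 (hard).

The Ertl-Schuffenhauer score combines a fragment-frequency contribution
(common substructures, as observed in large compound catalogues, are assumed
easy to make) with complexity penalties for molecule size, stereocentres,
spiro and bridgehead atoms and macrocycles, plus a symmetry correction based
on fingerprint density. The fragment-frequency table is loaded from the data
file distributed with RDKit's contributed SA-score implementation, so the two
implementations share the published contribution values and can be
cross-validated against each other.
"""

from __future__ import annotations

import gzip
import math
import os.path
import pickle
from functools import lru_cache

from rdkit import Chem
from rdkit.Chem import RDConfig, rdFingerprintGenerator, rdMolDescriptors

from .fingerprints import mol_from_smiles

__all__ = ["sa_score", "sa_score_mol"]

_UNKNOWN_FRAGMENT_SCORE = -4.0
_RAW_MIN, _RAW_MAX = -4.0, 2.5

_fragment_fp_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2)


@lru_cache(maxsize=1)
def _fragment_scores() -> dict[int, float]:
    path = os.path.join(RDConfig.RDContribDir, "SA_Score", "fpscores.pkl.gz")
    with gzip.open(path) as fh:
        rows = pickle.load(fh)
    # each row: [score, bit_id, bit_id, ...]
    return {bit: float(row[0]) for row in rows for bit in row[1:]}


def sa_score_mol(mol: Chem.Mol) -> float:
    """SA score of an RDKit molecule."""
    scores = _fragment_scores()

    counts = _fragment_fp_gen.GetSparseCountFingerprint(mol).GetNonzeroElements()
    n_fragments = sum(counts.values())
    fragment_score = (
        sum(scores.get(bit, _UNKNOWN_FRAGMENT_SCORE) * c for bit, c in counts.items())
        / n_fragments
    )

    n_atoms = mol.GetNumAtoms()
    n_chiral = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True))
    n_spiro = rdMolDescriptors.CalcNumSpiroAtoms(mol)
    n_bridgehead = rdMolDescriptors.CalcNumBridgeheadAtoms(mol)
    has_macrocycle = any(len(ring) > 8 for ring in mol.GetRingInfo().AtomRings())

    complexity_penalty = (
        (n_atoms**1.005 - n_atoms)
        + math.log10(n_chiral + 1)
        + math.log10(n_spiro + 1)
        + math.log10(n_bridgehead + 1)
        # a single log10(2) penalty regardless of macrocycle count
        + (math.log10(2) if has_macrocycle else 0.0)
    )

    # symmetry correction: few distinct fragments relative to size = easier
    symmetry_bonus = 0.0
    if n_atoms > len(counts):
        symmetry_bonus = 0.5 * math.log(n_atoms / len(counts))

    raw = fragment_score - complexity_penalty + symmetry_bonus

    # map the raw scale onto [1, 10], compressing the hard end smoothly
    score = 11.0 - (raw - _RAW_MIN + 1.0) / (_RAW_MAX - _RAW_MIN) * 9.0
    if score > 8.0:
        score = 8.0 + math.log(score + 1.0 - 9.0)
    return min(10.0, max(1.0, score))


def sa_score(smiles: str) -> float:
    """SA score of a molecule given as SMILES."""
    return sa_score_mol(mol_from_smiles(smiles))
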