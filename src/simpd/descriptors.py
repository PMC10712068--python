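"""Molecular descriptors and the train/test distribution-shift screen.

Four descriptors drive the simulated-time-split objectives, chosen because
their distributions shift consistently between the early and late compounds
of lead-optimization projects:

* SA score (synthetic accessibility, increases over a project),
* heavy atom count (increases),
* TPSA (topological polar surface area, increases),
* benzene rings per 1000 heavy atoms (decreases).

The module also carries the machinery that identifies such descriptors in the
first place: a full descriptor panel in raw and size-normalized (x 1000 /
heavy atoms) form, a Brunner-Munzel shift test per descriptor, consistency
ranking across datasets and Spearman-correlation pruning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import Descriptors, Fragments
from scipy import stats

from .data import AssayDataset, Split
from .fingerprints import mol_from_smiles
from .sascore import sa_score_mol

__all__ = [
    "SIMPD_DESCRIPTORS",
    "heavy_atom_count",
    "tpsa",
    "fr_benzene",
    "fr_benzene_per_1000_heavy",
    "simpd_descriptor_table",
    "descriptor_panel",
    "ShiftScreenResult",
    "descriptor_shift_screen",
    "rank_and_prune",
]

#: Names of the four split-objective descriptors, in objective order.
SIMPD_DESCRIPTORS = ("SA_Score", "HeavyAtomCount", "TPSA", "fr_benzene_per_1000_heavy")


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms."""
    return mol_from_smiles(smiles).GetNumHeavyAtoms()


def tpsa(smiles: str) -> float:
    """Ertl topological polar surface area (A^2), from fragment contributions."""
    return Descriptors.TPSA(mol_from_smiles(smiles))


def fr_benzene(smiles: str) -> int:
    """Number of benzene rings."""
    return Fragments.fr_benzene(mol_from_smiles(smiles))


def fr_benzene_per_1000_heavy(smiles: str) -> float:
    """Benzene-ring count scaled to a per-1000-heavy-atoms rate.

    The x1000/heavy-atoms scaling makes the descriptor size-intensive and
    puts typical drug-like values in the tens (e.g. toluene: 1000/7).
    """
    mol = mol_from_smiles(smiles)
    return Fragments.fr_benzene(mol) * 1000.0 / mol.GetNumHeavyAtoms()


def simpd_descriptor_table(smiles: Sequence[str], ids: Sequence[str] | None = None) -> pd.DataFrame:
    """The four objective descriptors for a list of molecules."""
    rows = []
    for smi in smiles:
        mol = mol_from_smiles(smi)
        ha = mol.GetNumHeavyAtoms()
        rows.append(
            {
                "SA_Score": sa_score_mol(mol),
                "HeavyAtomCount": float(ha),
                "TPSA": Descriptors.TPSA(mol),
                "fr_benzene_per_1000_heavy": Fragments.fr_benzene(mol) * 1000.0 / ha,
            }
        )
    return pd.DataFrame(rows, index=list(ids) if ids is not None else None)


def descriptor_panel(
    smiles: Sequence[str],
    ids: Sequence[str] | None = None,
    *,
    normalized: bool = True,
    descriptors: Sequence[tuple[str, callable]] | None = None,
) -> pd.DataFrame:
    """Full descriptor panel: every standard RDKit descriptor, and optionally a
    normalized (x 1000 / heavy atoms) variant of each.

    A custom ``descriptors`` list of ``(name, mol -> float)`` pairs may be
    supplied to replace the default panel. The four objective descriptors are
    always appended if missing.
    """
    desc_list = list(descriptors) if descriptors is not None else list(Descriptors.descList)
    mols = [mol_from_smiles(s) for s in smiles]
    data: dict[str, list[float]] = {}
    for name, fn in desc_list:
        data[name] = [float(fn(m)) for m in mols]
    if normalized:
        ha = np.array([m.GetNumHeavyAtoms() for m in mols], dtype=float)
        for name, _ in desc_list:
            data[f"{name}_per_1000_heavy"] = list(np.asarray(data[name]) * 1000.0 / ha)
    frame = pd.DataFrame(data, index=list(ids) if ids is not None else None)
    extra = simpd_descriptor_table(smiles, ids)
    for col in extra.columns:
        if col not in frame.columns:
            frame[col] = extra[col].values
    return frame


@dataclass(frozen=True)
class ShiftScreenResult:
    """Per-descriptor outcome of the train-vs-test distribution-shift screen."""

    descriptor: str
    p_value: float
    shift_sign: int  # sign of median(test) - median(train)
    median_frac_change: float
    significant: bool
    degenerate: bool = False  # constant on both sides; test undefined


def _screen_one(name: str, train: np.ndarray, test: np.ndarray, alpha: float) -> ShiftScreenResult:
    d_median = float(np.median(test) - np.median(train))
    sign = int(np.sign(d_median))
    m_train = float(np.median(train))
    frac_change = abs(d_median) / abs(m_train) if m_train != 0 else np.nan
    if np.ptp(train) == 0 and np.ptp(test) == 0:
        # Brunner-Munzel is undefined for two constant samples
        return ShiftScreenResult(name, np.nan, sign, frac_change, False, True)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = stats.brunnermunzel(train, test, distribution="t")
    p = float(stat.pvalue)
    return ShiftScreenResult(name, p, sign, frac_change, bool(p < alpha))


def descriptor_shift_screen(
    panel: pd.DataFrame, split: Split, dataset: AssayDataset, *, alpha: float = 0.01
) -> list[ShiftScreenResult]:
    """Brunner-Munzel test of each descriptor's train-vs-test distribution.

    The Brunner-Munzel test compares stochastic dominance between the two
    sides without assuming equal variances; descriptors with a two-sided
    p >= ``alpha`` are flagged not significant.
    """
    train_idx = [panel.index.get_loc(i) for i in split.train_ids]
    test_idx = [panel.index.get_loc(i) for i in split.test_ids]
    if len(train_idx) < 2 or len(test_idx) < 2:
        raise ValueError("need at least 2 compounds on each side of the split")
    results = []
    for name in panel.columns:
        col = panel[name].to_numpy(dtype=float)
        results.append(_screen_one(name, col[train_idx], col[test_idx], alpha))
    return results


def rank_and_prune(
    results_per_dataset: Sequence[Sequence[ShiftScreenResult]],
    correlations: pd.DataFrame,
    *,
    correlation_cut: float = 0.8,
    min_datasets: int = 1,
) -> pd.DataFrame:
    """Rank descriptors by shift-direction consistency and prune correlated ones.

    For each descriptor, over the datasets where its shift was significant,
    compute the fraction showing the modal sign (``frac_consistent``) and the
    median fractional change. Rank by ``frac_consistent`` (descending, ties by
    dataset count then name) and greedily keep descriptors whose absolute
    Spearman correlation with every already-kept descriptor is <=
    ``correlation_cut``.

    ``correlations`` is a square descriptor-by-descriptor Spearman matrix,
    e.g. ``panel.corr(method="spearman")`` on a pooled panel.
    """
    by_name: dict[str, list[ShiftScreenResult]] = {}
    for results in results_per_dataset:
        for r in results:
            by_name.setdefault(r.descriptor, []).append(r)

    rows = []
    for name, rs in by_name.items():
        sig = [r for r in rs if r.significant and r.shift_sign != 0]
        if len(sig) < min_datasets:
            continue
        signs = np.array([r.shift_sign for r in sig])
        n_pos = int((signs > 0).sum())
        modal_sign = 1 if n_pos * 2 >= len(signs) else -1
        frac = max(n_pos, len(signs) - n_pos) / len(signs)
        rows.append(
            {
                "descriptor": name,
                "sign": modal_sign,
                "frac_consistent": frac,
                "median_frac_change": float(
                    np.nanmedian([r.median_frac_change for r in sig])
                ),
                "n_datasets": len(sig),
            }
        )
    ranked = pd.DataFrame(rows).sort_values(
        ["frac_consistent", "n_datasets", "descriptor"],
        ascending=[False, False, True],
    )

    kept: list[str] = []
    selected = []
    for _, row in ranked.iterrows():
        name = row["descriptor"]
        if any(
            name in correlations.index
            and other in correlations.columns
            and abs(correlations.loc[name, other]) > correlation_cut
            for other in kept
        ):
            continue
        kept.append(name)
        selected.append(row)
    return pd.DataFrame(selected).reset_index(drop=True)
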