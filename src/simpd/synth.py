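"""Synthetic lead-optimization-series datasets for testing and benchmarking.

The generator emulates the structure of medicinal-chemistry project data:

* a handful of chemical series, each built on a shared ring-system scaffold
  (so the dataset clusters under fingerprint similarity);
* registration-date ordering with strictly increasing dates;
* an upward potency (pAC50) trend along the registration order, plus noise;
* gradual drift in the four split-objective descriptors: later compounds
  carry more and more-polar substituents (higher SA score, heavy-atom count
  and TPSA) while plain benzene rings become rarer.

Compounds are assembled as SMILES strings: a scaffold template with a slot
that receives a chain of substituent fragments drawn from polarity-ordered
pools whose rates ramp along the registration index. Every emitted SMILES is
validated with RDKit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AssayDataset, CompoundRecord, DEFAULT_THRESHOLD, required_test_size
from .fingerprints import mol_from_smiles

__all__ = ["SeriesConfig", "generate", "reference_toy_dataset"]

# ~20 common drug-like ring-system scaffolds; "{}" receives the substituent
# chain. All chosen to stay parsable with any fragment chain appended.
SCAFFOLDS = [
    "c1ccc2c(c1)oc({})c2",           # benzofuran
    "c1ccc(-c2nc({})cs2)cc1",        # phenyl-thiazole
    "c1ccc2nc({})ccc2c1",            # quinoline
    "c1ccc2c(c1)cc({})o2",           # benzofuran isomer
    "c1ccc2c(c1)nc({})[nH]2",        # benzimidazole
    "c1ccc2nc({})ncc2c1",            # quinazoline
    "c1ccc(-c2cc({})no2)cc1",        # phenyl-isoxazole
    "c1ccc2c(c1)sc({})c2",           # benzothiophene
    "c1ccc2[nH]c({})cc2c1",          # indole
    "c1cc({})cc2ccccc12",            # naphthalene
    "c1ccc(-n2cc({})cn2)cc1",        # phenyl-pyrazole
    "c1cnc2[nH]c({})cc2c1",          # azaindole
    "c1cc2cc({})ccc2[nH]1",          # indole isomer
    "c1ccc2c(c1)ncc({})n2",          # quinoxaline-like
    "c1cc({})oc1",                   # furan
    "c1cc({})cs1",                   # thiophene
    "c1cc({})c[nH]1",                # pyrrole
    "c1ccc({})nc1",                  # pyridine
    "c1ccc({})cc1",                  # benzene
    "c1cnc({})cn1",                  # pyrimidine
]

# series-characteristic motifs: each series prepends one of these to every
# substituent chain, so series members share a large common substructure (as
# real lead-optimization series do). All motifs share one composition (a
# secondary amide, one azine nitrogen, ten heavy atoms) and differ only in
# connectivity, so which series dominates a time period does not bias the
# descriptor drift; the scaffold/motif pairing order was chosen so scaffold
# properties show no trend across the series sequence either
SERIES_MOTIFS = [
    "CC(=O)Nc5ccncc5",
    "C(=O)NCc5cnccc5",
    "C(=O)Nc5ncccc5C",
    "C(=O)NCc5ccncc5",
    "CC(=O)Nc5cnccc5",
    "C(=O)NCc5cccnc5",
    "CC(=O)Nc5ncccc5",
    "C(=O)Nc5cccnc5C",
    "C(=O)Nc5ccncc5C",
    "C(=O)Nc5cnccc5C",
]

# substituent fragment pools; within each pool the entries alternate between
# property-heavy and property-light so any contiguous stretch of the
# deterministic cycle keeps a near-constant property profile
APOLAR_FRAGMENTS = ["CCCC", "C", "CC(C)C", "CC", "C(C)C", "CCC"]
PHENYL_FRAGMENTS = ["c5ccccc5", "CCc5ccccc5", "Cc5ccccc5"]
POLAR_FRAGMENTS = [
    "S(=O)(=O)N", "CO", "C(=O)N", "CN", "C(=O)NCCO", "CCO", "C(=O)O",
    "CCN", "OCCO", "C(=O)NC", "S(=O)(=O)C", "CNC(=O)C", "CC(=O)N",
]
# complexity fragments: stereocentres, small rings and branching raise the
# synthetic-accessibility score with little polarity or aromaticity coupling
COMPLEX_FRAGMENTS = [
    "[C@@H](C)CC", "[C@H](CC)C(C)C", "C5C[C@H](C)C5", "[C@@H](C)C5CC5",
    "C(C(F)(F)F)", "[C@H](C)CCC",
]


# Maps the configured (SA, heavy-atom, TPSA, benzene-rate) median-drift
# targets to the four fragment-pool rate slopes (polar, phenyl, complex,
# apolar). This is the inverse of the drift-response matrix measured on
# default-size datasets during development; it folds in the couplings
# between pools (e.g. polar fragments also add heavy atoms and raise the
# SA score).
_SLOPE_CALIBRATION = np.array(
    [
        [-0.053035, 0.044168, 0.056643, -0.006880],
        [-0.032231, 0.083307, 0.002758, 0.073356],
        [4.931678, -0.260602, 0.006217, 0.054054],
        [-9.112148, 0.936370, -0.081498, -0.242821],
    ]
)


def _slopes_from_targets(drift) -> np.ndarray:
    """Pool-rate slopes (polar, phenyl, complex, apolar) for drift targets."""
    return _SLOPE_CALIBRATION @ np.asarray(drift, dtype=float)


@dataclass(frozen=True)
class SeriesConfig:
    """Generator settings.

    ``descriptor_drift`` gives the target test-minus-train median deltas for
    (SA score, heavy atoms, TPSA, benzene rings per 1000 heavy atoms) under
    an 80/20 temporal split; defaults are the drifts observed in real project
    data that the split objectives target. ``active_fraction_targets`` fixes
    the fraction of actives in the early-80 % and late-20 % portions.
    """

    n_series: int = 8
    compounds_per_series: int = 63
    descriptor_drift: tuple[float, float, float, float] = (0.28, 3.1, 13.2, -8.8)
    activity_trend: float = 2.0  # pAC50 gain from first to last registration
    activity_noise_sd: float = 0.8
    activity_base: float = 5.6
    series_effect_sd: float = 0.6
    fragment_effect_sd: float = 0.4
    interaction_sd: float = 0.5
    epistasis_sd: float = 0.35
    series_overlap: float = 0.22  # sd of each series' activity window, in project-time units
    active_fraction_targets: tuple[float, float] | None = None
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def __post_init__(self):
        if self.n_series * self.compounds_per_series < 50:
            raise ValueError("need at least 50 compounds in total")
        if self.activity_noise_sd <= 0:
            raise ValueError("activity noise sd must be positive")
        d_sa, d_ha, d_tpsa, d_bz = self.descriptor_drift
        if d_ha < -10 or d_tpsa < -80:
            raise ValueError("infeasible drift targets")


def _substituent_chain(rng, u, slopes, counters):
    """Fragment chain for one compound at registration stage u in [0, 1].

    Expected fragment counts per pool ramp linearly in u with the given
    slopes, around fixed early-stage base rates.
    """
    s_polar, s_phenyl, s_complex, s_apolar = slopes
    polar_rate = max(0.0, 0.6 + u * s_polar)
    phenyl_rate = max(0.0, 0.9 + u * s_phenyl)
    complex_rate = max(0.0, 0.25 + u * s_complex)
    apolar_rate = max(0.0, 1.2 + u * s_apolar)
    # stochastic rounding keeps per-compound counts close to the ramped rate,
    # so the median drift realizes the configured targets tightly
    def draw(rate: float) -> int:
        base = int(rate)
        return base + (1 if rng.random() < rate - base else 0)

    # cycle deterministically through each pool (stride coprime with the pool
    # sizes) so the realized fragment mixture is balanced rather than sampled;
    # the remaining randomness is the stochastic count rounding above
    def take(pool: list[str], key: str, count: int) -> list[tuple[str, int]]:
        out = []
        for _ in range(count):
            idx = (counters[key] * 5) % len(pool)
            out.append((pool[idx], idx))
            counters[key] += 1
        return out

    counts = (draw(polar_rate), draw(phenyl_rate), draw(complex_rate), draw(apolar_rate))
    picks = (
        [("polar", f, i) for f, i in take(POLAR_FRAGMENTS, "polar", counts[0])]
        + [("phenyl", f, i) for f, i in take(PHENYL_FRAGMENTS, "phenyl", counts[1])]
        + [("complex", f, i) for f, i in take(COMPLEX_FRAGMENTS, "complex", counts[2])]
        + [("apolar", f, i) for f, i in take(APOLAR_FRAGMENTS, "apolar", counts[3])]
    )
    rng.shuffle(picks)
    chain = "".join(f for _, f, _ in picks) if picks else "C"
    used = [(pool, idx) for pool, _, idx in picks]
    return chain, counts, used


def _shift_to_fraction(values: np.ndarray, threshold: float, target: float) -> np.ndarray:
    """Additively shift values so the active (>= threshold) fraction ~ target."""
    if target is None:
        return values
    q = np.quantile(values, 1.0 - target)
    return values + (threshold - q) + 1e-9


def generate(config: SeriesConfig = SeriesConfig()) -> AssayDataset:
    """Generate a synthetic lead-optimization dataset.

    Deterministic for a given config (byte-for-byte identical SMILES, dates
    and activities). Raises if any assembled SMILES fails to parse.
    """
    rng_struct = np.random.default_rng([config.seed, 0])
    rng_act = np.random.default_rng([config.seed, 1])
    n = config.n_series * config.compounds_per_series
    scaffolds = [SCAFFOLDS[i % len(SCAFFOLDS)] for i in range(config.n_series)]
    # each series is worked on during a time window (overlapping with its
    # neighbours), as in real projects where series are started, optimized
    # and abandoned; late compounds therefore concentrate in few series
    centers = (np.arange(config.n_series) + 0.5) / config.n_series
    u_grid = np.arange(n) / max(1, n - 1)
    weights = np.exp(
        -((u_grid[:, None] - centers[None, :]) ** 2) / (2 * config.series_overlap**2)
    )
    weights /= weights.sum(axis=1, keepdims=True)
    series_of = np.array(
        [rng_struct.choice(config.n_series, p=w) for w in weights]
    )

    counters = {"polar": 0, "phenyl": 0, "complex": 0, "apolar": 0}
    slopes = _slopes_from_targets(config.descriptor_drift)
    pools = {
        "polar": POLAR_FRAGMENTS,
        "phenyl": PHENYL_FRAGMENTS,
        "complex": COMPLEX_FRAGMENTS,
        "apolar": APOLAR_FRAGMENTS,
    }
    # structure-activity signal: a global per-fragment contribution plus a
    # series-specific interaction (the same substituent can help one scaffold
    # and hurt another), so prediction quality degrades with chemical
    # distance from the training compounds
    frag_potency = {
        (key, i): rng_act.normal(0.0, config.fragment_effect_sd)
        for key, pool in pools.items()
        for i in range(len(pool))
    }
    interaction = {
        (s, key, i): rng_act.normal(0.0, config.interaction_sd)
        for s in range(config.n_series)
        for key, pool in pools.items()
        for i in range(len(pool))
    }
    # pairwise fragment epistasis: the effect of a substituent depends on
    # which other substituents are present. This makes the activity
    # landscape locally smooth but globally rugged, so model accuracy decays
    # with distance from the training compounds (close analogues share
    # fragment pairs; isolated compounds realize unseen combinations)
    frag_ids = [(key, i) for key, pool in pools.items() for i in range(len(pool))]
    pair_effect = {}
    for a in range(len(frag_ids)):
        for b in range(a, len(frag_ids)):
            key = tuple(sorted((frag_ids[a], frag_ids[b])))
            pair_effect[key] = rng_act.normal(0.0, config.epistasis_sd)
    series_effect = rng_act.normal(0.0, config.series_effect_sd, size=config.n_series)

    smiles_list = []
    structure_effect = np.zeros(n)
    for i in range(n):
        u = i / max(1, n - 1)
        chain, _, used = _substituent_chain(rng_struct, u, slopes, counters)
        s_id = int(series_of[i])
        motif = SERIES_MOTIFS[s_id % len(SERIES_MOTIFS)]
        smiles = scaffolds[s_id].format(motif + chain)
        mol_from_smiles(smiles, context=f"generated compound {i}")  # validity check
        smiles_list.append(smiles)
        effect = sum(frag_potency[k] + interaction[(s_id, *k)] for k in used)
        ordered = sorted(used)
        pair_terms = [
            pair_effect[(ordered[a], ordered[b])]
            for a in range(len(ordered))
            for b in range(a + 1, len(ordered))
        ]
        # normalize by the number of contributing terms so heavily
        # substituted compounds do not get systematically wider activity
        # spreads than lightly substituted ones
        n_main = max(1, len(used))
        effect = effect / np.sqrt(n_main)
        if pair_terms:
            effect += np.sum(pair_terms) / np.sqrt(len(pair_terms))
        structure_effect[i] = effect

    activities = (
        config.activity_base
        + config.activity_trend * np.arange(n) / max(1, n - 1)
        + series_effect[series_of]
        + structure_effect
        + rng_act.normal(0.0, config.activity_noise_sd, size=n)
    )
    if config.active_fraction_targets is not None:
        k = required_test_size(n, 0.2)
        tgt_train, tgt_test = config.active_fraction_targets
        activities[: n - k] = _shift_to_fraction(
            activities[: n - k], config.threshold, tgt_train
        )
        activities[n - k :] = _shift_to_fraction(
            activities[n - k :], config.threshold, tgt_test
        )

    start = pd.Timestamp("2012-01-01")
    records = [
        CompoundRecord(
            id=f"CPD{i:05d}",
            smiles=smiles_list[i],
            activity=float(activities[i]),
            date=start + pd.Timedelta(days=3 * i),
        )
        for i in range(n)
    ]
    return AssayDataset(records, config.threshold, f"synthetic-{config.seed}")


# ---------------------------------------------------------------------------
# Fixed 12-compound toy fixture (cross-module oracle anchor)

TOY_SMILES = [
    # series A: para-substituted toluenes (mutually similar)
    ("T01", "Cc1ccc(N)cc1"),
    ("T02", "Cc1ccc(O)cc1"),
    ("T03", "Cc1ccc(NC)cc1"),
    ("T04", "Cc1ccc(OC)cc1"),
    # series B: cyclohexane carboxamides
    ("T05", "O=C(N)C1CCCCC1"),
    ("T06", "O=C(NC)C1CCCCC1"),
    ("T07", "O=C(NCC)C1CCCCC1"),
    ("T08", "O=C(N)C1CCC(C)CC1"),
    # series C: pyridine sulfonamides
    ("T09", "O=S(=O)(N)c1ccccn1"),
    ("T10", "O=S(=O)(NC)c1ccccn1"),
    ("T11", "O=S(=O)(N)c1ccncc1"),
    # singleton
    ("T12", "OCC(O)CO"),
]

TOY_ACTIVITIES = [5.1, 5.4, 6.0, 6.5, 6.8, 7.1, 7.4, 5.9, 6.4, 7.0, 5.2, 4.8]


def reference_toy_dataset() -> AssayDataset:
    """The fixed 12-compound toy dataset used as a cross-module test anchor.

    Three small chemical series plus one singleton, with dates and
    activities. Frozen companion values (pairwise Tanimoto matrices, the
    Taylor-Butina partition, spatial sums) live in ``simpd._toyfrozen`` and in
    the test suite.
    """
    start = pd.Timestamp("2015-06-01")
    records = [
        CompoundRecord(cid, smi, act, start + pd.Timedelta(days=30 * i))
        for i, ((cid, smi), act) in enumerate(zip(TOY_SMILES, TOY_ACTIVITIES))
    ]
    return AssayDataset(records, DEFAULT_THRESHOLD, "toy12")
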