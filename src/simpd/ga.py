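"""Simulated-time-split generation with a multi-objective genetic algorithm.

A candidate solution (genome) is a boolean test-membership vector over the
dataset with exactly ``round(0.2 * n)`` bits set. The GA (NSGA-II) minimizes
eight penalty objectives that make the resulting split look like a real
temporal split of a lead-optimization project:

1-4. |Delta_test-train median(descriptor) - target| for SA score (+0.28),
     heavy atom count (+3.1), TPSA (+13.2) and benzene rings per 1000 heavy
     atoms (-8.8);
5-6. |frac_active(train/test) - target| where the targets come from a
     temporal split of the dataset (project mode); in public-data mode these
     collapse to the single objective |Delta frac_active(test-train) - 0.11|;
7.   hinge penalty outside 10 < sum G - sum F' < 30;
8.   hinge penalty below sum G > 70.

Two constraints apply: the exact 20 % test-set size (guaranteed by operator
design plus repair) and a relative cluster-population entropy of the test
set < 0.9 (handled by constraint domination).

After the run, each Pareto-front solution is scored with a weighted sum of
exponentially transformed scaled objectives (weight 10 for the spatial
difference objective, 5 for the sum-G objective, 1 otherwise) and the highest
scorer becomes the selected split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import Clustering, cluster_dataset, relative_entropy
from .data import AssayDataset, Split, required_test_size
from .descriptors import simpd_descriptor_table, SIMPD_DESCRIPTORS
from .fingerprints import morgan_fingerprints, tanimoto_matrix
from .nsga2 import (
    environmental_selection,
    nondominated_sort,
    rank_and_crowding,
    tournament_pick,
)
from .spatial import spatial_summary_from_matrix

__all__ = [
    "DESCRIPTOR_DELTA_TARGETS",
    "ObjectiveTargets",
    "GAConfig",
    "SolutionSet",
    "init_population",
    "mutate",
    "crossover",
    "run_simpd",
    "score_and_select",
    "simpd_split",
]

#: Target test-train median deltas for the four descriptors, in
#: :data:`~simpd.descriptors.SIMPD_DESCRIPTORS` order.
DESCRIPTOR_DELTA_TARGETS = {
    "SA_Score": 0.28,
    "HeavyAtomCount": 3.1,
    "TPSA": 13.2,
    "fr_benzene_per_1000_heavy": -8.8,
}


@dataclass(frozen=True)
class ObjectiveTargets:
    """Target values for the GA objectives.

    Exactly one of the activity-balance parameterizations must be active:
    paired ``frac_active_train``/``frac_active_test`` targets (project mode,
    taken from a temporal split) or the single ``d_frac_active`` delta target
    (public-data mode, default 0.11).
    """

    d_sa: float = DESCRIPTOR_DELTA_TARGETS["SA_Score"]
    d_heavy: float = DESCRIPTOR_DELTA_TARGETS["HeavyAtomCount"]
    d_tpsa: float = DESCRIPTOR_DELTA_TARGETS["TPSA"]
    d_frbenz: float = DESCRIPTOR_DELTA_TARGETS["fr_benzene_per_1000_heavy"]
    frac_active_train: float | None = None
    frac_active_test: float | None = None
    d_frac_active: float | None = None
    gf_low: float = 10.0
    gf_high: float = 30.0
    g_min: float = 70.0

    def __post_init__(self):
        paired = self.frac_active_train is not None and self.frac_active_test is not None
        single = self.d_frac_active is not None
        if paired == single:
            raise ValueError(
                "exactly one of paired frac-active targets (project mode) or a "
                "single delta target (public mode) must be set"
            )

    @property
    def public_mode(self) -> bool:
        return self.d_frac_active is not None

    @property
    def objective_names(self) -> tuple[str, ...]:
        names = [f"d_median({d})" for d in SIMPD_DESCRIPTORS]
        if self.public_mode:
            names.append("d_frac_active")
        else:
            names.extend(["frac_active(train)", "frac_active(test)"])
        names.extend(["G-F_window", "G_floor"])
        return tuple(names)

    @classmethod
    def public(cls, d_frac_active: float = 0.11, **kw) -> "ObjectiveTargets":
        return cls(d_frac_active=d_frac_active, **kw)

    @classmethod
    def from_temporal_split(cls, dataset: AssayDataset, split: Split, **kw) -> "ObjectiveTargets":
        """Project mode: activity-balance targets from an actual temporal split."""
        labels = dataset.labels()
        train = labels[split.train_index(dataset)]
        test = labels[split.test_index(dataset)]
        return cls(
            frac_active_train=float(train.mean()),
            frac_active_test=float(test.mean()),
            **kw,
        )


@dataclass(frozen=True)
class GAConfig:
    """Run parameters for the NSGA-II optimization."""

    population: int = 500
    generations: int = 300
    mutation_replace_frac: float = 0.1
    test_fraction: float = 0.2
    entropy_max: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 < self.mutation_replace_frac < 1:
            raise ValueError("mutation_replace_frac must be in (0, 1)")


@dataclass
class SolutionSet:
    """Feasible first-front solutions of a finished run."""

    genomes: np.ndarray  # (n_solutions, n) boolean test-membership masks
    objectives: np.ndarray  # (n_solutions, n_objectives) raw penalties
    objective_names: tuple[str, ...]
    dataset_ids: tuple[str, ...]
    config: GAConfig
    targets: ObjectiveTargets
    scores: np.ndarray | None = None
    generation_log: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genomes)

    def split_for(self, index: int) -> Split:
        mask = self.genomes[index]
        ids = np.asarray(self.dataset_ids, dtype=object)
        return Split(
            tuple(ids[~mask]),
            tuple(ids[mask]),
            "simpd",
            self.config.test_fraction,
            self.config.seed,
            {"mode": "public" if self.targets.public_mode else "project"},
        )


class SimpdProblem:
    """Cached per-dataset state: descriptors, labels, distances, clustering."""

    def __init__(
        self,
        dataset: AssayDataset,
        targets: ObjectiveTargets,
        config: GAConfig,
        clustering: Clustering | None = None,
    ):
        n = len(dataset)
        if n < 10:
            raise ValueError("dataset too small for a meaningful 20 % test set")
        self.dataset = dataset
        self.targets = targets
        self.config = config
        self.n = n
        self.quota = required_test_size(n, config.test_fraction)
        self.labels = dataset.labels().astype(float)
        table = simpd_descriptor_table(dataset.smiles)
        self.descriptors = table[list(SIMPD_DESCRIPTORS)].to_numpy()
        fps = morgan_fingerprints(dataset.smiles, radius=2)
        self.dist = 1.0 - tanimoto_matrix(fps)
        self.clustering = clustering if clustering is not None else cluster_dataset(dataset)
        self._delta_targets = np.array(
            [targets.d_sa, targets.d_heavy, targets.d_tpsa, targets.d_frbenz]
        )

    def evaluate(self, mask: np.ndarray) -> np.ndarray:
        """Raw penalty vector for one genome."""
        t = self.targets
        test_idx = np.flatnonzero(mask)
        train_idx = np.flatnonzero(~mask)
        deltas = np.median(self.descriptors[test_idx], axis=0) - np.median(
            self.descriptors[train_idx], axis=0
        )
        pens = list(np.abs(deltas - self._delta_targets))

        fa_test = self.labels[test_idx].mean()
        fa_train = self.labels[train_idx].mean()
        if t.public_mode:
            pens.append(abs((fa_test - fa_train) - t.d_frac_active))
        else:
            pens.append(abs(fa_train - t.frac_active_train))
            pens.append(abs(fa_test - t.frac_active_test))

        summary = spatial_summary_from_matrix(self.dist, test_idx, train_idx)
        gf = summary.sum_G - summary.sum_Fprime
        pens.append(max(0.0, t.gf_low - gf) + max(0.0, gf - t.gf_high))
        pens.append(max(0.0, t.g_min - summary.sum_G))
        return np.array(pens)

    def violation(self, mask: np.ndarray) -> float:
        """Total constraint violation: size quota + entropy bound."""
        size_viol = abs(int(mask.sum()) - self.quota)
        ent = relative_entropy(np.flatnonzero(mask), self.clustering)
        return float(size_viol) + max(0.0, ent - self.config.entropy_max)

    def evaluate_all(self, pop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        F = np.array([self.evaluate(g) for g in pop])
        cv = np.array([self.violation(g) for g in pop])
        return F, cv


# ---------------------------------------------------------------------------
# Variation operators


def _repair(mask: np.ndarray, quota: int, rng: np.random.Generator) -> None:
    """Randomly flip bits until the test quota is exact (in place)."""
    excess = int(mask.sum()) - quota
    if excess > 0:
        drop = rng.choice(np.flatnonzero(mask), size=excess, replace=False)
        mask[drop] = False
    elif excess < 0:
        add = rng.choice(np.flatnonzero(~mask), size=-excess, replace=False)
        mask[add] = True


def init_population(
    clustering: Clustering, n: int, quota: int, pop_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Cluster-based initial population.

    Each genome assigns whole clusters (drawn without replacement) to the test
    side until the quota is reached; the cluster that overshoots contributes a
    random subset exactly filling the quota.
    """
    if n < 10:
        raise ValueError("dataset too small for a meaningful 20 % test set")
    pop = np.zeros((pop_size, n), dtype=bool)
    members = [clustering.members(c) for c in range(clustering.n_clusters)]
    for g in range(pop_size):
        order = rng.permutation(clustering.n_clusters)
        filled = 0
        for c in order:
            need = quota - filled
            if need <= 0:
                break
            chunk = members[c]
            if len(chunk) > need:
                chunk = rng.choice(chunk, size=need, replace=False)
            pop[g, chunk] = True
            filled += len(chunk)
    return pop


def mutate(
    mask: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Swap ``max(1, round(rate * |test|))`` test members with train members."""
    out = mask.copy()
    test_idx = np.flatnonzero(out)
    train_idx = np.flatnonzero(~out)
    k = max(1, int(round(rate * len(test_idx))))
    k = min(k, len(test_idx), len(train_idx))
    out[rng.choice(test_idx, size=k, replace=False)] = False
    out[rng.choice(train_idx, size=k, replace=False)] = True
    return out


def crossover(
    a: np.ndarray, b: np.ndarray, quota: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform binary crossover followed by random-swap quota repair."""
    swap = rng.random(len(a)) < 0.5
    c1, c2 = a.copy(), b.copy()
    c1[swap], c2[swap] = b[swap], a[swap]
    _repair(c1, quota, rng)
    _repair(c2, quota, rng)
    return c1, c2


# ---------------------------------------------------------------------------
# Main loop


def run_simpd(
    dataset: AssayDataset,
    targets: ObjectiveTargets,
    config: GAConfig = GAConfig(),
    clustering: Clustering | None = None,
) -> SolutionSet:
    """Run the NSGA-II optimization and return the feasible first front.

    A single seeded RNG drives initialization, tournament selection,
    crossover, repair and mutation, so a run is reproducible bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    problem = SimpdProblem(dataset, targets, config, clustering)
    pop = init_population(problem.clustering, problem.n, problem.quota, config.population, rng)
    F, cv = problem.evaluate_all(pop)
    log: list[dict] = []

    for gen in range(config.generations):
        rank, crowd = rank_and_crowding(F, cv)
        offspring = np.empty_like(pop)
        i = 0
        while i < config.population:
            pa = pop[tournament_pick(rank, crowd, cv, rng)]
            pb = pop[tournament_pick(rank, crowd, cv, rng)]
            c1, c2 = crossover(pa, pb, problem.quota, rng)
            offspring[i] = mutate(c1, config.mutation_replace_frac, rng)
            i += 1
            if i < config.population:
                offspring[i] = mutate(c2, config.mutation_replace_frac, rng)
                i += 1
        Fo, cvo = problem.evaluate_all(offspring)
        all_pop = np.concatenate([pop, offspring])
        all_F = np.concatenate([F, Fo])
        all_cv = np.concatenate([cv, cvo])
        keep = environmental_selection(all_F, all_cv, config.population)
        pop, F, cv = all_pop[keep], all_F[keep], all_cv[keep]
        log.append(
            {
                "generation": gen,
                "n_feasible": int((cv == 0).sum()),
                "median_penalties": list(np.median(F, axis=0)),
                "min_penalties": list(F.min(axis=0)),
            }
        )

    fronts = nondominated_sort(F, cv)
    front0 = fronts[0]
    feasible = front0[cv[front0] == 0]
    if feasible.size == 0:
        raise RuntimeError(
            "no feasible solution on the final front "
            f"(min constraint violation {cv.min():.4f}); the dataset may be too "
            "homogeneous for the entropy bound, or too small"
        )
    # deduplicate identical genomes for a cleaner archive
    _, unique_idx = np.unique(pop[feasible], axis=0, return_index=True)
    feasible = feasible[np.sort(unique_idx)]
    return SolutionSet(
        genomes=pop[feasible],
        objectives=F[feasible],
        objective_names=targets.objective_names,
        dataset_ids=tuple(dataset.ids),
        config=config,
        targets=targets,
        generation_log=log,
    )


def score_and_select(solutions: SolutionSet) -> tuple[np.ndarray, int, Split]:
    """Rank Pareto solutions by the weighted exponential score; pick the best.

    Each objective is scaled so its 90th percentile over the solution set is
    1 (constant objectives fall back to scale 1), then
    ``score_i = sum_j w_j * exp(-x_ij)`` with weight 10 on the spatial
    difference (G-F') objective, 5 on the sum-G objective and 1 elsewhere.
    Ties go to the lowest solution index.
    """
    F = solutions.objectives
    scale = np.percentile(F, 90, axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    x = F / scale
    w = np.ones(F.shape[1])
    w[-2] = 10.0  # G - F' window objective
    w[-1] = 5.0  # sum-G floor objective
    scores = (w * np.exp(-x)).sum(axis=1)
    best = int(np.argmax(scores))  # argmax keeps the lowest index on ties
    solutions.scores = scores
    return scores, best, solutions.split_for(best)


def simpd_split(
    dataset: AssayDataset,
    targets: ObjectiveTargets | None = None,
    config: GAConfig = GAConfig(),
    clustering: Clustering | None = None,
) -> tuple[Split, SolutionSet]:
    """Convenience wrapper: run the GA and return the selected split.

    Without explicit targets, project mode is used when the dataset has
    registration dates (activity-balance targets from its temporal split) and
    public-data mode otherwise.
    """
    if targets is None:
        if all(r.date is not None for r in dataset.records):
            from .data import temporal_split

            targets = ObjectiveTargets.from_temporal_split(
                dataset, temporal_split(dataset, config.test_fraction)
            )
        else:
            targets = ObjectiveTargets.public()
    solutions = run_simpd(dataset, targets, config, clustering)
    _, _, split = score_and_select(solutions)
    return split, solutions
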