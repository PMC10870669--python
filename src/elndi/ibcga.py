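"""Inheritable bi-objective combinatorial GA for joint feature-subset and
SVM-parameter optimisation, with orthogonal-array intelligent crossover.

The optimisation problem C(n, m) is to pick a small subset of m features
out of n candidates together with the RBF-SVM cost C and kernel width
gamma, maximising mean stratified 10-fold cross-validated accuracy on a
balanced development cohort.  The search is *inheritable*: solutions at
subset size r seed the population at r + 1 by flipping one additional
feature gene on, so the sweep over sizes reuses what was already learned.
The bi-objective (accuracy up, subset size down) is resolved
lexicographically - on equal fitness the smaller subset wins.

Crossover follows the intelligent-evolutionary-algorithm recipe: the genes
on which two parents disagree become the factors of a two-level orthogonal
array; each array row is evaluated as a candidate chromosome, per-gene main
effects are estimated from the row fitnesses, and the child takes the
better level of every gene (repaired back to exactly r selected features).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import LabeledCohort
from .errors import ConfigurationError, InvalidInputError, StratificationError

__all__ = [
    "GAConfig",
    "Chromosome",
    "FitnessRecord",
    "ELNDIModel",
    "OrthogonalArray",
    "init_population",
    "evaluate_fitness",
    "intelligent_crossover",
    "inherit_step",
    "run_ibcga",
    "compute_med",
]


def _default_c_grid() -> np.ndarray:
    return 2.0 ** np.arange(-5, 16, 2, dtype=float)  # 2^-5 .. 2^15 by powers of 4


def _default_gamma_grid() -> np.ndarray:
    return 2.0 ** np.arange(-15, 4, 2, dtype=float)  # 2^-15 .. 2^3 by powers of 4


@dataclass
class GAConfig:
    population_size: int = 50
    generations_per_r: int = 30
    r_start: int = 3
    r_end: int = 15
    c_grid: np.ndarray = field(default_factory=_default_c_grid)
    gamma_grid: np.ndarray = field(default_factory=_default_gamma_grid)
    cv_folds: int = 10
    crossover_rate: float = 0.5
    mutation_rate: float = 0.05
    param_mutation_rate: float = 0.1
    svm_max_iter: int = 5000  # bounds solver effort in the ill-conditioned grid corners
    seed: int = 0

    def __post_init__(self) -> None:
        self.c_grid = np.asarray(self.c_grid, dtype=float)
        self.gamma_grid = np.asarray(self.gamma_grid, dtype=float)
        if self.r_start < 1 or self.r_end < self.r_start:
            raise ConfigurationError("need 1 <= r_start <= r_end")
        if self.c_grid.size == 0 or self.gamma_grid.size == 0:
            raise ConfigurationError("parameter grids must be non-empty")


@dataclass
class Chromosome:
    """Binary feature mask plus grid indices for the SVM parameters (C, gamma)."""

    mask: np.ndarray  # bool, length n
    c_idx: int
    gamma_idx: int

    @property
    def r(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "Chromosome":
        return Chromosome(self.mask.copy(), self.c_idx, self.gamma_idx)

    def key(self) -> tuple:
        return (self.mask.tobytes(), self.c_idx, self.gamma_idx)


@dataclass
class FitnessRecord:
    chromosome: Chromosome
    fitness: float
    fold_accuracies: np.ndarray


class OrthogonalArray:
    """Two-level orthogonal array L_{2^m}(2^{2^m - 1}) from the parity design.

    Row i, column j (1-based factor columns) holds parity(i & j); any two
    distinct columns contain each of the four level pairs equally often.
    """

    def __init__(self, n_factors: int):
        if n_factors < 1:
            raise InvalidInputError("need at least one factor")
        m = 1
        while (1 << m) - 1 < n_factors:
            m += 1
        rows = 1 << m
        i = np.arange(rows)[:, None]
        j = np.arange(1, n_factors + 1)[None, :]
        bits = i & j
        # popcount parity of each entry
        par = np.zeros_like(bits)
        while bits.any():
            par ^= bits & 1
            bits >>= 1
        self.design = par.astype(np.int8)  # rows x n_factors, levels {0,1}

    @property
    def n_rows(self) -> int:
        return self.design.shape[0]

    def is_orthogonal(self) -> bool:
        d = self.design
        rows, k = d.shape
        for a, b in itertools.combinations(range(k), 2):
            pair = d[:, a] * 2 + d[:, b]
            counts = np.bincount(pair, minlength=4)
            if not np.all(counts == rows // 4):
                return False
        return True


# ---------------------------------------------------------------------------
# Fitness machinery
# ---------------------------------------------------------------------------


class _Evaluator:
    """Caches 10-fold CV fitness per chromosome on one fixed dataset + fold plan."""

    def __init__(self, data: LabeledCohort, config: GAConfig):
        self.X = data.features.to_numpy(dtype=float)
        self.y = data.labels.to_numpy(dtype=int)
        self.config = config
        counts = np.bincount(self.y, minlength=2)
        if counts.min() < config.cv_folds:
            raise StratificationError(
                f"each class needs >= cv_folds={config.cv_folds} members"
            )
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed % (2**31)
        )
        self.folds = list(skf.split(self.X, self.y))
        self.cache: dict[tuple, FitnessRecord] = {}
        self.n_evaluations = 0

    def __call__(self, chrom: Chromosome) -> FitnessRecord:
        key = chrom.key()
        rec = self.cache.get(key)
        if rec is not None:
            return rec
        rec = self._evaluate(chrom)
        self.cache[key] = rec
        return rec

    def _evaluate(self, chrom: Chromosome) -> FitnessRecord:
        mask = chrom.mask
        if not mask.any():
            rec = FitnessRecord(chrom.copy(), 0.0, np.zeros(self.config.cv_folds))
            return rec
        self.n_evaluations += 1
        X = self.X[:, mask]
        C = float(self.config.c_grid[chrom.c_idx])
        gamma = float(self.config.gamma_grid[chrom.gamma_idx])
        accs = np.empty(len(self.folds))
        for f, (tr, te) in enumerate(self.folds):
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (X[tr] - mu) / sd
            Xte = (X[te] - mu) / sd
            clf = SVC(C=C, gamma=gamma, kernel="rbf", max_iter=self.config.svm_max_iter)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=ConvergenceWarning)
                clf.fit(Xtr, self.y[tr])
            accs[f] = float(np.mean(clf.predict(Xte) == self.y[te]))
        return FitnessRecord(chrom.copy(), float(accs.mean()), accs)


def evaluate_fitness(
    chrom: Chromosome, data: LabeledCohort, config: GAConfig
) -> FitnessRecord:
    """Stratified k-fold CV accuracy of the RBF SVM encoded by ``chrom``.

    Features are z-standardised inside each training fold.  Deterministic
    given ``config.seed`` (which fixes the fold plan).
    """
    return _Evaluator(data, config)(chrom)


# ---------------------------------------------------------------------------
# Genetic operators
# ---------------------------------------------------------------------------


def init_population(
    n: int, r: int, config: GAConfig, rng: Optional[np.random.Generator] = None
) -> list[Chromosome]:
    """Seeded random population: each chromosome has exactly r feature genes on."""
    if r > n:
        raise ConfigurationError(f"subset size r={r} exceeds n={n} candidates")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pop = []
    for _ in range(config.population_size):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=r, replace=False)] = True
        pop.append(
            Chromosome(
                mask,
                int(rng.integers(config.c_grid.size)),
                int(rng.integers(config.gamma_grid.size)),
            )
        )
    return pop


def inherit_step(
    population: list[Chromosome], rng: np.random.Generator
) -> list[Chromosome]:
    """Grow every chromosome from subset size r to r+1 by switching on one 0-gene."""
    out = []
    for chrom in population:
        zeros = np.flatnonzero(~chrom.mask)
        if zeros.size == 0:
            raise ConfigurationError("cannot inherit: all feature genes already on")
        child = chrom.copy()
        child.mask[rng.choice(zeros)] = True
        out.append(child)
    return out


def _repair(
    mask: np.ndarray, r: int, diff_positions: np.ndarray, effect_by_pos: dict[int, float]
) -> np.ndarray:
    """Flip lowest-|main-effect| disagreeing genes until the mask sums to r."""
    mask = mask.copy()
    excess = int(mask.sum()) - r
    if excess == 0:
        return mask
    want_on = excess < 0
    candidates = [p for p in diff_positions if mask[p] != want_on]
    candidates.sort(key=lambda p: abs(effect_by_pos.get(p, 0.0)))
    for p in candidates[: abs(excess)]:
        mask[p] = want_on
    return mask


def intelligent_crossover(
    parent_a: Chromosome,
    parent_b: Chromosome,
    evaluate: Callable[[Chromosome], FitnessRecord],
) -> Chromosome:
    """Recombine two parents through an orthogonal-array experiment.

    Genes shared by both parents are inherited directly.  Each disagreeing
    gene (feature positions where the masks differ, and the two parameter
    genes when they differ) becomes a two-level factor; every OA row is
    evaluated as a candidate chromosome, per-factor main effects are the
    mean fitness difference between its two levels, and the child adopts
    the better level of every factor.  The feature mask is repaired back to
    exactly r ones by flipping the least influential disagreeing genes; the
    best evaluated OA row (likewise repaired) is kept as a fallback if it
    outperforms the composed child.
    """
    if parent_a.r != parent_b.r:
        raise InvalidInputError("parents must share the subset size r")
    r = parent_a.r
    diff_feat = np.flatnonzero(parent_a.mask != parent_b.mask)
    factors: list[tuple[str, int]] = [("feat", int(p)) for p in diff_feat]
    if parent_a.c_idx != parent_b.c_idx:
        factors.append(("c", -1))
    if parent_a.gamma_idx != parent_b.gamma_idx:
        factors.append(("gamma", -1))
    if not factors:
        return parent_a.copy()

    oa = OrthogonalArray(len(factors))

    def build(levels: np.ndarray) -> Chromosome:
        mask = parent_a.mask.copy()
        c_idx, g_idx = parent_a.c_idx, parent_a.gamma_idx
        for (kind, pos), lev in zip(factors, levels):
            src = parent_b if lev else parent_a
            if kind == "feat":
                mask[pos] = src.mask[pos]
            elif kind == "c":
                c_idx = src.c_idx
            else:
                g_idx = src.gamma_idx
        return Chromosome(mask, c_idx, g_idx)

    rows = [build(oa.design[i]) for i in range(oa.n_rows)]
    fits = np.array([evaluate(c).fitness for c in rows])
    effects = np.empty(len(factors))
    best_levels = np.empty(len(factors), dtype=np.int8)
    for f in range(len(factors)):
        lev = oa.design[:, f]
        m1, m0 = fits[lev == 1].mean(), fits[lev == 0].mean()
        effects[f] = m1 - m0
        best_levels[f] = 1 if m1 > m0 else 0
    effect_by_pos = {
        pos: effects[f] for f, (kind, pos) in enumerate(factors) if kind == "feat"
    }

    child = build(best_levels)
    child.mask = _repair(child.mask, r, diff_feat, effect_by_pos)

    best_row = rows[int(np.argmax(fits))]
    best_row = Chromosome(
        _repair(best_row.mask, r, diff_feat, effect_by_pos),
        best_row.c_idx,
        best_row.gamma_idx,
    )
    if evaluate(best_row).fitness > evaluate(child).fitness:
        return best_row
    return child


def _mutate(chrom: Chromosome, config: GAConfig, rng: np.random.Generator) -> Chromosome:
    """Count-preserving swap mutation plus occasional parameter-gene redraw."""
    child = chrom.copy()
    if rng.random() < config.mutation_rate:
        ones = np.flatnonzero(child.mask)
        zeros = np.flatnonzero(~child.mask)
        if ones.size and zeros.size:
            child.mask[rng.choice(ones)] = False
            child.mask[rng.choice(zeros)] = True
    if rng.random() < config.param_mutation_rate:
        if rng.random() < 0.5:
            child.c_idx = int(rng.integers(config.c_grid.size))
        else:
            child.gamma_idx = int(rng.integers(config.gamma_grid.size))
    return child


# ---------------------------------------------------------------------------
# The full sweep
# ---------------------------------------------------------------------------


@dataclass
class ELNDIModel:
    """Result of the evolutionary search: subset, SVM parameters, ranked effects."""

    selected_features: list[str]
    C: float
    gamma: float
    classifier: Pipeline
    med_ranks: list[tuple[str, float]]
    fit_log: pd.DataFrame  # columns: r, generation, best_fitness
    cv_fitness: float
    seed: int

    @property
    def m(self) -> int:
        return len(self.selected_features)

    def decision_values(self, features: pd.DataFrame) -> np.ndarray:
        return self.classifier.decision_function(
            features[self.selected_features].to_numpy(dtype=float)
        )

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.classifier.predict(
            features[self.selected_features].to_numpy(dtype=float)
        )

    def model_card(self) -> dict:
        return {
            "model": "EL-NDI",
            "selected_features": self.selected_features,
            "m": self.m,
            "C": self.C,
            "gamma": self.gamma,
            "cv_fitness": self.cv_fitness,
            "med_ranks": [[f, v] for f, v in self.med_ranks],
            "seed": self.seed,
        }

    def save_card(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_card(), indent=1, sort_keys=True))


def run_ibcga(data: LabeledCohort, config: GAConfig) -> ELNDIModel:
    """Sweep subset sizes r_start..r_end, evolving population at each size.

    Within a size: elitism of 1, tournament selection of size 2,
    orthogonal-array intelligent crossover at ``crossover_rate``, swap
    mutation, for ``generations_per_r`` generations.  Between sizes the
    population is inherited by switching one extra feature gene on.  The
    returned model is the best chromosome over the whole sweep (ties broken
    toward smaller subsets), refit on all supplied data.
    """
    n = data.features.shape[1]
    if n < config.r_start:
        raise ConfigurationError(
            f"{n} candidate features but r_start={config.r_start}"
        )
    r_end = min(config.r_end, n)
    evaluate = _Evaluator(data, config)
    rng = np.random.default_rng(config.seed)

    population = init_population(n, config.r_start, config, rng)
    best_per_r: dict[int, FitnessRecord] = {}
    log_rows = []

    for r in range(config.r_start, r_end + 1):
        if r > config.r_start:
            population = inherit_step(population, rng)
        records = [evaluate(c) for c in population]
        best = max(records, key=lambda rec: rec.fitness)
        for gen in range(config.generations_per_r):
            new_pop = [best.chromosome.copy()]  # elite, unmutated
            while len(new_pop) < config.population_size:
                a = _tournament(records, rng)
                b = _tournament(records, rng)
                if rng.random() < config.crossover_rate:
                    child = intelligent_crossover(a, b, evaluate)
                else:
                    child = (a if evaluate(a).fitness >= evaluate(b).fitness else b).copy()
                new_pop.append(_mutate(child, config, rng))
            population = new_pop
            records = [evaluate(c) for c in population]
            gen_best = max(records, key=lambda rec: rec.fitness)
            if gen_best.fitness > best.fitness:
                best = gen_best
            log_rows.append({"r": r, "generation": gen, "best_fitness": best.fitness})
        assert all(c.r == r for c in population), "subset-size invariant violated"
        best_per_r[r] = best

    # bi-objective resolution: max fitness, then smallest subset size
    winner_r = max(best_per_r, key=lambda r: (best_per_r[r].fitness, -r))
    winner = best_per_r[winner_r]
    chrom = winner.chromosome
    names = [data.features.columns[i] for i in np.flatnonzero(chrom.mask)]
    C = float(config.c_grid[chrom.c_idx])
    gamma = float(config.gamma_grid[chrom.gamma_idx])
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(C=C, gamma=gamma, kernel="rbf", max_iter=config.svm_max_iter)),
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        clf.fit(
            data.features[names].to_numpy(dtype=float),
            data.labels.to_numpy(dtype=int),
        )
    model = ELNDIModel(
        selected_features=names,
        C=C,
        gamma=gamma,
        classifier=clf,
        med_ranks=[],
        fit_log=pd.DataFrame(log_rows),
        cv_fitness=winner.fitness,
        seed=config.seed,
    )
    model.med_ranks = compute_med(model, data)
    return model


def _tournament(records: list[FitnessRecord], rng: np.random.Generator) -> Chromosome:
    i, j = rng.integers(len(records)), rng.integers(len(records))
    return records[i if records[i].fitness >= records[j].fitness else j].chromosome


def compute_med(model: ELNDIModel, data: LabeledCohort) -> list[tuple[str, float]]:
    """Rank selected features by main effect difference (MED).

    For feature j, MED_j is the absolute difference between the mean SVM
    decision value when column j is set to its observed maximum and when it
    is set to its observed minimum, all other features at their observed
    values.  Larger MED = larger individual effect on the prediction.
    A constant feature yields MED 0.
    """
    X = data.features[model.selected_features].to_numpy(dtype=float)
    ranks = []
    for j, name in enumerate(model.selected_features):
        lo, hi = X[:, j].min(), X[:, j].max()
        if lo == hi:
            ranks.append((name, 0.0))
            continue
        Xhi = X.copy()
        Xhi[:, j] = hi
        Xlo = X.copy()
        Xlo[:, j] = lo
        d_hi = model.classifier.decision_function(Xhi).mean()
        d_lo = model.classifier.decision_function(Xlo).mean()
        ranks.append((name, float(abs(d_hi - d_lo))))
    ranks.sort(key=lambda t: -t[1])
    return ranks
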