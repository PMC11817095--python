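"""Modified Genetic-Random Forest (MG-RF) regressor.

A generational genetic algorithm searches jointly over (a) a printed grid
of random-forest hyperparameters (tree depth, mtry rule, leaf/split
minima, ensemble size) and (b) a per-tree retention bitmask that prunes
the fitted ensemble: a mask bit of 1 keeps the corresponding decision
tree in the averaged prediction, 0 drops it. Fitness is the validation
error (MSE by default, MAE optionally) of the *masked* ensemble: the base
forest is fitted once per decoded hyperparameter combination at its full
size, and the mask selects the sub-ensemble whose mean prediction is
scored. Selection is by tournament, variation by single-point crossover
applied independently within the hyperparameter segment and within the
mask segment (the segments never mix), plus per-gene/per-bit mutation;
elitism keeps the best individuals verbatim, which makes best-ever
fitness non-increasing across generations.

The base forests are scikit-learn ``RandomForestRegressor`` instances;
the genome encoding, evolution loop, pruned prediction and feature
ranking wrapper live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .fusion import FeatureMatrix

__all__ = [
    "HyperGrid",
    "Chromosome",
    "GAConfig",
    "OptimizedForest",
    "rank_features",
    "init_population",
    "decode_chromosome",
    "encode_chromosome",
    "evaluate_fitness",
    "evolve_generation",
    "fit_mgrf",
    "predict_ages",
]

_AXES = ("max_depth", "max_features", "min_samples_leaf", "min_samples_split", "n_estimators")


@dataclass(frozen=True)
class HyperGrid:
    """The hyperparameter grid the GA searches.

    Both ``'auto'`` and ``'sqrt'`` mtry rules decode to sqrt(d) candidate
    features per split (they alias the same rule for regression forests in
    current scikit-learn).
    """

    max_depth: tuple = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100, None)
    max_features: tuple = ("auto", "sqrt")
    min_samples_leaf: tuple = (1, 2, 4)
    min_samples_split: tuple = (2, 5, 10)
    n_estimators: tuple = (200, 400, 600, 800, 1000, 1200, 1400, 1600, 1800, 2000)

    def __post_init__(self):
        for name in _AXES:
            if not getattr(self, name):
                raise ValueError(f"grid axis {name} must be non-empty")

    @property
    def axes(self) -> tuple[tuple, ...]:
        return tuple(getattr(self, name) for name in _AXES)

    @property
    def max_trees(self) -> int:
        return max(self.n_estimators)


@dataclass(frozen=True)
class Chromosome:
    """One candidate: 5 grid-index genes plus a tree-retention bitmask."""

    hyper_genes: tuple
    tree_mask: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "hyper_genes", tuple(int(g) for g in self.hyper_genes))
        object.__setattr__(self, "tree_mask", np.asarray(self.tree_mask, dtype=bool))
        if len(self.hyper_genes) != len(_AXES):
            raise ValueError(f"expected {len(_AXES)} hyper genes")

    def key(self) -> tuple:
        """Hashable identity (used for fitness memoization)."""
        return (self.hyper_genes, self.tree_mask.tobytes())


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults are the standard configuration: population 20 evolved for 50
    generations with tournament selection (size 3), crossover rate 0.8,
    per-gene/per-bit mutation rate 0.1, one elite, and validation MSE as
    the fitness. ``optimize_tree_mask=False`` restricts the search to the
    hyperparameter grid (the mask stays all-ones). ``fitness_threshold``
    optionally stops evolution early once best fitness falls at or below
    it; by default all generations run.
    """

    population_size: int = 20
    generations: int = 50
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    tournament_size: int = 3
    elitism: int = 1
    fitness_metric: str = "mse"
    rng_seed: int = 0
    optimize_tree_mask: bool = True
    fitness_threshold: float | None = None

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must be in [0, 1]")
        if not 1 <= self.tournament_size <= self.population_size:
            raise ValueError("tournament_size must be in [1, population_size]")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("elitism must be in [0, population_size)")
        if self.fitness_metric not in ("mse", "mae"):
            raise ValueError("fitness_metric must be 'mse' or 'mae'")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass
class OptimizedForest:
    """The GA's best decoded, fitted, pruned forest plus run diagnostics."""

    model_spec: dict
    forest: RandomForestRegressor
    retained: np.ndarray  # indices of retained trees
    feature_ranking: np.ndarray  # importance-ordered feature indices
    importance_scores: np.ndarray  # aligned with feature_ranking
    ga_history: list  # per generation: {"best": float, "mean": float}
    best_chromosome: Chromosome
    best_fitness: float
    n_features: int


# ---------------------------------------------------------------------------
# feature ranking


def rank_features(F, y, seed: int, n_estimators: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Rank features by impurity importance of a seeded RF regressor.

    Returns (ordered feature indices, their importance scores); scores are
    non-negative and sum to 1. Ties break by ascending index.
    """
    X = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("feature matrix must have at least one column")
    if X.shape[0] < 2:
        raise ValueError("need at least two samples to rank features")
    rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    imp = rf.feature_importances_
    order = np.lexsort((np.arange(imp.size), -imp))
    return order, imp[order]


# ---------------------------------------------------------------------------
# genome


def decode_chromosome(c: Chromosome, grid: HyperGrid) -> tuple[dict, np.ndarray]:
    """Map gene indices to grid values and the mask to retained tree indices."""
    spec = {}
    for name, axis, g in zip(_AXES, grid.axes, c.hyper_genes):
        if not 0 <= g < len(axis):
            raise ValueError(f"gene for {name} out of range: {g} not in [0, {len(axis)})")
        spec[name] = axis[g]
    n_est = spec["n_estimators"]
    if c.tree_mask.size < n_est:
        raise ValueError("tree_mask shorter than the decoded n_estimators")
    retained = np.flatnonzero(c.tree_mask[:n_est])
    return spec, retained


def encode_chromosome(spec: dict, tree_mask: np.ndarray, grid: HyperGrid) -> Chromosome:
    """Inverse of :func:`decode_chromosome` on the hyperparameter part."""
    genes = []
    for name, axis in zip(_AXES, grid.axes):
        try:
            genes.append(axis.index(spec[name]))
        except ValueError:
            raise ValueError(f"value {spec[name]!r} not on grid axis {name}") from None
    return Chromosome(hyper_genes=tuple(genes), tree_mask=tree_mask)


def _sklearn_params(spec: dict) -> dict:
    """Decoded spec -> RandomForestRegressor constructor arguments."""
    params = dict(spec)
    # 'auto' aliased 'sqrt' for regression mtry; sklearn dropped the name
    if params["max_features"] == "auto":
        params["max_features"] = "sqrt"
    return params


def _repair_mask(c: Chromosome, grid: HyperGrid, rng: np.random.Generator) -> Chromosome:
    """Guarantee at least one retained tree in the active mask window."""
    n_est = grid.axes[-1][c.hyper_genes[-1]]
    if c.tree_mask[:n_est].any():
        return c
    mask = c.tree_mask.copy()
    mask[rng.integers(0, n_est)] = True
    return replace(c, tree_mask=mask)


def init_population(cfg: GAConfig, grid: HyperGrid, rng: np.random.Generator) -> list[Chromosome]:
    """Random initial population: uniform genes, Bernoulli(0.5) mask bits."""
    pop = []
    for _ in range(cfg.population_size):
        genes = tuple(int(rng.integers(0, len(axis))) for axis in grid.axes)
        if cfg.optimize_tree_mask:
            mask = rng.random(grid.max_trees) < 0.5
        else:
            mask = np.ones(grid.max_trees, dtype=bool)
        pop.append(_repair_mask(Chromosome(genes, mask), grid, rng))
    return pop


# ---------------------------------------------------------------------------
# fitness


def _masked_mean_prediction(forest: RandomForestRegressor, X: np.ndarray,
                            retained: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the retained trees' individual predictions."""
    if retained.size == 0:
        raise RuntimeError("retained tree set is empty; mask repair failed")
    preds = np.stack([forest.estimators_[i].predict(X) for i in retained])
    return preds.mean(axis=0)


def _error(pred: np.ndarray, y: np.ndarray, metric: str) -> float:
    resid = pred - y
    return float(np.mean(resid**2) if metric == "mse" else np.mean(np.abs(resid)))


class _FitnessEvaluator:
    """Memoizing fitness oracle over a fixed train/validation split.

    Base forests are fitted once per decoded hyperparameter combination
    and their per-tree validation predictions cached, so evaluating a new
    mask for an already-seen combination costs only an average. Valid
    because fitting is deterministic under the run seed.
    """

    def __init__(self, X_tr, y_tr, X_val, y_val, grid: HyperGrid, cfg: GAConfig):
        if len(y_val) == 0:
            raise ValueError("validation set must be non-empty")
        self.X_tr, self.y_tr = X_tr, y_tr
        self.X_val, self.y_val = X_val, y_val
        self.grid, self.cfg = grid, cfg
        self._tree_preds: dict[tuple, np.ndarray] = {}
        self._fitness: dict[tuple, float] = {}

    def _val_tree_predictions(self, genes: tuple) -> np.ndarray:
        if genes not in self._tree_preds:
            spec, _ = decode_chromosome(Chromosome(genes, np.ones(self.grid.max_trees)), self.grid)
            rf = RandomForestRegressor(
                **_sklearn_params(spec), random_state=self.cfg.rng_seed, n_jobs=1
            )
            rf.fit(self.X_tr, self.y_tr)
            self._tree_preds[genes] = np.stack(
                [t.predict(self.X_val) for t in rf.estimators_]
            )
        return self._tree_preds[genes]

    def __call__(self, c: Chromosome) -> float:
        key = c.key()
        if key not in self._fitness:
            spec, retained = decode_chromosome(c, self.grid)
            if retained.size == 0:
                raise RuntimeError("retained tree set is empty; mask repair failed")
            preds = self._val_tree_predictions(c.hyper_genes)
            pred = preds[retained].mean(axis=0)
            fit = _error(pred, self.y_val, self.cfg.fitness_metric)
            if not np.isfinite(fit):
                raise RuntimeError("non-finite fitness")
            self._fitness[key] = fit
        return self._fitness[key]


def evaluate_fitness(c: Chromosome, train, val, grid: HyperGrid, cfg: GAConfig) -> float:
    """Validation error (lower is better) of one chromosome.

    ``train`` and ``val`` are (X, y) pairs over disjoint rows. The forest
    is fitted on train with the decoded hyperparameters; the prediction is
    the mean over *retained* trees only.
    """
    X_tr, y_tr = train
    X_val, y_val = val
    return _FitnessEvaluator(
        np.asarray(X_tr, float), np.asarray(y_tr, float),
        np.asarray(X_val, float), np.asarray(y_val, float), grid, cfg
    )(c)


# ---------------------------------------------------------------------------
# evolution


def _tournament(fitnesses: np.ndarray, k: int, rng: np.random.Generator) -> int:
    idx = rng.choice(fitnesses.size, size=k, replace=False)
    return int(idx[np.argmin(fitnesses[idx])])


def _crossover_pair(a: Chromosome, b: Chromosome, cfg: GAConfig,
                    rng: np.random.Generator) -> tuple[Chromosome, Chromosome]:
    ga, gb = list(a.hyper_genes), list(b.hyper_genes)
    if rng.random() < cfg.crossover_rate and len(ga) > 1:
        pt = int(rng.integers(1, len(ga)))
        ga[pt:], gb[pt:] = gb[pt:], ga[pt:]
    ma, mb = a.tree_mask.copy(), b.tree_mask.copy()
    if cfg.optimize_tree_mask and rng.random() < cfg.crossover_rate and ma.size > 1:
        pt = int(rng.integers(1, ma.size))
        ma[pt:], mb[pt:] = mb[pt:].copy(), ma[pt:].copy()
    return Chromosome(tuple(ga), ma), Chromosome(tuple(gb), mb)


def _mutate(c: Chromosome, cfg: GAConfig, grid: HyperGrid,
            rng: np.random.Generator) -> Chromosome:
    genes = list(c.hyper_genes)
    for i, axis in enumerate(grid.axes):
        if rng.random() < cfg.mutation_rate:
            genes[i] = int(rng.integers(0, len(axis)))
    mask = c.tree_mask.copy()
    if cfg.optimize_tree_mask:
        flips = rng.random(mask.size) < cfg.mutation_rate
        mask ^= flips
    return Chromosome(tuple(genes), mask)


def evolve_generation(population: list[Chromosome], fitnesses, cfg: GAConfig,
                      grid: HyperGrid, rng: np.random.Generator) -> list[Chromosome]:
    """One generational step: elitism, tournament selection, single-point
    crossover per segment, per-gene/bit mutation, mask repair."""
    fit = np.asarray(fitnesses, dtype=float)
    if len(population) != cfg.population_size or fit.size != cfg.population_size:
        raise ValueError("population and fitnesses must both have population_size entries")
    order = np.argsort(fit, kind="stable")
    next_pop: list[Chromosome] = [population[i] for i in order[: cfg.elitism]]
    while len(next_pop) < cfg.population_size:
        pa = population[_tournament(fit, cfg.tournament_size, rng)]
        pb = population[_tournament(fit, cfg.tournament_size, rng)]
        ca, cb = _crossover_pair(pa, pb, cfg, rng)
        for child in (ca, cb):
            if len(next_pop) < cfg.population_size:
                child = _repair_mask(_mutate(child, cfg, grid, rng), grid, rng)
                next_pop.append(child)
    return next_pop


# ---------------------------------------------------------------------------
# fitting and prediction


def _stratified_val_split(ages: np.ndarray, val_fraction: float,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic split stratified by integer age-year.

    Each integer-year stratum contributes ~val_fraction of its rows to the
    validation side (at least one when it has two or more rows).
    """
    years = np.floor(ages).astype(int)
    tr_idx, val_idx = [], []
    for year in np.unique(years):
        members = np.flatnonzero(years == year)
        members = members[rng.permutation(members.size)]
        n_val = int(round(val_fraction * members.size))
        if members.size >= 2:
            n_val = min(max(n_val, 1), members.size - 1)
        else:
            n_val = 0
        val_idx.extend(members[:n_val])
        tr_idx.extend(members[n_val:])
    return np.sort(np.array(tr_idx, dtype=int)), np.sort(np.array(val_idx, dtype=int))


def fit_mgrf(F, y, cfg: GAConfig | None = None, grid: HyperGrid | None = None,
             val_fraction: float = 0.25) -> OptimizedForest:
    """Fit the MG-RF regressor on a feature matrix and ages.

    The rows are split internally (seeded, stratified by integer
    age-year) into a GA-train and GA-validation part; the GA evolves
    chromosomes against validation error, and the best-ever chromosome's
    decoded forest is refitted on all rows with its retention mask
    applied. ``ga_history`` records best-ever and population-mean fitness
    per generation; with elitism >= 1 the best series is non-increasing.
    """
    cfg = cfg or GAConfig()
    grid = grid or HyperGrid()
    X = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("feature matrix and age vector lengths differ")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 rows for the internal GA split")

    rng = np.random.default_rng(cfg.rng_seed)
    tr_idx, val_idx = _stratified_val_split(y, val_fraction, rng)
    evaluator = _FitnessEvaluator(X[tr_idx], y[tr_idx], X[val_idx], y[val_idx], grid, cfg)

    population = init_population(cfg, grid, rng)
    history: list[dict] = []
    best_c: Chromosome | None = None
    best_fit = np.inf
    for _ in range(cfg.generations):
        fits = np.array([evaluator(c) for c in population])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_c = population[gen_best]
        history.append({"best": best_fit, "mean": float(fits.mean())})
        if cfg.fitness_threshold is not None and best_fit <= cfg.fitness_threshold:
            break
        population = evolve_generation(population, fits, cfg, grid, rng)

    spec, retained = decode_chromosome(best_c, grid)
    forest = RandomForestRegressor(
        **_sklearn_params(spec), random_state=cfg.rng_seed, n_jobs=1
    )
    forest.fit(X, y)
    ranking, scores = rank_features(X, y, seed=cfg.rng_seed)
    return OptimizedForest(
        model_spec=spec,
        forest=forest,
        retained=retained,
        feature_ranking=ranking,
        importance_scores=scores,
        ga_history=history,
        best_chromosome=best_c,
        best_fitness=best_fit,
        n_features=X.shape[1],
    )


def predict_ages(model: OptimizedForest, F) -> np.ndarray:
    """Predict ages (years) as the mean over the retained trees."""
    X = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else '?'} does not match "
            f"training width {model.n_features}"
        )
    if X.shape[0] == 0:
        return np.empty(0)
    return _masked_mean_prediction(model.forest, X, model.retained)
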