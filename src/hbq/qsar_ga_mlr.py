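"""OLS regression of percent inhibition on selected distance variables, and
genetic-algorithm search over fixed-cardinality variable subsets with the
in-fit coefficient of determination as fitness.

The regression is deliberately descriptive: no validation split, no
regularization. R² and RMSE are computed in fitting over the training rows.
An exhaustive enumerator over all k-subsets serves as the search oracle for
small catalogs; the GA handles the combinatorially large ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .hbond_features import FeatureMatrix, VariableKey

__all__ = [
    "MLRFit",
    "SubsetSelection",
    "GAConfig",
    "SignReport",
    "SignEntry",
    "CollinearityError",
    "fit_mlr",
    "exhaustive_select",
    "ga_select",
    "sign_report",
]


class CollinearityError(ValueError):
    """The design matrix for the requested subset is rank deficient."""


@dataclass
class MLRFit:
    intercept: float
    coefficients: dict[VariableKey, float]
    r_squared: float
    rmse: float
    predictions: dict[str, float]

    @property
    def subset(self) -> tuple[VariableKey, ...]:
        return tuple(self.coefficients)


@dataclass
class SubsetSelection:
    variable_indices: tuple[VariableKey, ...]
    fitness: float
    fit: MLRFit
    trace: list[float] = field(default_factory=list)  # best-ever R² per generation


@dataclass
class GAConfig:
    k: int = 8
    population_size: int = 100
    generations: int = 200
    mutation_rate: float = 0.1
    elitism_count: int = 1
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass(frozen=True)
class SignEntry:
    variable: VariableKey
    coefficient: float
    sign: str  # "+", "-" or "0"
    tag: str | None

    @property
    def rendered(self) -> str:
        return self.variable.rendered


@dataclass
class SignReport:
    entries: list[SignEntry]

    def __iter__(self):
        return iter(self.entries)


#: Interpretation attached to each coefficient sign: a negative coefficient
#: rewards short (strong) bonds; a positive one rewards long/absent contact.
SIGN_TAGS = {
    "-": "short-bond-favors-activity",
    "+": "no-interaction-favors-activity",
    "0": None,
}


def _design(matrix: FeatureMatrix, cols: tuple[int, ...]) -> np.ndarray:
    X = matrix.values[:, list(cols)]
    return np.column_stack([np.ones(matrix.n_rows), X])


def _check_rank(matrix: FeatureMatrix, cols: tuple[int, ...]) -> None:
    X = _design(matrix, cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify columns whose removal restores full rank
        culprits = []
        for drop in range(len(cols)):
            rest = cols[:drop] + cols[drop + 1:]
            if np.linalg.matrix_rank(_design(matrix, rest)) == len(rest) + 1:
                culprits.append(matrix.variables[cols[drop]].label)
        names = ", ".join(culprits) if culprits else "unidentified"
        raise CollinearityError(f"rank-deficient design; collinear columns: {names}")


def fit_mlr(matrix: FeatureMatrix, subset) -> MLRFit:
    """OLS with intercept of I% on the given subset of distance variables.

    ``subset`` may contain VariableKeys, "Vj" labels or rendered residue
    keys. R² = 1 - SS_res/SS_tot (0 when the response is constant); RMSE is
    the in-fit root mean squared residual.
    """
    cols = tuple(matrix.column_index(s) for s in subset)
    if len(set(cols)) != len(cols):
        raise ValueError("subset contains duplicate variables")
    if matrix.n_rows < len(cols) + 2:
        raise ValueError(
            f"need at least {len(cols) + 2} rows for {len(cols)} variables, "
            f"have {matrix.n_rows}")
    _check_rank(matrix, cols)

    X = _design(matrix, cols)
    y = matrix.response
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    variables = [matrix.variables[c] for c in cols]
    return MLRFit(
        intercept=float(beta[0]),
        coefficients={v: float(b) for v, b in zip(variables, beta[1:])},
        r_squared=r_squared,
        rmse=rmse,
        predictions={rid: float(p) for rid, p in zip(matrix.row_ids, yhat)},
    )


def _fitness(matrix: FeatureMatrix, cols: tuple[int, ...],
             cache: dict[tuple[int, ...], float]) -> float:
    """In-fit R² of the OLS on the given columns; -inf for singular designs."""
    cached = cache.get(cols)
    if cached is not None:
        return cached
    X = _design(matrix, cols)
    y = matrix.response
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        score = -np.inf
    else:
        ss_res = float(np.sum((y - X @ beta) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        score = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    cache[cols] = score
    return score


def exhaustive_select(matrix: FeatureMatrix, k: int,
                      enumeration_cap: int = 500_000) -> SubsetSelection:
    """Evaluate every k-subset and return the best by R² (ties broken by
    lexicographically smallest column tuple)."""
    p = matrix.n_variables
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}]")
    n_subsets = math.comb(p, k)
    if n_subsets > enumeration_cap:
        raise ValueError(
            f"C({p},{k}) = {n_subsets} exceeds the enumeration cap "
            f"({enumeration_cap}); use ga_select instead")
    if matrix.n_rows < k + 2:
        raise ValueError("too few rows for the requested subset size")

    cache: dict[tuple[int, ...], float] = {}
    best_cols: tuple[int, ...] | None = None
    best_score = -np.inf
    for cols in itertools.combinations(range(p), k):
        score = _fitness(matrix, cols, cache)
        if score > best_score:  # first (lexicographically smallest) wins ties
            best_score, best_cols = score, cols
    if best_cols is None or not np.isfinite(best_score):
        raise CollinearityError("every candidate subset was rank deficient")
    variables = tuple(matrix.variables[c] for c in best_cols)
    return SubsetSelection(variable_indices=variables, fitness=best_score,
                           fit=fit_mlr(matrix, variables))


def ga_select(matrix: FeatureMatrix, config: GAConfig) -> SubsetSelection:
    """Genetic-algorithm search over fixed-size variable subsets.

    Individuals are k-subsets of column indices. Each generation applies
    tournament selection, cardinality-preserving uniform crossover (keep the
    intersection, refill from the parents' symmetric difference), per-gene
    swap mutation, and elitism. Returns the best-ever subset with its fit
    and the per-generation best-ever fitness trace.
    """
    p = matrix.n_variables
    k = config.k
    if k > p:
        raise ValueError(f"k = {k} exceeds the number of variables ({p})")
    if matrix.n_rows < k + 2:
        raise ValueError("too few rows for the requested subset size")

    rng = np.random.default_rng(config.seed)
    cache: dict[tuple[int, ...], float] = {}

    def random_subset() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(p, size=k, replace=False).tolist()))

    def crossover(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
        keep = set(a) & set(b)
        pool = list(set(a) ^ set(b))
        rng.shuffle(pool)
        child = list(keep) + pool[: k - len(keep)]
        return tuple(sorted(child))

    def mutate(ind: tuple[int, ...]) -> tuple[int, ...]:
        genes = list(ind)
        outside = [v for v in range(p) if v not in ind]
        for i in range(k):
            if outside and rng.random() < config.mutation_rate:
                j = int(rng.integers(len(outside)))
                genes[i], outside[j] = outside[j], genes[i]
        return tuple(sorted(genes))

    def tournament(pop: list[tuple[int, ...]], scores: list[float]) -> tuple[int, ...]:
        idx = rng.integers(len(pop), size=config.tournament_size)
        best = max(idx, key=lambda i: scores[i])
        return pop[best]

    population = [random_subset() for _ in range(config.population_size)]
    best_ind: tuple[int, ...] | None = None
    best_score = -np.inf
    trace: list[float] = []

    for _ in range(config.generations):
        scores = [_fitness(matrix, ind, cache) for ind in population]
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_score:
            best_score = scores[gen_best]
            best_ind = population[gen_best]
        trace.append(best_score)

        elite = [population[i] for i in
                 sorted(range(len(scores)), key=lambda i: -scores[i])
                 [: config.elitism_count]]
        offspring = list(elite)
        while len(offspring) < config.population_size:
            parent_a = tournament(population, scores)
            parent_b = tournament(population, scores)
            offspring.append(mutate(crossover(parent_a, parent_b)))
        population = offspring

    # final population may contain an unevaluated improvement
    for ind in population:
        score = _fitness(matrix, ind, cache)
        if score > best_score:
            best_score, best_ind = score, ind
    if best_ind is None or not np.isfinite(best_score):
        raise CollinearityError("GA found no full-rank subset")
    variables = tuple(matrix.variables[c] for c in best_ind)
    return SubsetSelection(variable_indices=variables, fitness=best_score,
                           fit=fit_mlr(matrix, variables), trace=trace)


def sign_report(fit: MLRFit) -> SignReport:
    """Coefficient signs with their mechanistic reading: negative means the
    bond should be short (strong) for activity, positive means the contact
    should be long or absent."""
    entries = []
    for var, coef in fit.coefficients.items():
        sign = "0" if coef == 0 else ("+" if coef > 0 else "-")
        entries.append(SignEntry(variable=var, coefficient=coef, sign=sign,
                                 tag=SIGN_TAGS[sign]))
    return SignReport(entries=entries)
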