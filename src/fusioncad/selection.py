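"""Feature selection: GA wrapper, kNN mutual information, fusion, undersampling.

Two complementary selectors run on the same hybrid feature table:

* :func:`ga_select` -- a wrapper selector. Individuals are binary gene
  strings over the feature columns; fitness is the mean 5-fold
  cross-validated accuracy of a decision tree restricted to the genes set.
  Survivor selection is the elitist (mu + lambda) strategy: parents and
  offspring pooled, best mu retained, so best fitness never decreases.
  Crossover exchanges a contiguous block at the midpoint; mutation flips
  genes independently.
* :func:`mi_scores` -- a filter selector. Per-feature mutual information with
  the class label, estimated by the k-nearest-neighbour (Chebyshev-distance)
  estimator in its mixed continuous/discrete form: for each sample, the
  distance to its k-th neighbour *within its own class* defines a radius,
  neighbours within that radius in the full sample are counted, and the
  digamma identity combines the counts. Negative estimates are clamped to 0.

:func:`fuse_selections` concatenates the two selected column sets (duplicates
retained), and :func:`random_undersample` balances classes by seeded
without-replacement downsampling to the minority count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from .data import FeatureTable

_JITTER = 1e-10


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters (defaults follow the study setup)."""

    population_size: int = 500
    crossover_fraction: float = 0.5
    mutation_rate: float = 0.05
    mu: int = 50
    lam: int = 100
    max_generations: int = 35
    patience: int = 5
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 < self.crossover_fraction < 1:
            raise ValueError("crossover_fraction must lie in (0, 1)")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.mu < 1 or self.lam < 1:
            raise ValueError("mu and lam must be >= 1")


@dataclass(frozen=True)
class SelectionMask:
    """Boolean keep-vector over feature columns plus per-column scores."""

    keep: np.ndarray
    scores: np.ndarray
    method: str  # "GA" or "MI"

    def __post_init__(self) -> None:
        if len(self.keep) != len(self.scores):
            raise ValueError("keep and scores must have equal length")

    @property
    def n_selected(self) -> int:
        return int(np.asarray(self.keep).sum())

    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep)


def _fitness(
    genes: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    cv_folds: int,
    seed: int,
    cache: dict[bytes, float],
) -> float:
    key = genes.tobytes()
    if key in cache:
        return cache[key]
    if not genes.any():
        cache[key] = 0.0
        return 0.0
    clf = DecisionTreeClassifier(random_state=seed)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    score = float(cross_val_score(clf, x[:, genes], y, cv=cv, scoring="accuracy").mean())
    cache[key] = score
    return score


def ga_select(table: FeatureTable, config: GAConfig | None = None) -> SelectionMask:
    """Wrapper feature selection by an elitist (mu+lambda) genetic algorithm.

    Returns the best individual's gene vector as the keep mask; scores are
    each column's inclusion frequency in the final surviving population.
    Fully reproducible from ``config.seed``.
    """
    config = config or GAConfig()
    x, y = table.x(), table.y()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n_feat = table.n_features
    rng = np.random.default_rng(config.seed)
    cache: dict[bytes, float] = {}

    def fit_of(genes: np.ndarray) -> float:
        return _fitness(genes, x, y, config.cv_folds, config.seed, cache)

    pop = rng.random((config.population_size, n_feat)) < 0.5
    if n_feat == 1:
        pop[:] = True  # single feature: the only useful genome
    fits = np.array([fit_of(g) for g in pop])

    cut = int(round(n_feat * config.crossover_fraction))
    best_fit = -np.inf
    stall = 0
    for _gen in range(config.max_generations):
        order = np.argsort(-fits, kind="stable")
        parents = pop[order[: config.mu]]
        parent_fits = fits[order[: config.mu]]
        gen_best = parent_fits[0]
        if gen_best > best_fit + 1e-12:
            best_fit = gen_best
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
        children = np.empty((config.lam, n_feat), dtype=bool)
        for i in range(config.lam):
            a, b = rng.choice(len(parents), size=2, replace=len(parents) < 2)
            child = np.concatenate([parents[a, :cut], parents[b, cut:]])
            flips = rng.random(n_feat) < config.mutation_rate
            children[i] = child ^ flips
        child_fits = np.array([fit_of(g) for g in children])
        pop = np.vstack([parents, children])  # (mu + lambda) pool
        fits = np.concatenate([parent_fits, child_fits])

    order = np.argsort(-fits, kind="stable")
    survivors = pop[order[: config.mu]]
    best = pop[order[0]]
    return SelectionMask(
        keep=best.copy(), scores=survivors.mean(axis=0), method="GA"
    )


def _mi_discrete_feature(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Mixed continuous/discrete kNN MI estimate for one feature vs labels."""
    n = len(x)
    classes, class_idx = np.unique(y, return_inverse=True)
    m_terms = np.empty(n)
    n_c_terms = np.empty(n)
    dist = np.abs(x[:, None] - x[None, :])  # 1-D Chebyshev = absolute difference
    for ci, _c in enumerate(classes):
        members = np.flatnonzero(class_idx == ci)
        d_cls_sorted = np.sort(dist[np.ix_(members, members)], axis=1)
        # column 0 is self (distance 0); k-th same-class neighbour radius
        radius = d_cls_sorted[:, k]
        for row, i in enumerate(members):
            # count of points strictly inside the radius, the point itself
            # included (the digamma-identity convention)
            m_terms[i] = np.count_nonzero(dist[i] < radius[row])
            n_c_terms[i] = len(members)
    est = (
        digamma(n)
        + digamma(k)
        - np.mean(digamma(n_c_terms))
        - np.mean(digamma(np.maximum(m_terms, 1)))
    )
    return float(est)


def mi_scores(table: FeatureTable, k: int = 3, seed: int = 0) -> np.ndarray:
    """Per-feature mutual information (nats) with the class label, kNN estimator.

    Constant features score 0; small seeded jitter breaks ties; negative
    estimates are clamped to 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.array(list(table.class_counts().values()))
    if (counts <= k).any():
        raise ValueError("k must be smaller than every class count")
    x, y = table.x(), table.y()
    rng = np.random.default_rng(seed)
    scores = np.zeros(table.n_features)
    for j in range(table.n_features):
        col = x[:, j]
        scale = np.max(np.abs(col))
        if scale == 0 or np.ptp(col) == 0:
            continue  # constant feature carries no information
        jittered = col + _JITTER * scale * rng.standard_normal(len(col))
        scores[j] = max(_mi_discrete_feature(jittered, y, k), 0.0)
    return scores


def ksg_mi(x: np.ndarray, y: np.ndarray, k: int = 3) -> float:
    """Continuous-continuous kNN (Chebyshev) MI estimate, in nats.

    The joint-space radius is the Chebyshev distance to the k-th neighbour;
    marginal neighbour counts within that radius enter through digamma terms.
    Used as the estimator core check against the Gaussian closed form.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    dx = np.abs(x[:, None] - x[None, :])
    dy = np.abs(y[:, None] - y[None, :])
    dz = np.maximum(dx, dy)
    np.fill_diagonal(dz, np.inf)
    radius = np.sort(dz, axis=1)[:, k - 1]
    nx = (dx < radius[:, None]).sum(axis=1) - 1
    ny = (dy < radius[:, None]).sum(axis=1) - 1
    est = digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    return max(float(est), 0.0)


def select_top_k(scores: np.ndarray, k: int) -> SelectionMask:
    """Keep the k highest-scoring features; ties broken by lower column index."""
    scores = np.asarray(scores, dtype=float)
    if k > len(scores):
        raise ValueError(f"k={k} exceeds feature count {len(scores)}")
    order = np.argsort(-scores, kind="stable")  # stable: lower index wins ties
    keep = np.zeros(len(scores), dtype=bool)
    keep[order[:k]] = True
    return SelectionMask(keep=keep, scores=scores, method="MI")


def fuse_selections(
    table: FeatureTable, ga: SelectionMask, mi: SelectionMask
) -> FeatureTable:
    """Concatenate GA-selected then MI-selected columns (duplicates retained).

    Column names are suffixed by the selecting method so the output stays
    unique even when both selectors pick the same feature; the output width
    is always |GA kept| + |MI kept|.
    """
    for mask in (ga, mi):
        if len(mask.keep) != table.n_features:
            raise ValueError("selection mask length does not match the table")
    cols = table.values.columns
    parts = []
    for mask, tag in ((ga, "ga"), (mi, "mi")):
        sub = table.values.iloc[:, mask.selected_indices()].copy()
        sub.columns = [f"{c}_{tag}" for c in sub.columns]
        parts.append(sub)
    fused = pd.concat(parts, axis=1)
    return FeatureTable(fused, table.labels.copy())


def random_undersample(table: FeatureTable, seed: int = 0) -> FeatureTable:
    """Downsample every class (without replacement) to the minority count."""
    counts = table.class_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes to balance")
    if min(counts.values()) == 0:
        raise ValueError("empty class")
    m = min(counts.values())
    rng = np.random.default_rng(seed)
    chosen = []
    for label in sorted(counts):
        idx = np.flatnonzero(table.labels == label)
        chosen.append(rng.choice(idx, size=m, replace=False))
    keep = np.concatenate(chosen)
    rng.shuffle(keep)
    return table.subset_rows(keep)
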