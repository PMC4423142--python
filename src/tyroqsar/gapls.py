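"""Genetic-algorithm descriptor selection with PLS regression fitness.

Each chromosome is a binary inclusion vector over the descriptor pool. Its
fitness is the leave-n-out cross-validated Q² of a PLS model on the encoded
subset (component count chosen internally by the same cross-validation),
minus a small sparsity penalty per selected descriptor — implementing the
preference for the smallest subsets with the highest fitness. The GA uses
tournament selection, single-point crossover, per-gene mutation and elitism,
and is bit-reproducible for a fixed seed.

PLS fitting is delegated to scikit-learn's NIPALS implementation; the fitted
model is exposed both in latent form and as collapsed original-space
coefficients (the shape of the published GA-PLS equation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "Chromosome",
    "GAConfig",
    "PLSModel",
    "pls_fit",
    "pls_cv_q2",
    "ga_select",
]


@dataclass
class PLSModel:
    """A fitted PLS model with its collapsed linear-equation form."""

    names: list[str]
    n_components: int
    coef: np.ndarray          # original-space coefficients
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    estimator: PLSRegression | None = None

    @property
    def k(self) -> int:
        return len(self.names)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        vals = X[self.names].to_numpy(dtype=float)
        return pd.Series(vals @ self.coef + self.intercept, index=X.index)

    def predict_latent(self, X: pd.DataFrame) -> np.ndarray:
        """Prediction through the latent scores path (consistency check)."""
        if self.estimator is None:
            raise ValueError("latent estimator not retained")
        return self.estimator.predict(X[self.names].to_numpy(dtype=float)).ravel()


def pls_fit(X: pd.DataFrame, y: pd.Series, n_components: int) -> PLSModel:
    """Fit a PLS1 model with the given number of latent components.

    Columns are centered internally (no scaling, matching models built on raw
    descriptor values). ``n_components`` must not exceed min(n−1, p).
    """
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    yv = y.loc[X.index].to_numpy(dtype=float)
    n, p = Xv.shape
    if np.std(yv) == 0:
        raise ValueError("activity vector has zero variance")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in 1..min(n-1, p) = {min(n - 1, p)}")
    est = PLSRegression(n_components=n_components, scale=False)
    est.fit(Xv, yv)
    coef = est.coef_.ravel().astype(float)
    intercept = float(yv.mean() - Xv.mean(axis=0) @ coef)
    return PLSModel(names, n_components, coef, intercept,
                    Xv.mean(axis=0), float(yv.mean()), est)


def _fold_indices(n: int, leave_n: int) -> list[np.ndarray]:
    if not 1 <= leave_n < n:
        raise ValueError("leave_n must be in 1..n-1")
    idx = np.arange(n)
    return [idx[k:k + leave_n] for k in range(0, n, leave_n)]


def pls_cv_q2(X: pd.DataFrame, y: pd.Series, n_components: int,
              leave_n: int = 1) -> float:
    """Leave-n-out cross-validated Q² = 1 − PRESS/Σ(y−ȳ)² for a PLS model.

    Consecutive groups of ``leave_n`` rows are deleted in turn and predicted
    from a refit on the remainder.
    """
    Xv = X.to_numpy(dtype=float)
    yv = y.loc[X.index].to_numpy(dtype=float)
    n = len(yv)
    folds = _fold_indices(n, leave_n)
    smallest_train = n - max(len(f) for f in folds)
    if n_components > min(smallest_train - 1, Xv.shape[1]):
        raise ValueError("more components than the smallest training fold allows")
    press = 0.0
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        est = PLSRegression(n_components=n_components, scale=False)
        est.fit(Xv[mask], yv[mask])
        pred = est.predict(Xv[fold]).ravel()
        press += float(np.sum((yv[fold] - pred) ** 2))
    tss = float(np.sum((yv - yv.mean()) ** 2))
    return 1.0 - press / tss


@dataclass(frozen=True)
class Chromosome:
    """Binary descriptor-inclusion vector with its evaluated fitness."""

    genes: tuple
    fitness: float

    @property
    def n_selected(self) -> int:
        return int(sum(self.genes))


@dataclass
class GAConfig:
    """Hyperparameters of the GA-PLS selection run.

    Population size defaults to 100 and is validated against the 80–125 band
    used in the original runs unless ``enforce_population_band`` is off
    (convenient for small test problems). Mutation probability defaults to
    1/pool size; the initial gene-on probability is low (0.1) so starting
    subsets are sparse.
    """

    population_size: int = 100
    generations: int = 100
    crossover_prob: float = 0.9
    mutation_prob: float | None = None
    elitism: int = 2
    tournament_size: int = 2
    leave_n: int = 1
    max_components: int = 5
    init_gene_prob: float = 0.1
    sparsity_penalty: float = 0.005
    seed: int | None = None
    enforce_population_band: bool = True

    def __post_init__(self) -> None:
        if self.enforce_population_band and not 80 <= self.population_size <= 125:
            raise ValueError("population size outside the 80–125 band "
                             "(set enforce_population_band=False to override)")
        for p in (self.crossover_prob, self.init_gene_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GATrace:
    """Per-generation best fitness and subset size."""

    table: pd.DataFrame


def _subset_fitness(Xv: np.ndarray, yv: np.ndarray, genes: np.ndarray,
                    cfg: GAConfig) -> tuple[float, int]:
    k = int(genes.sum())
    if k == 0:
        return -np.inf, 0
    sub = Xv[:, genes]
    n = len(yv)
    folds = _fold_indices(n, cfg.leave_n)
    smallest_train = n - max(len(f) for f in folds)
    max_a = min(cfg.max_components, k, smallest_train - 1, n - 2)
    if max_a < 1:
        return -np.inf, 0
    tss = float(np.sum((yv - yv.mean()) ** 2))
    best_q2, best_a = -np.inf, 1
    for a in range(1, max_a + 1):
        press = 0.0
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            est = PLSRegression(n_components=a, scale=False)
            est.fit(sub[mask], yv[mask])
            press += float(np.sum((yv[fold] - est.predict(sub[fold]).ravel()) ** 2))
        q2 = 1.0 - press / tss
        if q2 > best_q2:
            best_q2, best_a = q2, a
    return best_q2 - cfg.sparsity_penalty * k, best_a


def ga_select(X: pd.DataFrame, y: pd.Series,
              config: GAConfig | None = None) -> tuple[Chromosome, PLSModel, GATrace]:
    """Run the GA over the descriptor pool and refit the best subset.

    Returns the best-ever chromosome, the PLS model refitted on its subset
    with the cross-validation-chosen component count, and the per-generation
    trace. Elitism guarantees the best-ever fitness is non-decreasing.
    """
    cfg = config or GAConfig()
    if X.shape[1] == 0:
        raise ValueError("descriptor pool is empty")
    rng = np.random.default_rng(cfg.seed)
    Xv = X.to_numpy(dtype=float)
    yv = y.loc[X.index].to_numpy(dtype=float)
    pool = X.shape[1]
    pm = cfg.mutation_prob if cfg.mutation_prob is not None else 1.0 / pool
    cache: dict[bytes, tuple[float, int]] = {}

    def fitness(genes: np.ndarray) -> tuple[float, int]:
        key = np.packbits(genes).tobytes()
        if key not in cache:
            cache[key] = _subset_fitness(Xv, yv, genes, cfg)
        return cache[key]

    pop = rng.random((cfg.population_size, pool)) < cfg.init_gene_prob
    for row in pop:  # guarantee at least one active gene
        if not row.any():
            row[rng.integers(pool)] = True
    fits = np.array([fitness(g)[0] for g in pop])
    best_idx = int(np.argmax(fits))
    best_genes, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    trace_rows = [{"generation": 0, "best_fitness": best_fit,
                   "best_n_selected": int(best_genes.sum())}]
    for gen in range(1, cfg.generations + 1):
        order = np.argsort(-fits, kind="stable")
        new = [pop[i].copy() for i in order[:cfg.elitism]]
        while len(new) < cfg.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
                parents.append(pop[contenders[np.argmax(fits[contenders])]].copy())
            a, b = parents
            if pool > 1 and rng.random() < cfg.crossover_prob:
                cut = int(rng.integers(1, pool))
                a = np.concatenate([a[:cut], b[cut:]])
            flip = rng.random(pool) < pm
            a = np.logical_xor(a, flip)
            new.append(a)
        pop = np.array(new[:cfg.population_size])
        fits = np.array([fitness(g)[0] for g in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit, best_genes = float(fits[gen_best]), pop[gen_best].copy()
        trace_rows.append({"generation": gen, "best_fitness": best_fit,
                           "best_n_selected": int(best_genes.sum())})
    _, best_a = fitness(best_genes)
    names = [c for c, g in zip(X.columns, best_genes) if g]
    model = pls_fit(X[names], y, best_a)
    chrom = Chromosome(tuple(bool(g) for g in best_genes), best_fit)
    return chrom, model, GATrace(pd.DataFrame(trace_rows))
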