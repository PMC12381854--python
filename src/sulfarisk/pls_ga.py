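"""Partial least squares (PLS1, NIPALS) and genetic-algorithm variable selection.

The PLS model extracts latent components sequentially by NIPALS deflation and
keeps the smallest number of components whose cumulative explained fraction of
descriptor (X) variance reaches a threshold (default 85%), capped by the rank
bound min(n_train - 1, n_descriptors).

The genetic algorithm searches binary descriptor-inclusion chromosomes for the
subset minimizing the leave-one-out standard error of cross-validation (SEV,
J/g), with rank-proportional parent selection, contiguous-span crossover,
per-bit mutation, purge-and-replace of the weakest fraction, and elitist
retention of the single best chromosome.  The study-scale sizing rule is
population = 50 × p and generations = 20 × p (3550 and 1420 at p = 71); both
are overridable for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .feature_schema import FeatureTable
from .preprocessing import prepare_fold_arrays

__all__ = [
    "PlsModel",
    "GaConfig",
    "GaResult",
    "ga_sizing",
    "fit_pls",
    "predict_pls",
    "loo_sev",
    "ga_select",
]


@dataclass
class PlsModel:
    """Fitted PLS1 model in the (already scaled) descriptor space."""

    weights: np.ndarray           # W, p × k
    x_loadings: np.ndarray        # P, p × k
    y_loadings: np.ndarray        # q, k
    coef: np.ndarray              # regression vector b, p
    y_mean: float
    n_components: int
    cum_x_variance: np.ndarray    # cumulative X-variance fractions, length k

    def to_dict(self) -> dict:
        return {
            "n_components": int(self.n_components),
            "y_mean": float(self.y_mean),
            "coef": [float(c) for c in self.coef],
            "cum_x_variance": [float(v) for v in self.cum_x_variance],
        }


def fit_pls(X: np.ndarray, y: np.ndarray, variance_threshold: float = 0.85,
            max_components: int | None = None) -> PlsModel:
    """Fit single-response PLS on a scaled descriptor matrix.

    ``y`` is given in original units and centered internally; the number of
    components is the smallest k whose cumulative explained X-variance
    reaches ``variance_threshold``, capped by min(n - 1, p).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PLS requires at least 2 rows")
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")

    y_mean = float(y.mean())
    Xd = X.copy()
    yd = y - y_mean
    total_ss = float((Xd * Xd).sum())
    cap = min(n - 1, p)
    if max_components is not None:
        cap = min(cap, max_components)

    W, P, Q, cumvar = [], [], [], []
    explained = 0.0
    for _ in range(cap):
        w = Xd.T @ yd
        nw = float(np.linalg.norm(w))
        if nw < 1e-12:          # response residual orthogonal to X (or zero)
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pl = (Xd.T @ t) / tt
        q = float(yd @ t) / tt
        Xd -= np.outer(t, pl)
        yd = yd - q * t
        W.append(w)
        P.append(pl)
        Q.append(q)
        explained += tt * float(pl @ pl) / total_ss if total_ss > 0 else 0.0
        cumvar.append(min(explained, 1.0))
        if explained >= variance_threshold:
            break

    k = len(W)
    if k == 0:
        return PlsModel(np.zeros((p, 0)), np.zeros((p, 0)), np.zeros(0),
                        np.zeros(p), y_mean, 0, np.zeros(0))
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    qv = np.array(Q)
    coef = Wm @ np.linalg.solve(Pm.T @ Wm, qv)
    return PlsModel(Wm, Pm, qv, coef, y_mean, k, np.array(cumvar))


def predict_pls(model: PlsModel, X_new: np.ndarray, clip_negative: bool = True
                ) -> np.ndarray:
    """Predict responses (original units); negative enthalpies floored at 0."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.coef.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.coef.shape[0]}")
    yhat = model.y_mean + X_new @ model.coef
    if clip_negative:
        yhat = np.maximum(yhat, 0.0)
    return yhat


class _LooFolds:
    """Per-fold imputed & scaled matrices, computed once and reused.

    Imputation and autoscaling are column-wise, so the scaled submatrix for a
    descriptor subset equals the subset of the scaled full matrix; caching the
    per-fold full matrices makes repeated subset evaluations (the GA fitness)
    cheap without changing the leakage-free per-fold protocol.
    """

    def __init__(self, X_raw: np.ndarray, y: np.ndarray):
        n = X_raw.shape[0]
        idx = np.arange(n)
        self.folds = []
        for i in range(n):
            tr = idx != i
            Xt, Xo, _, _ = prepare_fold_arrays(X_raw[tr], X_raw[i:i + 1])
            self.folds.append((Xt, Xo[0], y[tr], y[i]))

    def sev(self, cols, variance_threshold: float) -> float:
        res = np.empty(len(self.folds))
        for k, (Xt, xo, yt, yi) in enumerate(self.folds):
            model = fit_pls(Xt[:, cols], yt, variance_threshold)
            pred = model.y_mean + xo[cols] @ model.coef
            if pred < 0.0:
                pred = 0.0
            res[k] = pred - yi
        return float(np.sqrt(np.mean(np.square(res))))


def _loo_sev_arrays(X_raw: np.ndarray, y: np.ndarray,
                    variance_threshold: float = 0.85) -> float:
    """LOO SEV on raw (possibly gapped) arrays with per-fold impute/scale."""
    cols = np.arange(X_raw.shape[1])
    return _LooFolds(X_raw, y).sev(cols, variance_threshold)


def loo_sev(table: FeatureTable, subset: Sequence[str],
            variance_threshold: float = 0.85) -> float:
    """Leave-one-out SEV (J/g) of a PLS model on the training rows restricted
    to the given descriptor subset.  Imputer and scaler are refitted within
    every fold; held-out predictions are clipped at 0 J/g."""
    subset = list(subset)
    if not subset:
        raise ValueError("descriptor subset must be non-empty")
    train = table.train
    if len(train) < 3:
        raise ValueError("LOO SEV requires at least 3 training rows")
    return _loo_sev_arrays(train.X(subset), train.y_per_gram, variance_threshold)


@dataclass
class GaConfig:
    """Genetic-algorithm settings (study operator rates as defaults)."""

    population_multiplier: int = 50
    generation_multiplier: int = 20
    population_size: int | None = None    # override for desk-scale runs
    n_generations: int | None = None
    crossover_rate: float = 0.70
    mutation_rate: float = 0.04
    purge_rate: float = 0.20
    variance_threshold: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate", "purge_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.population_multiplier < 1 or self.generation_multiplier < 1:
            raise ValueError("multipliers must be >= 1")


def ga_sizing(p: int, config: GaConfig | None = None) -> tuple[int, int]:
    """Population and generation counts implied by the sizing rule for ``p``
    descriptors (50 × p and 20 × p unless overridden)."""
    config = config or GaConfig()
    pop = config.population_size or config.population_multiplier * p
    gens = config.n_generations or config.generation_multiplier * p
    return pop, gens


@dataclass
class GaResult:
    """Outcome of a GA run."""

    best_chromosome: np.ndarray     # boolean inclusion vector
    best_ids: tuple[str, ...]
    best_sev: float
    trace: np.ndarray               # best-so-far SEV per generation
    mean_trace: np.ndarray          # population-mean SEV per generation
    n_evaluations: int


def _random_population(rng: np.random.Generator, size: int, p: int) -> np.ndarray:
    pop = rng.random((size, p)) < 0.5
    for row in pop:
        if not row.any():
            row[rng.integers(p)] = True
    return pop


def ga_select(table: FeatureTable, config: GaConfig | None = None,
              log: Callable[[str], None] | None = None) -> GaResult:
    """Select the descriptor subset minimizing LOO SEV by genetic search."""
    config = config or GaConfig()
    train = table.train
    if len(train) < 3:
        raise ValueError("GA needs at least 3 training rows")
    ids = list(table.registry.ids)
    p = len(ids)
    pop_size, n_gens = ga_sizing(p, config)
    rng = np.random.default_rng(config.seed)

    folds = _LooFolds(train.X(ids), train.y_per_gram)
    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = chrom.tobytes()
        if key not in cache:
            cache[key] = folds.sev(chrom, config.variance_threshold)
        return cache[key]

    pop = _random_population(rng, pop_size, p)
    best_chrom: np.ndarray | None = None
    best_sev = np.inf
    trace, mean_trace = [], []

    n_purge = int(round(config.purge_rate * pop_size))
    n_children = max(0, pop_size - 1 - n_purge)

    for gen in range(n_gens):
        fit = np.array([fitness(c) for c in pop])
        order = np.argsort(fit, kind="stable")
        if fit[order[0]] < best_sev:
            best_sev = float(fit[order[0]])
            best_chrom = pop[order[0]].copy()
        trace.append(best_sev)
        mean_trace.append(float(fit.mean()))
        if log is not None:
            log(f"generation {gen}: best SEV {best_sev:.4f} J/g, "
                f"mean SEV {mean_trace[-1]:.4f} J/g")
        if gen == n_gens - 1:
            break

        # rank-proportional selection probabilities (best gets weight N)
        weights = np.empty(pop_size)
        weights[order] = np.arange(pop_size, 0, -1, dtype=float)
        probs = weights / weights.sum()

        children = np.empty((n_children, p), dtype=bool)
        for c in range(n_children):
            pa, pb = rng.choice(pop_size, size=2, p=probs)
            child = pop[pa].copy()
            if rng.random() < config.crossover_rate:
                i, j = sorted(rng.integers(0, p + 1, size=2))
                child[i:j] = pop[pb, i:j]
            flips = rng.random(p) < config.mutation_rate
            child ^= flips
            if not child.any():
                child[rng.integers(p)] = True
            children[c] = child
        fresh = _random_population(rng, n_purge, p)
        pop = np.vstack([best_chrom[None, :], children, fresh])

    assert best_chrom is not None
    return GaResult(
        best_chromosome=best_chrom,
        best_ids=tuple(i for i, b in zip(ids, best_chrom) if b),
        best_sev=best_sev,
        trace=np.array(trace),
        mean_trace=np.array(mean_trace),
        n_evaluations=len(cache),
    )
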