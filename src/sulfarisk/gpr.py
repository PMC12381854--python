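"""Gaussian-process regression on the per-mol enthalpy scale.

The GP uses a constant + inhomogeneous dot-product + white-noise kernel.  A
dot-product kernel makes the GP equivalent to Bayesian linear regression with
a Gaussian prior on the weights, so the model stays linear in the descriptors
while providing calibrated predictive uncertainty.  Targets are reaction
enthalpies per mol (J/mol): on that scale the descriptor → enthalpy mapping
does not have to encode the molecular weight.  Predictions are converted back
to J/g and floored at 0, with 95% intervals mean ± 1.96·sd.

Feature selection is a reproducible encoding of correlation-guided manual
choice: rank descriptors by |Pearson r| with the per-mol enthalpy on the
training set, drop near-duplicates (pairwise |r| > 0.9 against an already
kept descriptor), guarantee at least one steric (visible-sky / surface-area)
descriptor, and pick the subset size from a small ladder by LOO SEV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, DotProduct, WhiteKernel

from .feature_schema import FeatureTable
from .preprocessing import (
    ImputerState, ScalerState, apply_imputer, apply_scaler,
    fit_imputer, fit_scaler, prepare_fold_arrays,
)

__all__ = [
    "GprModel",
    "GprPrediction",
    "rank_features_by_correlation",
    "select_features_gpr",
    "fit_gpr",
    "predict_gpr",
    "loo_sev_gpr",
]

_LOG_BOUND = 6.0  # optimizer bounds on log-hyperparameters: [-6, 6]
_STERIC_FAMILIES = ("visible_sky", "labute_asa")


def _imputed_train_matrix(train: FeatureTable) -> np.ndarray:
    X, _, _, _ = prepare_fold_arrays(train.X(list(train.registry.ids)))
    return X


def rank_features_by_correlation(table: FeatureTable) -> list[tuple[str, float]]:
    """Descriptors sorted by decreasing |Pearson r| with per-mol enthalpy on
    the training rows; zero-variance descriptors get r = 0."""
    train = table.train
    if len(train) < 3:
        raise ValueError("correlation ranking requires at least 3 training rows")
    ids = list(table.registry.ids)
    X = _imputed_train_matrix(train)
    y = train.y_per_mol
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    out = []
    for j, did in enumerate(ids):
        xc = X[:, j] - X[:, j].mean()
        sx = np.sqrt((xc**2).sum())
        r = 0.0 if sx == 0 or sy == 0 else float(xc @ yc / (sx * sy))
        out.append((did, abs(r)))
    # stable sort keeps registry order among ties
    return sorted(out, key=lambda t: -t[1])


def _make_kernel(constant: float = 1.0, sigma_0: float = 1.0,
                 noise: float = 1.0, fixed: bool = False):
    b = "fixed" if fixed else (np.exp(-_LOG_BOUND), np.exp(_LOG_BOUND))
    return (ConstantKernel(constant, constant_value_bounds=b)
            + DotProduct(sigma_0=sigma_0, sigma_0_bounds=b)
            + WhiteKernel(noise_level=noise, noise_level_bounds=b))


@dataclass
class GprModel:
    """Fitted GP with its preprocessing states and descriptor subset."""

    gp: GaussianProcessRegressor
    subset: tuple[str, ...]
    imputer: ImputerState
    scaler: ScalerState

    @property
    def kernel_params(self) -> dict[str, float]:
        k = self.gp.kernel_
        return {
            "constant": float(k.k1.k1.constant_value),
            "sigma_0": float(k.k1.k2.sigma_0),
            "noise_level": float(k.k2.noise_level),
        }

    def to_dict(self) -> dict:
        return {"subset": list(self.subset), "kernel": self.kernel_params,
                "log_marginal_likelihood": float(self.gp.log_marginal_likelihood_value_)}


@dataclass
class GprPrediction:
    """Posterior predictions per compound, on both enthalpy scales."""

    mean_j_per_mol: np.ndarray
    sd_j_per_mol: np.ndarray
    mean_j_per_g: np.ndarray
    sd_j_per_g: np.ndarray
    lo95_j_per_g: np.ndarray
    hi95_j_per_g: np.ndarray


def fit_gpr(table: FeatureTable, subset: Sequence[str], n_restarts: int = 10,
            seed: int = 0,
            fixed_hyperparameters: dict[str, float] | None = None) -> GprModel:
    """Fit the GP on the training rows restricted to ``subset``.

    Hyperparameters maximize the log marginal likelihood with ``n_restarts``
    random re-initializations (deterministic given ``seed``); passing
    ``fixed_hyperparameters`` skips optimization (used by closed-form
    equivalence checks).
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("descriptor subset must be non-empty")
    train = table.train
    if len(train) < 2:
        raise ValueError("GPR requires at least 2 training rows")

    imputer = fit_imputer(train)
    completed = apply_imputer(imputer, train)
    scaler = fit_scaler(completed)
    scaled = apply_scaler(scaler, completed)
    X = scaled.X(list(subset))
    y = train.y_per_mol

    if fixed_hyperparameters is not None:
        kernel = _make_kernel(fixed=True, **fixed_hyperparameters)
        gp = GaussianProcessRegressor(kernel=kernel, optimizer=None, normalize_y=False)
    else:
        kernel = _make_kernel()
        gp = GaussianProcessRegressor(
            kernel=kernel, n_restarts_optimizer=n_restarts, normalize_y=True,
            random_state=seed)
    gp.fit(X, y)
    return GprModel(gp=gp, subset=subset, imputer=imputer, scaler=scaler)


def predict_gpr(model: GprModel, table: FeatureTable) -> GprPrediction:
    """Posterior mean and sd for the rows of ``table`` (J/mol and J/g).

    Per-gram means and the 95% interval bounds are floored at 0 J/g.
    """
    mw = table.mw
    scaled = apply_scaler(model.scaler, apply_imputer(model.imputer, table))
    X = scaled.X(list(model.subset))
    mean, sd = model.gp.predict(X, return_std=True)
    mean_g_raw = mean / mw
    sd_g = sd / mw
    return GprPrediction(
        mean_j_per_mol=mean,
        sd_j_per_mol=sd,
        mean_j_per_g=np.maximum(mean_g_raw, 0.0),
        sd_j_per_g=sd_g,
        lo95_j_per_g=np.maximum(mean_g_raw - 1.96 * sd_g, 0.0),
        hi95_j_per_g=np.maximum(mean_g_raw + 1.96 * sd_g, 0.0),
    )


def loo_sev_gpr(table: FeatureTable, subset: Sequence[str], n_restarts: int = 1,
                seed: int = 0) -> float:
    """Leave-one-out SEV (J/g) of the GP on the training rows."""
    train = table.train
    n = len(train)
    if n < 3:
        raise ValueError("LOO SEV requires at least 3 training rows")
    residuals = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        fold = train.subset(mask)
        held = train.subset(~mask)
        model = fit_gpr(fold.with_column("split", "train"), subset,
                        n_restarts=n_restarts, seed=seed)
        pred = predict_gpr(model, held)
        residuals[i] = pred.mean_j_per_g[0] - held.y_per_gram[0]
    return float(np.sqrt(np.mean(residuals**2)))


def select_features_gpr(table: FeatureTable, sizes: Sequence[int] = (4, 6, 8),
                        similarity_threshold: float = 0.9, n_restarts: int = 1,
                        seed: int = 0) -> tuple[tuple[str, ...], dict[int, float]]:
    """Correlation-guided reproducible feature selection.

    Returns the winning subset and the LOO SEV per candidate size.
    """
    train = table.train
    ranked = [did for did, _ in rank_features_by_correlation(table)]
    ids = list(table.registry.ids)
    X = _imputed_train_matrix(train)
    col = {did: X[:, ids.index(did)] for did in ids}

    # de-duplicate: keep a descriptor only if not too similar to any kept one
    kept: list[str] = []
    for did in ranked:
        ok = True
        for other in kept:
            a, b = col[did], col[other]
            ac, bc = a - a.mean(), b - b.mean()
            denom = np.linalg.norm(ac) * np.linalg.norm(bc)
            r = 0.0 if denom == 0 else float(ac @ bc / denom)
            if abs(r) > similarity_threshold:
                ok = False
                break
        if ok:
            kept.append(did)

    steric_ids = [did for did in kept
                  if table.registry[did].family in _STERIC_FAMILIES]

    sev_by_size: dict[int, float] = {}
    best_subset: tuple[str, ...] | None = None
    best_sev = np.inf
    for size in sizes:
        subset = kept[:size]
        if steric_ids and not any(s in subset for s in steric_ids):
            subset = subset[:-1] + [steric_ids[0]]  # guarantee a steric term
        sev = loo_sev_gpr(table, subset, n_restarts=n_restarts, seed=seed)
        sev_by_size[size] = sev
        if sev < best_sev:
            best_sev = sev
            best_subset = tuple(subset)
    assert best_subset is not None
    return best_subset, sev_by_size
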