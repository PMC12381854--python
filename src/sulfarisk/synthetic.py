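"""Synthetic study generator.

Emulates the *statistical structure* of the measured sulfamidate data set —
29 compounds, 71 descriptors with correlated within-family blocks, a dense
linear descriptor → enthalpy relationship on the per-mol scale, multiplicative
measurement noise, per-gram enthalpies spanning roughly 0–800 J/g, two missing
bond-dissociation-energy cells, and a 20/9 enthalpy-stratified train/prediction
split.  No actual quantum-chemical physics is simulated: the generator exists
so every downstream modeling stage can be exercised and tested with a known
ground truth.

Enthalpy is generated per mol (intercept + X·β, descriptors ~ unit normal) and
divided by the molecular weight, so a model working on the per-mol scale does
not have to learn the molecular weight.  Rows whose noise-free per-gram value
falls outside the physical target range are redrawn, which keeps the linear
law exact; only the noise-perturbed realized values are clipped into range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_schema import (
    DescriptorSpec, FeatureRegistry, FeatureTable, build_default_registry,
)
from .steric import Conformer, ConformerEnsemble, _radii_for

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generic_registry",
    "generate_study",
    "split_train_predict",
    "generate_conformer_cloud",
]


def generic_registry(p: int, prefix: str = "d") -> FeatureRegistry:
    """Registry of ``p`` anonymous molecule-level descriptors (for simulations
    that do not need the full sulfamidate schema)."""
    return FeatureRegistry([
        DescriptorSpec(id=f"{prefix}{k:02d}", level="molecule", site="none",
                       family="dipole", units="")
        for k in range(1, p + 1)
    ])


@dataclass
class SimConfig:
    """Conditions of the emulated study.

    Defaults mirror the measured data set: 29 compounds with a 20-compound
    training set, per-gram enthalpies confined to 0–800 J/g, ~6% relative
    (triplicate-level) measurement noise, within-family descriptor
    correlation of 0.6, and two missing BDE cells (one in a low-enthalpy
    training compound, one in a prediction compound).
    """

    n_compounds: int = 29
    registry: FeatureRegistry | None = None
    n_informative: int = 5
    informative_effect: float = 25_000.0   # J/mol per unit (scaled) descriptor
    dense_effect_sd: float = 1_500.0       # small dense effects on the rest
    intercept: float = 110_000.0           # J/mol
    block_correlation: float = 0.6
    rel_noise_sd: float = 0.06
    mw_range: tuple[float, float] = (150.0, 400.0)
    target_range: tuple[float, float] = (0.0, 800.0)
    n_train: int = 20
    missing_cells: Sequence[tuple[str, str]] | None = None  # None → study default
    informative_ids: Sequence[str] | None = None            # None → random draw
    seed: int = 0

    def __post_init__(self) -> None:
        if self.registry is None:
            self.registry = build_default_registry()
        if not 2 <= self.n_train < self.n_compounds:
            raise ValueError("need 2 <= n_train < n_compounds")
        if not 0.0 <= self.rel_noise_sd < 1.0:
            raise ValueError("rel_noise_sd must be in [0, 1)")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in [0, 1)")
        if self.n_informative > len(self.registry):
            raise ValueError("n_informative exceeds registry size")
        if self.informative_ids is not None:
            unknown = [i for i in self.informative_ids if i not in self.registry]
            if unknown:
                raise ValueError(f"unknown informative descriptors: {unknown}")
            if len(self.informative_ids) != self.n_informative:
                raise ValueError("informative_ids length must equal n_informative")


@dataclass
class GroundTruth:
    """Generating model behind a synthetic table (per-mol J scale)."""

    coefficients: np.ndarray            # per descriptor, registry order
    intercept: float
    informative_ids: tuple[str, ...]
    per_mol_noise_free: np.ndarray      # before noise/clipping
    per_gram_realized: np.ndarray       # what the table reports

    def to_dict(self, registry: FeatureRegistry) -> dict:
        return {
            "intercept_j_per_mol": self.intercept,
            "coefficients_j_per_mol": dict(zip(registry.ids, map(float, self.coefficients))),
            "informative_ids": list(self.informative_ids),
            "per_mol_noise_free": [float(v) for v in self.per_mol_noise_free],
            "per_gram_realized": [float(v) for v in self.per_gram_realized],
        }


def _family_groups(registry: FeatureRegistry) -> list[np.ndarray]:
    keys: dict[tuple[str, str], list[int]] = {}
    for k, spec in enumerate(registry):
        keys.setdefault((spec.level, spec.family), []).append(k)
    return [np.array(v) for v in keys.values()]


def generate_study(config: SimConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate a feature table plus its ground truth, deterministically."""
    rng = np.random.default_rng(config.seed)
    reg = config.registry
    p = len(reg)
    n = config.n_compounds
    groups = _family_groups(reg)
    rho = config.block_correlation

    # effect sizes: dense small effects everywhere, a few large planted ones
    if config.informative_ids is not None:
        informative = np.array([reg.index_of(i) for i in config.informative_ids], dtype=int)
    else:
        informative = rng.choice(p, size=config.n_informative, replace=False)
    beta = rng.normal(0.0, config.dense_effect_sd, size=p)
    signs = rng.choice([-1.0, 1.0], size=config.n_informative)
    beta[informative] = signs * config.informative_effect

    lo, hi = config.target_range
    X = np.empty((n, p))
    mw = np.empty(n)
    per_mol_clean = np.empty(n)
    for i in range(n):
        for _attempt in range(1000):
            m = rng.uniform(*config.mw_range)
            row = np.empty(p)
            for g in groups:
                shared = rng.normal()
                row[g] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.normal(size=g.size)
            pm = config.intercept + row @ beta
            if lo <= pm / m <= hi:
                break
        else:
            raise RuntimeError("could not draw a row inside target_range; "
                               "check intercept/effect sizes vs target_range")
        X[i], mw[i], per_mol_clean[i] = row, m, pm

    noise = rng.normal(0.0, config.rel_noise_sd, size=n) if config.rel_noise_sd > 0 else np.zeros(n)
    per_gram = np.clip(per_mol_clean * (1.0 + noise) / mw, lo, hi)

    df = pd.DataFrame(X, columns=list(reg.ids))
    df.insert(0, "compound_id", [f"C{i+1:02d}" for i in range(n)])
    df.insert(1, "mw_g_per_mol", mw)
    df.insert(2, "enthalpy_j_per_g", per_gram)
    df.insert(3, "split", pd.Series([None] * n, dtype=object))
    table = FeatureTable(reg, df, validate=False)

    table = split_train_predict(table, config.n_train, rng)

    # missing cells: defaults emulate the study (one BDE gap per set)
    cells = config.missing_cells
    if cells is None:
        cells = _default_missing_cells(table)
    for compound_id, descriptor_id in cells:
        if descriptor_id not in reg:
            raise ValueError(f"unknown descriptor {descriptor_id!r}")
        if not reg[descriptor_id].allow_missing:
            raise ValueError(f"descriptor {descriptor_id!r} does not allow missing values")
        idx = np.flatnonzero(table.df["compound_id"].to_numpy() == compound_id)
        if idx.size != 1:
            raise ValueError(f"unknown compound {compound_id!r}")
        table.df.loc[idx[0], descriptor_id] = np.nan

    truth = GroundTruth(
        coefficients=beta, intercept=config.intercept,
        informative_ids=tuple(reg.ids[k] for k in informative),
        per_mol_noise_free=per_mol_clean, per_gram_realized=per_gram,
    )
    return table, truth


def _default_missing_cells(table: FeatureTable) -> list[tuple[str, str]]:
    reg = table.registry
    if "C(O)_H_abstraction_energy" not in reg or "C(N)_H_abstraction_energy" not in reg:
        return []
    cells = []
    train, pred = table.train.df, table.predict.df
    co_train = train.loc[train["enthalpy_j_per_g"].idxmin(), "compound_id"]
    cells.append((co_train, "C(O)_H_abstraction_energy"))
    cn_pred = pred.loc[pred["enthalpy_j_per_g"].idxmin(), "compound_id"]
    cells.append((cn_pred, "C(N)_H_abstraction_energy"))
    return cells


def split_train_predict(table: FeatureTable, n_train: int,
                        seed: int | np.random.Generator = 0) -> FeatureTable:
    """Enthalpy-stratified split: rows ranked by measured enthalpy, one
    prediction-set member drawn per quantile stratum."""
    n = len(table)
    if not 2 <= n_train < n:
        raise ValueError("need 2 <= n_train < n rows")
    y = table.y_per_gram
    if np.any(~np.isfinite(y)):
        raise ValueError("all compounds need a measured enthalpy to split")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    order = np.argsort(y, kind="stable")
    strata = np.array_split(order, n - n_train)
    predict_rows = np.array([rng.choice(s) for s in strata])
    split = np.full(n, "train", dtype=object)
    split[predict_rows] = "predict"
    df = table.df.copy()
    df["split"] = split
    return FeatureTable(table.registry, df, validate=False)


_CLOUD_ELEMENTS = ("C", "N", "O", "S", "H")


def generate_conformer_cloud(n_atoms: int, seed: int = 0, n_conformers: int = 3,
                             temperature: float = 298.15) -> ConformerEnsemble:
    """Random non-overlapping atom clouds as steric-descriptor fixtures.

    Atom centers are rejection-sampled so every pairwise distance exceeds
    0.55 × the sum of the two vdW radii (strictly more than the 0.5 × bound
    the tests check).  Deterministic given the seed.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    half_box = 1.6 * max(2.0, n_atoms ** (1.0 / 3.0) * 1.8)
    conformers = []
    for _ in range(n_conformers):
        symbols = tuple(rng.choice(_CLOUD_ELEMENTS, size=n_atoms))
        radii = _radii_for(symbols)  # Bondi set
        coords = np.empty((n_atoms, 3))
        for i in range(n_atoms):
            for _attempt in range(10_000):
                pos = rng.uniform(-half_box, half_box, size=3)
                if i == 0:
                    break
                d = np.linalg.norm(coords[:i] - pos, axis=1)
                if np.all(d > 0.55 * (radii[:i] + radii[i])):
                    break
            else:
                raise RuntimeError("failed to place non-overlapping atoms")
            coords[i] = pos
        energy = float(rng.uniform(0.0, 8.0))
        conformers.append(Conformer(symbols, coords, radii=radii, energy=energy))
    return ConformerEnsemble(conformers, temperature=temperature)
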