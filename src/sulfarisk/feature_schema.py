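"""Descriptor registry, compound feature tables, and the published selection table.

The study represents each 5-membered cyclic sulfamidate by 71 conformer-averaged
quantum-chemical descriptors: for every atom-level property (partial charges,
Fukui indices of three kinds, nucleophilic/electrophilic frontier-orbital Fukui
variants, and the "visible sky" steric fraction) one value per ring heavy atom
(N, S, O, C(O), C(N)) and per ring-bonded hydrogen site (NH, C(N)H, C(O)H);
plus two C–H bond dissociation energies, the ring C–O bond order, whole-molecule
and degradant properties, reaction free-energy differences, and the summed DSC
event enthalpy.  The registry is loaded from a packaged manifest so the column
order is fixed and identical everywhere.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorSpec",
    "FeatureRegistry",
    "CompoundRecord",
    "FeatureTable",
    "SelectionTable",
    "DataError",
    "build_default_registry",
    "load_selection_fixture",
    "count_selected",
    "selection_overlap",
    "LEVELS",
    "SITES",
    "FAMILIES",
    "META_COLUMNS",
]

LEVELS = ("atom", "bond", "molecule", "degradant", "experimental")
SITES = ("N", "NH", "C(N)", "C(N)H", "C(O)", "C(O)H", "O", "S", "none")
FAMILIES = (
    "partial_charge", "fukui_plus", "fukui_zero", "fukui_minus",
    "fukui_nn_homo", "fukui_nn_lumo", "bde", "bond_order", "visible_sky",
    "labute_asa", "dipole", "homo_lumo_gap", "free_energy_diff", "dsc_sum_dh",
)

#: Leading (non-descriptor) columns of the feature-table CSV dialect.
META_COLUMNS = ("compound_id", "mw_g_per_mol", "enthalpy_j_per_g", "split")

#: Canonical model keys and accepted aliases for the selection table.
_MODEL_ALIASES = {
    "pls_ga": "pls_ga", "pls-ga": "pls_ga", "plsga": "pls_ga", "pls": "pls_ga",
    "lasso": "lasso",
    "gpr": "gpr",
}


class DataError(ValueError):
    """Raised when table contents violate the schema (not a usage error)."""


def _canon_model(name: str) -> str:
    key = name.strip().lower().replace(" ", "")
    try:
        return _MODEL_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown model name: {name!r}") from None


@dataclass(frozen=True)
class DescriptorSpec:
    """Schema entry for a single descriptor column."""

    id: str
    level: str
    site: str
    family: str
    units: str = ""
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"invalid level {self.level!r} for {self.id}")
        if self.site not in SITES:
            raise ValueError(f"invalid site {self.site!r} for {self.id}")
        if self.family not in FAMILIES:
            raise ValueError(f"invalid family {self.family!r} for {self.id}")
        if self.allow_missing:
            # Missing values occur only where the underlying quantity is
            # undefined: the two C-H dissociation energies and atom-level
            # H-site properties when no hydrogen is present.
            h_site_atom = self.level == "atom" and self.site in ("NH", "C(N)H", "C(O)H")
            if not (self.family == "bde" or h_site_atom):
                raise ValueError(
                    f"allow_missing is restricted to BDE and H-site atom "
                    f"descriptors, not {self.id}"
                )


class FeatureRegistry:
    """Ordered, immutable collection of :class:`DescriptorSpec`."""

    def __init__(self, specs: Iterable[DescriptorSpec]):
        self._specs = tuple(specs)
        ids = [s.id for s in self._specs]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate descriptor ids: {sorted(dupes)}")
        self._index = {s.id: k for k, s in enumerate(self._specs)}

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self._specs)

    @property
    def specs(self) -> tuple[DescriptorSpec, ...]:
        return self._specs

    def __len__(self) -> int:
        return len(self._specs)

    def __iter__(self) -> Iterator[DescriptorSpec]:
        return iter(self._specs)

    def __contains__(self, descriptor_id: str) -> bool:
        return descriptor_id in self._index

    def __getitem__(self, key: str | int) -> DescriptorSpec:
        if isinstance(key, str):
            return self._specs[self._index[key]]
        return self._specs[key]

    def index_of(self, descriptor_id: str) -> int:
        return self._index[descriptor_id]

    def filter(self, *, family: str | None = None, level: str | None = None,
               site: str | None = None) -> "FeatureRegistry":
        kept = [
            s for s in self._specs
            if (family is None or s.family == family)
            and (level is None or s.level == level)
            and (site is None or s.site == site)
        ]
        return FeatureRegistry(kept)

    def allow_missing_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self._specs if s.allow_missing)


def build_default_registry() -> FeatureRegistry:
    """Load the packaged 71-descriptor registry.

    The manifest itemizes the full descriptor set: seven atom-level property
    families with eight ring sites each, the two C–H bond dissociation
    energies, the ring C–O bond order, molecule- and degradant-level
    properties, two reaction free-energy differences, and the DSC event sum.
    """
    ref = resources.files("sulfarisk.data").joinpath("descriptor_manifest.csv")
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        specs = [
            DescriptorSpec(
                id=row["id"], level=row["level"], site=row["site"],
                family=row["family"], units=row["units"],
                allow_missing=bool(int(row["allow_missing"])),
            )
            for row in reader
        ]
    registry = FeatureRegistry(specs)
    if len(registry) != 71:  # manifest is packaged data; fail loudly if corrupt
        raise DataError(f"descriptor manifest must define 71 descriptors, got {len(registry)}")
    return registry


@dataclass
class CompoundRecord:
    """One compound: identity, molecular weight, measured enthalpy and values."""

    compound_id: str
    mw: float
    values: Mapping[str, float]
    enthalpy_j_per_g: float | None = None
    split: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mw) or self.mw <= 0:
            raise ValueError(f"{self.compound_id}: mw must be positive, got {self.mw}")
        if self.split not in (None, "train", "predict"):
            raise ValueError(f"{self.compound_id}: invalid split {self.split!r}")


class FeatureTable:
    """A registry plus a compounds × descriptors table (pandas-backed).

    Missing descriptor values are NaN and may occur only in columns whose
    spec has ``allow_missing=True``.
    """

    def __init__(self, registry: FeatureRegistry, df: pd.DataFrame, *, validate: bool = True):
        expected = list(META_COLUMNS) + list(registry.ids)
        if list(df.columns) != expected:
            raise DataError("feature table columns do not match registry order")
        self.registry = registry
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        mw = self.df["mw_g_per_mol"].to_numpy(float)
        if not np.all(np.isfinite(mw)) or np.any(mw <= 0):
            raise DataError("molecular weights must be finite and positive")
        allowed = set(self.registry.allow_missing_ids())
        for col in self.registry.ids:
            vals = self.df[col].to_numpy(float)
            if np.any(~np.isfinite(vals)) and col not in allowed:
                bad = self.df.loc[~np.isfinite(vals), "compound_id"].tolist()
                raise DataError(f"missing values in non-missing column {col!r} (rows {bad})")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, registry: FeatureRegistry,
                     records: Sequence[CompoundRecord]) -> "FeatureTable":
        rows = []
        for rec in records:
            row = {
                "compound_id": rec.compound_id,
                "mw_g_per_mol": rec.mw,
                "enthalpy_j_per_g": np.nan if rec.enthalpy_j_per_g is None else rec.enthalpy_j_per_g,
                "split": rec.split,
            }
            for did in registry.ids:
                row[did] = rec.values.get(did, np.nan)
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(registry.ids))
        return cls(registry, df)

    def records(self) -> list[CompoundRecord]:
        out = []
        for _, row in self.df.iterrows():
            h = row["enthalpy_j_per_g"]
            out.append(CompoundRecord(
                compound_id=row["compound_id"], mw=float(row["mw_g_per_mol"]),
                enthalpy_j_per_g=None if pd.isna(h) else float(h),
                split=None if pd.isna(row["split"]) else row["split"],
                values={d: float(row[d]) for d in self.registry.ids},
            ))
        return out

    # -- views -------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def compound_ids(self) -> np.ndarray:
        return self.df["compound_id"].to_numpy()

    def subset(self, mask) -> "FeatureTable":
        return FeatureTable(self.registry, self.df.loc[mask].reset_index(drop=True),
                            validate=False)

    @property
    def train(self) -> "FeatureTable":
        return self.subset(self.df["split"] == "train")

    @property
    def predict(self) -> "FeatureTable":
        return self.subset(self.df["split"] == "predict")

    def X(self, subset_ids: Sequence[str] | None = None) -> np.ndarray:
        cols = list(subset_ids) if subset_ids is not None else list(self.registry.ids)
        for c in cols:
            if c not in self.registry:
                raise KeyError(f"descriptor {c!r} not in registry")
        return self.df[cols].to_numpy(float)

    @property
    def mw(self) -> np.ndarray:
        return self.df["mw_g_per_mol"].to_numpy(float)

    @property
    def y_per_gram(self) -> np.ndarray:
        return self.df["enthalpy_j_per_g"].to_numpy(float)

    @property
    def y_per_mol(self) -> np.ndarray:
        return self.y_per_gram * self.mw

    def with_column(self, name: str, values) -> "FeatureTable":
        df = self.df.copy()
        df[name] = values
        return FeatureTable(self.registry, df, validate=False)

    # -- CSV dialect -------------------------------------------------------
    def to_csv(self, path) -> None:
        df = self.df.copy()
        df.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path, registry: FeatureRegistry | None = None) -> "FeatureTable":
        df = pd.read_csv(path, dtype={"compound_id": str, "split": str})
        cols = list(df.columns)
        if cols[: len(META_COLUMNS)] != list(META_COLUMNS):
            raise DataError(
                f"feature CSV must start with columns {META_COLUMNS}, got {cols[:4]}"
            )
        descriptor_cols = cols[len(META_COLUMNS):]
        if registry is None:
            default = build_default_registry()
            if descriptor_cols == list(default.ids):
                registry = default
            else:
                # generic registry for tables written with a custom schema
                registry = FeatureRegistry([
                    DescriptorSpec(id=c, level="molecule", site="none",
                                   family="dipole", units="")
                    for c in descriptor_cols
                ])
        if descriptor_cols != list(registry.ids):
            raise DataError("descriptor columns do not match the supplied registry")
        for col in descriptor_cols:
            if not np.issubdtype(df[col].dtype, np.number):
                bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
                rows = bad["compound_id"].tolist()
                raise DataError(f"non-numeric values in column {col!r} (rows {rows})")
        return cls(registry, df)


class SelectionTable:
    """Mapping from model name to the set of descriptor ids it selected."""

    def __init__(self, selections: Mapping[str, Iterable[str]],
                 registry: FeatureRegistry | None = None):
        self._sets = {_canon_model(k): frozenset(v) for k, v in selections.items()}
        if registry is not None:
            for model, ids in self._sets.items():
                unknown = [i for i in ids if i not in registry]
                if unknown:
                    raise DataError(f"{model} selects unknown descriptors: {unknown}")

    @property
    def models(self) -> tuple[str, ...]:
        return tuple(self._sets)

    def selected(self, model: str) -> frozenset[str]:
        return self._sets[_canon_model(model)]


def load_selection_fixture(registry: FeatureRegistry | None = None) -> SelectionTable:
    """Load the packaged published selection table (descriptor × model flags)."""
    if registry is None:
        registry = build_default_registry()
    ref = resources.files("sulfarisk.data").joinpath("table1_selection.csv")
    try:
        with ref.open("r", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if set(reader.fieldnames or []) != {"descriptor", "pls_ga", "lasso", "gpr"}:
                raise DataError("selection fixture has unexpected columns")
            sel: dict[str, set[str]] = {"pls_ga": set(), "lasso": set(), "gpr": set()}
            for row in reader:
                for model in ("pls_ga", "lasso", "gpr"):
                    if int(row[model]):
                        sel[model].add(row["descriptor"])
    except FileNotFoundError as exc:
        raise IOError("packaged selection fixture is missing") from exc
    return SelectionTable(sel, registry=registry)


def count_selected(table: SelectionTable, model: str) -> int:
    """Number of descriptors the given model selected."""
    return len(table.selected(model))


def selection_overlap(table: SelectionTable, a: str, b: str) -> int:
    """Size of the intersection of two models' selected descriptor sets."""
    return len(table.selected(a) & table.selected(b))
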