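"""Steric "visible sky" descriptor and Boltzmann conformer averaging.

The visible-sky descriptor quantifies steric shielding of an atom: the
fraction of the full solid angle, seen from the atom's nuclear center, that is
NOT obstructed by the van der Waals spheres of the other atoms.  1.0 means the
atom is fully exposed, 0.0 fully buried.  Directions are sampled with a
deterministic Fibonacci sphere so the value is reproducible without a seed.

Because quantum-chemical properties depend on conformation, descriptors are
averaged over a conformer ensemble with Boltzmann weights
``w_i ∝ exp(-(E_i - E_min) / (R T))`` (R = 0.0083145 kJ/(mol K)).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "BONDI_RADII",
    "GAS_CONSTANT_KJ",
    "Conformer",
    "ConformerEnsemble",
    "fibonacci_sphere",
    "visible_sky",
    "boltzmann_weights",
    "boltzmann_average",
    "read_xyz",
    "write_xyz",
]

#: Bondi van der Waals radii, Å.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70  # fallback for elements outside the table

#: Gas constant in kJ/(mol K).
GAS_CONSTANT_KJ = 0.0083145


def _radii_for(symbols: Sequence[str]) -> np.ndarray:
    return np.array([BONDI_RADII.get(s, _DEFAULT_RADIUS) for s in symbols], float)


@dataclass
class Conformer:
    """A single 3-D structure: element symbols, coordinates (Å), vdW radii (Å)
    and a relative energy (kJ/mol)."""

    symbols: tuple[str, ...]
    coords: np.ndarray
    radii: np.ndarray | None = None
    energy: float = 0.0

    def __post_init__(self) -> None:
        self.symbols = tuple(self.symbols)
        self.coords = np.asarray(self.coords, float).reshape(len(self.symbols), 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("conformer coordinates must be finite")
        if self.radii is None:
            self.radii = _radii_for(self.symbols)
        self.radii = np.asarray(self.radii, float)
        if self.radii.shape != (len(self.symbols),):
            raise ValueError("one radius per atom required")
        if np.any(self.radii <= 0):
            raise ValueError("vdW radii must be positive")
        if len(self.symbols) > 1:
            d = np.linalg.norm(
                self.coords[:, None, :] - self.coords[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if np.any(d < 1e-8):
                raise ValueError("two atom centers coincide")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class ConformerEnsemble:
    """Non-empty list of conformers sharing an averaging temperature (K)."""

    conformers: list[Conformer]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformers], float)

    def weights(self) -> np.ndarray:
        return boltzmann_weights(self.energies, self.temperature)

    def average(self, per_conformer_values: Sequence[float]) -> float:
        return boltzmann_average(per_conformer_values, self.weights())


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors (golden-angle spiral on the sphere)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def visible_sky(conformer: Conformer, atom_index: int, n_rays: int = 100_000,
                directions: np.ndarray | None = None) -> float:
    """Fraction of the solid angle around an atom not blocked by other atoms.

    A direction is obstructed iff the half-line from the atom's center
    intersects another atom's vdW sphere; the central atom's own radius is
    ignored (the viewpoint is the nucleus).

    Parameters
    ----------
    conformer : Conformer
    atom_index : int
        Index of the atom whose exposure is measured.
    n_rays : int
        Number of deterministic Fibonacci-sphere directions (>= 100).
    directions : ndarray, optional
        Explicit (m, 3) unit direction set; overrides ``n_rays`` (used by the
        Monte-Carlo test oracle).
    """
    n_atoms = len(conformer)
    if not 0 <= atom_index < n_atoms:
        raise IndexError(f"atom_index {atom_index} out of range for {n_atoms} atoms")
    if directions is None:
        if n_rays < 100:
            raise ValueError("n_rays must be at least 100")
        directions = fibonacci_sphere(n_rays)
    if n_atoms == 1:
        return 1.0

    others = np.arange(n_atoms) != atom_index
    centers = conformer.coords[others] - conformer.coords[atom_index]
    radii = conformer.radii[others]
    d2 = np.einsum("ij,ij->i", centers, centers)
    if np.any(d2 <= radii**2):
        return 0.0  # viewpoint lies inside a neighboring sphere

    # ray t*dir hits sphere (c, r) iff projection > 0 and perp distance < r
    proj = directions @ centers.T                      # (m, k)
    perp2 = d2[None, :] - proj**2
    blocked = np.any((proj > 0.0) & (perp2 < radii[None, :] ** 2), axis=1)
    return float(1.0 - blocked.mean())


def boltzmann_weights(energies, temperature: float = 298.15) -> np.ndarray:
    """Normalized Boltzmann weights of relative energies in kJ/mol."""
    e = np.asarray(energies, float)
    if e.size == 0:
        raise ValueError("energies must be non-empty")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    w = np.exp(-(e - e.min()) / (GAS_CONSTANT_KJ * temperature))
    return w / w.sum()


def boltzmann_average(values, weights) -> float:
    """Weighted average Σ w_i v_i of per-conformer property values."""
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    if v.shape != w.shape:
        raise ValueError(f"length mismatch: {v.shape} values vs {w.shape} weights")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return float(v @ w)


def read_xyz(path, temperature: float = 298.15) -> ConformerEnsemble:
    """Read a (multi-frame) XYZ file into a :class:`ConformerEnsemble`.

    Per-conformer relative energies (kJ/mol) are parsed from an ``E=<value>``
    token on the comment line when present, else 0.
    """
    text = Path(path).read_text().splitlines()
    conformers: list[Conformer] = []
    i = 0
    while i < len(text):
        line = text[i].strip()
        if not line:
            i += 1
            continue
        n = int(line)
        comment = text[i + 1] if i + 1 < len(text) else ""
        energy = 0.0
        for token in comment.split():
            if token.startswith("E="):
                energy = float(token[2:])
        symbols, coords = [], []
        for j in range(n):
            parts = text[i + 2 + j].split()
            symbols.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        conformers.append(Conformer(tuple(symbols), np.array(coords), energy=energy))
        i += 2 + n
    return ConformerEnsemble(conformers, temperature=temperature)


def write_xyz(path, ensemble: ConformerEnsemble) -> None:
    """Write an ensemble as multi-frame XYZ with ``E=`` comment tokens."""
    lines = []
    for c in ensemble.conformers:
        lines.append(str(len(c)))
        lines.append(f"E={c.energy:.6f}")
        for s, (x, y, z) in zip(c.symbols, c.coords):
            lines.append(f"{s} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")
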