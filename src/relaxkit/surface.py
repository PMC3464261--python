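"""Solvent-accessible surface area by the Shrake-Rupley method.

Each atom is expanded by the probe radius (default 1.4 A, a water
molecule) and sampled with a deterministic Fibonacci-spiral point set;
the accessible area is the sphere area times the fraction of points not
buried inside any neighbouring expanded sphere.  Heavy atoms only by
default, matching how accessibility is conventionally reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .structure import Structure

__all__ = ["VDW_RADII", "SASAResult", "shrake_rupley_sasa", "sphere_points"]

#: van der Waals radii (A) -- a fixed published set; other tabulations
#: (e.g. the one NACCESS ships) differ by a few hundredths of an Angstrom.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.10,
    "P": 1.80,
    "CU": 1.40,
}


@dataclass(frozen=True)
class SASAResult:
    """Per-atom accessible areas (A^2) keyed by (residue_index, atom_name)."""

    areas: dict[tuple[int, str], float]
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(sum(self.areas.values()))

    def atom_area(self, residue_index: int, atom_name: str) -> float:
        return self.areas[(residue_index, atom_name)]

    def residue_area(self, residue_index: int) -> float:
        return float(sum(a for (r, _), a in self.areas.items() if r == residue_index))


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (Fibonacci spiral)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * math.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    default_radius: float = 1.70,
    include_hydrogens: bool = False,
) -> SASAResult:
    """Per-atom solvent-accessible surface area of the first model.

    Unknown elements fall back to `default_radius` with a warning.
    """
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    model = structure.model()
    atoms = [a for a in model.atoms if include_hydrogens or a.element.upper() != "H"]
    if not atoms:
        raise ValueError("no atoms to analyse")
    coords = np.array([[a.x, a.y, a.z] for a in atoms])
    rad = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        el = a.element.upper()
        if el not in table:
            warnings.warn(f"no vdW radius for element {el!r}; using {default_radius} A")
        rad[i] = table.get(el, default_radius)

    pts = sphere_points(n_points)
    expanded = rad + probe
    areas: dict[tuple[int, str], float] = {}
    for i, a in enumerate(atoms):
        ri = expanded[i]
        # neighbours whose expanded spheres can bury points of atom i
        d = np.linalg.norm(coords - coords[i], axis=1)
        nb = np.nonzero((d < ri + expanded) & (np.arange(len(atoms)) != i))[0]
        sample = coords[i] + ri * pts
        if nb.size:
            d2 = np.sum((sample[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < expanded[nb][None, :] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[(a.residue_index, a.atom_name)] = 4.0 * math.pi * ri * ri * float(frac)
    return SASAResult(areas=areas, probe_radius=probe, n_sphere_points=n_points)
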