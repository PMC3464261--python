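"""Paramagnetic-center localization from PRE-bleached amides.

A bound paramagnetic ion (here Cu2+) broadens NMR resonances within about
8 A beyond detection.  The set of bleached amides therefore constrains
the ion to lie within a distance window (default 1.8-8.0 A) of each
affected N-H group; the center is localized by minimizing a flat-bottom
quadratic penalty (zero inside the window, squared excursion outside)
over the ion coordinates, from the restrained-atom centroid plus a
deterministic multi-start.  The converse operation predicts which amides
a given center position would bleach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .structure import Atom, Structure

__all__ = [
    "BleachSet",
    "CenterModel",
    "MetalCenterLocator",
    "locate_center",
    "predict_bleached",
    "BLEACHED_BACKBONE_RESIDUES",
    "BLEACHED_BACKBONE_RESIDUES_WITH_GLN52",
    "BLEACHED_SIDECHAIN_GLN_RESIDUES",
]

#: Backbone amides bleached at 1:1 Cu2+ in the Ber e 1 titration (body list).
BLEACHED_BACKBONE_RESIDUES = (20, 21, 22, 24, 43, 45, 47, 48, 49)
#: Same set with Gln 52 added (the figure-caption variant of the list).
BLEACHED_BACKBONE_RESIDUES_WITH_GLN52 = BLEACHED_BACKBONE_RESIDUES + (52,)
#: Glutamine side-chain N-H groups affected at the same ratio.
BLEACHED_SIDECHAIN_GLN_RESIDUES = (11, 13, 28, 83)


@dataclass(frozen=True)
class BleachSet:
    """Atoms whose resonances are bleached, with the Cu:protein ratio seen."""

    entries: tuple[tuple[int, str], ...]  # (residue_index, atom_name)
    stoichiometry_ratio: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple((int(r), str(a)) for r, a in self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def residues(self) -> tuple[int, ...]:
        return tuple(sorted({r for r, _ in self.entries}))

    @classmethod
    def from_residues(
        cls,
        structure: Structure,
        residues: tuple[int, ...] | list[int],
        prefer: str = "H",
        stoichiometry_ratio: str | None = None,
    ) -> "BleachSet":
        """Backbone bleach set: amide H when present, else N."""
        model = structure.model()
        entries = []
        for resi in residues:
            try:
                model.atom(resi, prefer)
                entries.append((resi, prefer))
            except KeyError:
                model.atom(resi, "N")  # raises if the residue is absent entirely
                entries.append((resi, "N"))
        return cls(tuple(entries), stoichiometry_ratio)


@dataclass(frozen=True)
class CenterModel:
    """Fitted center with per-restraint distances and violation summary."""

    position: tuple[float, float, float]
    distances: dict[tuple[int, str], float]
    max_violation: float
    penalty: float  # A^2
    satisfied: bool
    bounds: tuple[float, float]


def _restraint_coords(structure: Structure, bleached: BleachSet) -> np.ndarray:
    model = structure.model()
    pts = []
    for resi, name in bleached.entries:
        pts.append(model.atom(resi, name).position)
    return np.array(pts).reshape(-1, 3)


def _penalty_and_grad(x: np.ndarray, pts: np.ndarray, lower: float, upper: float):
    diff = x[None, :] - pts
    d = np.linalg.norm(diff, axis=1)
    d_safe = np.where(d == 0, 1e-12, d)
    over = np.maximum(0.0, d - upper)
    under = np.maximum(0.0, lower - d)
    pen = float(np.sum(over**2 + under**2))
    coef = 2.0 * (over - under) / d_safe
    grad = (coef[:, None] * diff).sum(axis=0)
    return pen, grad


class MetalCenterLocator(BaseEstimator):
    """Locate a paramagnetic center satisfying distance windows to bleached atoms.

    Parameters
    ----------
    lower, upper : float
        Flat-bottom window in Angstrom (default 1.8-8.0, the effective
        PRE bleaching range of Cu2+).
    multistart_offset : float
        The six axis-aligned multi-start displacements from the
        restrained-atom centroid, Angstrom.
    tol : float
        Residual penalty above which the restraint set is flagged
        unsatisfiable (no exception is raised).

    Attributes (after fit): position_, distances_, penalty_,
    max_violation_, satisfied_.
    """

    def __init__(self, lower: float = 1.8, upper: float = 8.0,
                 multistart_offset: float = 5.0, tol: float = 1e-8):
        self.lower = lower
        self.upper = upper
        self.multistart_offset = multistart_offset
        self.tol = tol

    def fit(self, structure: Structure, bleached: BleachSet) -> "MetalCenterLocator":
        if len(bleached) == 0:
            raise ValueError("bleach set is empty")
        if not (0 <= self.lower < self.upper):
            raise ValueError("need 0 <= lower < upper")
        pts = _restraint_coords(structure, bleached)
        centroid = pts.mean(axis=0)
        starts = [centroid]
        for axis in range(3):
            for sign in (+1.0, -1.0):
                off = np.zeros(3)
                off[axis] = sign * self.multistart_offset
                starts.append(centroid + off)

        best = None
        for x0 in starts:
            res = optimize.minimize(
                _penalty_and_grad, x0, args=(pts, self.lower, self.upper),
                jac=True, method="L-BFGS-B",
                options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        x = best.x
        pen, _ = _penalty_and_grad(x, pts, self.lower, self.upper)
        d = np.linalg.norm(x[None, :] - pts, axis=1)
        violations = np.maximum(np.maximum(0.0, d - self.upper),
                                np.maximum(0.0, self.lower - d))
        self.position_ = tuple(float(v) for v in x)
        self.distances_ = {key: float(di) for key, di in zip(bleached.entries, d)}
        self.penalty_ = float(pen)
        self.max_violation_ = float(violations.max())
        self.satisfied_ = bool(pen <= self.tol)
        return self

    def to_center_model(self) -> CenterModel:
        return CenterModel(
            position=self.position_,
            distances=self.distances_,
            max_violation=self.max_violation_,
            penalty=self.penalty_,
            satisfied=self.satisfied_,
            bounds=(self.lower, self.upper),
        )


def locate_center(
    structure: Structure,
    bleached: BleachSet,
    bounds: tuple[float, float] = (1.8, 8.0),
) -> CenterModel:
    """Fit the center position; thin wrapper over MetalCenterLocator."""
    loc = MetalCenterLocator(lower=bounds[0], upper=bounds[1]).fit(structure, bleached)
    return loc.to_center_model()


def predict_bleached(
    structure: Structure,
    center: tuple[float, float, float],
    radius: float = 8.0,
    include_sidechains: bool = False,
) -> BleachSet:
    """All amide N/H atoms within `radius` of `center`, sorted by distance.

    With include_sidechains=True every nitrogen-bound or nitrogen atom
    outside the backbone is considered as well.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    c = np.asarray(center, dtype=float)
    model = structure.model()
    hits = []
    for a in model.atoms:
        backbone_amide = a.atom_name in ("N", "H")
        sidechain_nh = (
            include_sidechains
            and a.atom_name not in ("N", "H", "CA", "C", "O", "CB")
            and a.element.upper() in ("N", "H")
        )
        if not (backbone_amide or sidechain_nh):
            continue
        dist = float(np.linalg.norm(a.position - c))
        if dist <= radius:
            hits.append((dist, a))
    hits.sort(key=lambda pair: pair[0])
    return BleachSet(tuple((a.residue_index, a.atom_name) for _, a in hits))


def append_center(structure: Structure, center: tuple[float, float, float]) -> Structure:
    """Copy of the first model with a CU pseudo-atom at the fitted center."""
    model = structure.model()
    resi = max(model.residue_indices()) + 1
    cu = Atom(model.model_ids[0], "Z", resi, "CU", "CU", "CU",
              float(center[0]), float(center[1]), float(center[2]))
    return Structure(model.atoms + [cu])
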