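"""Protein structures: atom records, PDB I/O and ideal-geometry builders.

The in-memory representation is deliberately small: a flat list of atom
records (model, chain, residue, atom name, element, coordinates in
Angstrom).  PDB reading/writing is delegated to gemmi; the builders place
backbone atoms (N, CA, C, O, amide H, optionally CB) with ideal bond
geometry from phi/psi torsions, which is all the downstream consumers
(PRE localization, SASA, bead hydrodynamics) need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gemmi
import numpy as np

AA_3LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_1LETTER = {v: k for k, v in AA_3LETTER.items()}

# ideal backbone geometry (Engh-Huber-like averages), Angstrom / degrees
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.01
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-139.0, 135.0)


@dataclass(frozen=True)
class Atom:
    """One atom record."""

    model_id: int
    chain: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Structure:
    """A (possibly multi-model) collection of atom records."""

    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = {(a.model_id, a.chain, a.residue_index, a.atom_name) for a in self.atoms}
        if len(keys) != len(self.atoms):
            raise ValueError("duplicate (model, chain, residue, atom) key in structure")
        for a in self.atoms:
            if not (math.isfinite(a.x) and math.isfinite(a.y) and math.isfinite(a.z)):
                raise ValueError(f"non-finite coordinate on atom {a}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def model_ids(self) -> list[int]:
        return sorted({a.model_id for a in self.atoms})

    def model(self, model_id: int | None = None) -> "Structure":
        """Single-model view; defaults to the first model."""
        if model_id is None:
            model_id = self.model_ids[0]
        sub = [a for a in self.atoms if a.model_id == model_id]
        if not sub:
            raise KeyError(f"no model {model_id} in structure")
        return Structure(sub)

    def select(
        self,
        atom_names: Iterable[str] | None = None,
        elements: Iterable[str] | None = None,
        heavy_only: bool = False,
    ) -> "Structure":
        names = set(atom_names) if atom_names is not None else None
        elems = {e.upper() for e in elements} if elements is not None else None
        out = []
        for a in self.atoms:
            if heavy_only and a.element.upper() == "H":
                continue
            if names is not None and a.atom_name not in names:
                continue
            if elems is not None and a.element.upper() not in elems:
                continue
            out.append(a)
        return Structure(out)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float).reshape(-1, 3)

    def atom(self, residue_index: int, atom_name: str, model_id: int | None = None) -> Atom:
        for a in (self.model(model_id).atoms if len(self.model_ids) > 1 else self.atoms):
            if a.residue_index == residue_index and a.atom_name == atom_name:
                return a
        raise KeyError(f"atom {atom_name} of residue {residue_index} not found")

    def residue_indices(self) -> list[int]:
        return sorted({a.residue_index for a in self.atoms})

    def sequence(self) -> str:
        """One-letter sequence of the first model, by residue index."""
        first = self.model()
        by_res: dict[int, str] = {}
        for a in first.atoms:
            by_res.setdefault(a.residue_index, a.residue_name)
        return "".join(AA_1LETTER.get(by_res[i], "X") for i in sorted(by_res))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid transform x -> R x + t applied to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        out = []
        for a in self.atoms:
            p = R @ a.position + t
            out.append(replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2])))
        return Structure(out)

    # -- PDB I/O ------------------------------------------------------

    def to_gemmi(self) -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = "relaxkit"
        for mid in self.model_ids:
            model = gemmi.Model(mid)
            chains: dict[str, gemmi.Chain] = {}
            for a in self.atoms:
                if a.model_id != mid:
                    continue
                ch = chains.setdefault(a.chain, gemmi.Chain(a.chain))
                res = None
                for r in ch:
                    if r.seqid.num == a.residue_index:
                        res = r
                        break
                if res is None:
                    res = gemmi.Residue()
                    res.name = a.residue_name
                    res.seqid = gemmi.SeqId(a.residue_index, " ")
                    ch.add_residue(res)
                    res = ch[-1]
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(a.x, a.y, a.z)
                res.add_atom(at)
            for ch in chains.values():
                model.add_chain(ch)
            st.add_model(model)
        st.setup_entities()
        return st

    def write_pdb(self, path: str) -> None:
        self.to_gemmi().write_pdb(path)

    @classmethod
    def from_gemmi(cls, st: gemmi.Structure) -> "Structure":
        atoms = []
        for i, model in enumerate(st, start=1):
            for chain in model:
                for res in chain:
                    for at in res:
                        atoms.append(
                            Atom(
                                model_id=i,
                                chain=chain.name,
                                residue_index=res.seqid.num,
                                residue_name=res.name,
                                atom_name=at.name,
                                element=at.element.name.upper(),
                                x=at.pos.x,
                                y=at.pos.y,
                                z=at.pos.z,
                            )
                        )
        return cls(atoms)

    @classmethod
    def read_pdb(cls, path: str) -> "Structure":
        return cls.from_gemmi(gemmi.read_structure(str(path)))


# -- ideal-geometry construction --------------------------------------


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd|=bond, angle(b,c,d), dihedral(a,b,c,d)."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(dih),
         bond * math.sin(ang) * math.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(
    sequence: str,
    phi_psi: Sequence[tuple[float, float]] | tuple[float, float],
    include_cb: bool = False,
    chain: str = "A",
    model_id: int = 1,
    first_residue: int = 1,
) -> Structure:
    """Build backbone atoms for `sequence` from per-residue (phi, psi) torsions.

    Omega is fixed trans (180 deg).  A single (phi, psi) pair is broadcast to
    all residues.  Amide H is placed in the peptide plane; CB (optional) by the
    standard tetrahedral construction; glycine never gets a CB.
    """
    sequence = sequence.strip().upper()
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    bad = [c for c in sequence if c not in AA_3LETTER]
    if bad:
        raise ValueError(f"unknown residue letter(s): {bad}")
    n_res = len(sequence)
    if isinstance(phi_psi, tuple) and len(phi_psi) == 2 and np.isscalar(phi_psi[0]):
        torsions = [(float(phi_psi[0]), float(phi_psi[1]))] * n_res
    else:
        torsions = [(float(p), float(s)) for p, s in phi_psi]
        if len(torsions) != n_res:
            raise ValueError("phi_psi length must match sequence length")

    N = [np.zeros(3)]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(_A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for i in range(n_res - 1):
        psi_i = torsions[i][1]
        phi_next = torsions[i + 1][0]
        N.append(_place(N[i], CA[i], C[i], _B_C_N, _A_CA_C_N, psi_i))
        CA.append(_place(CA[i], C[i], N[i + 1], _B_N_CA, _A_C_N_CA, 180.0))
        C.append(_place(C[i], N[i + 1], CA[i + 1], _B_CA_C, _A_N_CA_C, phi_next))

    atoms: list[Atom] = []

    def add(resi: int, resname: str, name: str, element: str, pos: np.ndarray) -> None:
        atoms.append(
            Atom(model_id, chain, resi, resname, name, element,
                 float(pos[0]), float(pos[1]), float(pos[2]))
        )

    for i, letter in enumerate(sequence):
        resi = first_residue + i
        resname = AA_3LETTER[letter]
        add(resi, resname, "N", "N", N[i])
        add(resi, resname, "CA", "C", CA[i])
        add(resi, resname, "C", "C", C[i])
        O = _place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, torsions[i][1] + 180.0)
        add(resi, resname, "O", "O", O)
        if i > 0:
            u1 = N[i] - C[i - 1]
            u2 = N[i] - CA[i]
            h_dir = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
        else:
            h_dir = N[i] - 0.5 * (CA[i] + C[i])
        add(resi, resname, "H", "H", N[i] + _B_N_H * h_dir / np.linalg.norm(h_dir))
        if include_cb and letter != "G":
            b = CA[i] - N[i]
            cv = C[i] - CA[i]
            a_v = np.cross(b, cv)
            cb = -0.58273431 * a_v + 0.56802827 * b - 0.54067466 * cv + CA[i]
            add(resi, resname, "CB", "C", cb)
    return Structure(atoms)


def helix_axis(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares axis through the CA trace: (centroid, unit direction)."""
    ca = structure.select(atom_names=["CA"]).coords()
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    direction = vt[0]
    # orient along increasing residue order
    if np.dot(ca[-1] - ca[0], direction) < 0:
        direction = -direction
    return centroid, direction


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180 deg about any perpendicular axis
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return -np.eye(3) + 2.0 * np.outer(perp, perp)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)  # sin of the rotation angle
    axis /= s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * K @ K
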