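"""Synthetic inputs for the full relaxation-analysis chain.

Everything the pipeline consumes can be generated here from known ground
truth with seeded randomness: per-residue motional profiles, exponential
decay series and NOE saturation pairs forward-modelled from those
profiles, 2D Lorentzian peak grids, and ideal-geometry toy structures.

The default conditions emulate the study system: a 114-residue protein
tumbling at tau_m = 7.9 ns, a rigid core with S^2 around 0.8, flexible
termini and loops with S^2 down to 0.2, a ~15% subset of residues with
microsecond-millisecond exchange (Rex 1-5 1/s), acquisition at a 600 MHz
1H field (60.8 MHz 15N), the standard delay lists with duplicate points,
and Gaussian intensity noise of 1% of the initial intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import GAMMA_H, GAMMA_N, SpinSystemConstants
from .modelfree import forward_rates
from .rates import DecaySeries, PeakGrid, SpinLockGeometry
from .structure import (
    EXTENDED_PHI_PSI,
    HELIX_PHI_PSI,
    Atom,
    Structure,
    build_peptide,
    helix_axis,
    _rotation_between,
)

__all__ = [
    "GroundTruthProfile",
    "AcquisitionScheme",
    "SyntheticDataset",
    "generate_profile",
    "generate_dataset",
    "generate_peak_grid",
    "generate_toy_structure",
    "synthetic_four_helix_bundle",
    "SYNTHETIC_SEQUENCE_114",
]

#: Synthetic 114-residue sequence used by fixtures and the bundle builder.
#: 2S-albumin-flavoured composition (Gln/Glu/Cys/Met rich, a few F/L pepsin
#: anchors) but entirely made up -- it is NOT a natural sequence.
SYNTHETIC_SEQUENCE_114 = (
    "MAKLTILVAL" "ALFLLAAHAS" "ARQQWEQCRE" "QMQRQEMLSH" "CRMYMRQQME"
    "SGGFQPQQCQ" "LRGMMDLPGQ" "CGMEPQRCQM" "LQQMEPHMRM" "CNMRQMMCPM"
    "LRQPMFGGFL" "PRQA"
)


@dataclass(frozen=True)
class GroundTruthProfile:
    """True motional parameters of one residue."""

    residue_index: int
    s2: float
    tau_e: float  # ps
    rex: float  # 1/s
    class_label: str  # core | loop | terminus | exchange

    def __post_init__(self) -> None:
        if not (0.0 <= self.s2 <= 1.0):
            raise ValueError(f"s2={self.s2} outside [0, 1]")
        if self.tau_e < 0 or self.rex < 0:
            raise ValueError("tau_e and rex must be non-negative")
        if self.class_label not in {"core", "loop", "terminus", "exchange"}:
            raise ValueError(f"unknown class_label {self.class_label!r}")


@dataclass(frozen=True)
class AcquisitionScheme:
    """Spectrometer and delay-list metadata for the simulated experiments.

    Delays are in milliseconds; duplicate_delays lists the delay values
    recorded twice (emitted as separate noisy observations, never
    pre-averaged).  noise_sigma is the Gaussian volume noise as a
    fraction of the initial intensity.
    """

    proton_freq: float = 600.0  # MHz
    nitrogen_freq: float = 60.8  # MHz
    spinlock_b1: float = 1560.0  # Hz
    offset: float = 0.0  # resonance offset from the spin-lock carrier, Hz
    r1_delays: tuple[float, ...] = (10.0, 150.0, 300.0, 450.0, 600.0, 700.0, 900.0, 1200.0)
    r1rho_delays: tuple[float, ...] = (10.0, 50.0, 80.0, 100.0, 120.0, 150.0, 170.0, 190.0)
    duplicate_r1_delays: tuple[float, ...] = (10.0, 600.0)
    duplicate_r1rho_delays: tuple[float, ...] = (10.0, 100.0)
    noise_sigma: float = 0.01
    temperature: float = 303.0  # K

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.r1_delays + self.r1rho_delays):
            raise ValueError("all delays must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        expected = self.proton_freq * abs(GAMMA_N / GAMMA_H)
        if abs(self.nitrogen_freq - expected) / expected > 0.005:
            raise ValueError(
                f"nitrogen_freq {self.nitrogen_freq} MHz inconsistent with "
                f"proton_freq {self.proton_freq} MHz (expected ~{expected:.2f})"
            )

    def expanded_delays(self, which: str) -> tuple[float, ...]:
        """Delay list in seconds with duplicate points repeated."""
        if which == "r1":
            base, dup = self.r1_delays, self.duplicate_r1_delays
        elif which == "r1rho":
            base, dup = self.r1rho_delays, self.duplicate_r1rho_delays
        else:
            raise ValueError("which must be 'r1' or 'r1rho'")
        ms = sorted(tuple(base) + tuple(dup))
        return tuple(d * 1e-3 for d in ms)

    @property
    def constants(self) -> SpinSystemConstants:
        return SpinSystemConstants(proton_freq=self.proton_freq)

    @property
    def spinlock(self) -> SpinLockGeometry:
        return SpinLockGeometry(omega1=self.spinlock_b1, delta_omega=self.offset)


@dataclass(frozen=True)
class SyntheticDataset:
    """Ground truth plus every simulated observable, regenerable from seed."""

    truth: tuple[GroundTruthProfile, ...]
    tau_m: float  # ns
    scheme: AcquisitionScheme
    decays_r1: dict[int, DecaySeries]
    decays_r1rho: dict[int, DecaySeries]
    noe_pairs: dict[int, tuple[float, float, float]]  # (saturated, unsaturated, sigma)
    seed: int

    def __post_init__(self) -> None:
        for p in self.truth:
            i = p.residue_index
            if i not in self.decays_r1 or i not in self.decays_r1rho or i not in self.noe_pairs:
                raise ValueError(f"residue {i} missing from an observable map")


def generate_profile(
    n_residues: int,
    seed: int,
    rex_fraction: float = 0.15,
    n_terminal: int = 3,
    loop_fraction: float = 0.10,
) -> list[GroundTruthProfile]:
    """Seeded per-residue motional ground truth.

    The first and last `n_terminal` residues are flexible termini
    (S^2 in [0.2, 0.6], slow internal motion); one contiguous interior
    loop covering ~`loop_fraction` of the chain is moderately flexible;
    the remaining core draws S^2 in [0.75, 0.9].  A `rex_fraction` subset
    of non-terminal residues carries exchange (Rex in [1, 5] 1/s) and no
    internal-motion time, so every residue is exactly one of the three
    canonical models.
    """
    if n_residues < 5:
        raise ValueError("n_residues must be >= 5")
    rng = np.random.default_rng(seed)
    labels = ["core"] * n_residues
    for i in range(min(n_terminal, n_residues // 2)):
        labels[i] = "terminus"
        labels[n_residues - 1 - i] = "terminus"
    n_loop = int(round(loop_fraction * n_residues))
    if n_loop > 0 and n_residues > 2 * n_terminal + n_loop:
        start = int(rng.integers(n_terminal, n_residues - n_terminal - n_loop))
        for i in range(start, start + n_loop):
            labels[i] = "loop"

    n_rex = int(round(rex_fraction * n_residues))
    eligible = [i for i, lab in enumerate(labels) if lab != "terminus"]
    rex_idx = set(rng.choice(eligible, size=min(n_rex, len(eligible)), replace=False).tolist())

    profiles = []
    for i in range(n_residues):
        lab = labels[i]
        if i in rex_idx:
            s2 = float(rng.uniform(0.75, 0.9)) if lab == "core" else float(rng.uniform(0.55, 0.75))
            profiles.append(GroundTruthProfile(i + 1, s2, 0.0, float(rng.uniform(1.0, 5.0)),
                                               "exchange"))
        elif lab == "terminus":
            profiles.append(
                GroundTruthProfile(i + 1, float(rng.uniform(0.2, 0.6)),
                                   float(rng.uniform(200.0, 800.0)), 0.0, "terminus")
            )
        elif lab == "loop":
            profiles.append(
                GroundTruthProfile(i + 1, float(rng.uniform(0.55, 0.75)),
                                   float(rng.uniform(100.0, 500.0)), 0.0, "loop")
            )
        else:
            # half the core is a pure rigid rotor, half has fast internal motion
            tau_e = 0.0 if rng.random() < 0.5 else float(rng.uniform(20.0, 80.0))
            profiles.append(
                GroundTruthProfile(i + 1, float(rng.uniform(0.75, 0.9)), tau_e, 0.0, "core")
            )
    return profiles


def generate_dataset(
    truth: list[GroundTruthProfile],
    tau_m: float = 7.9,
    scheme: AcquisitionScheme | None = None,
    seed: int = 0,
    amplitude: float = 100.0,
) -> SyntheticDataset:
    """Forward-simulate decay series and NOE pairs from ground truth.

    Volumes are I0 exp(-R t) plus Gaussian noise of sd noise_sigma * I0;
    R1rho decays use R1rho = R1 cos^2(theta) + R2 sin^2(theta) at the
    scheme's spin-lock geometry; NOE pairs are (NOE * I0, I0) with
    independent noise on each.  Duplicate delay points get independent
    noise draws.
    """
    if not truth:
        raise ValueError("truth must contain at least one residue")
    if tau_m <= 0:
        raise ValueError("tau_m must be positive (ns)")
    scheme = scheme or AcquisitionScheme()
    rng = np.random.default_rng(seed)
    consts = scheme.constants
    geom = scheme.spinlock
    s2t, c2t = math.sin(geom.theta) ** 2, math.cos(geom.theta) ** 2
    sd = scheme.noise_sigma * amplitude

    t_r1 = scheme.expanded_delays("r1")
    t_r1rho = scheme.expanded_delays("r1rho")
    decays_r1: dict[int, DecaySeries] = {}
    decays_r1rho: dict[int, DecaySeries] = {}
    noe_pairs: dict[int, tuple[float, float, float]] = {}
    for p in truth:
        rates = forward_rates(p.s2, p.tau_e, p.rex, tau_m, consts, residue_index=p.residue_index)
        r1rho = rates.r1 * c2t + rates.r2 * s2t
        for which, t_list, rate, store in (
            ("r1", t_r1, rates.r1, decays_r1),
            ("r1rho", t_r1rho, r1rho, decays_r1rho),
        ):
            clean = amplitude * np.exp(-rate * np.asarray(t_list))
            noisy = clean + rng.normal(0.0, sd, size=clean.size) if sd > 0 else clean
            store[p.residue_index] = DecaySeries(
                residue_index=p.residue_index,
                delays=t_list,
                volumes=tuple(noisy),
                sigma=sd,
            )
        sat = rates.noe * amplitude + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        unsat = amplitude + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        noe_pairs[p.residue_index] = (float(sat), float(unsat), sd)

    return SyntheticDataset(
        truth=tuple(truth),
        tau_m=tau_m,
        scheme=scheme,
        decays_r1=decays_r1,
        decays_r1rho=decays_r1rho,
        noe_pairs=noe_pairs,
        seed=seed,
    )


def generate_peak_grid(
    peaks: list[tuple[float, float, float, tuple[float, float]]],
    grid_spec: tuple[tuple[float, float], tuple[float, float], float],
) -> PeakGrid:
    """Sum of 2D Lorentzian peaks on a regular grid.

    Each peak is (center_h, center_n, amplitude, (fwhm_h, fwhm_n)) in Hz;
    grid_spec is ((h_min, h_max), (n_min, n_max), spacing).  The peak
    surface is A / (1 + (2 dh / fwhm_h)^2) / (1 + (2 dn / fwhm_n)^2), so
    the grid maximum of an isolated peak is its amplitude.
    """
    (h_min, h_max), (n_min, n_max), spacing = grid_spec
    if spacing <= 0 or h_max <= h_min or n_max <= n_min:
        raise ValueError("invalid grid specification")
    h_axis = np.arange(h_min, h_max + spacing / 2, spacing)
    n_axis = np.arange(n_min, n_max + spacing / 2, spacing)
    values = np.zeros((h_axis.size, n_axis.size))
    for ch, cn, amp, (lwh, lwn) in peaks:
        if lwh <= 0 or lwn <= 0:
            raise ValueError("linewidths must be positive")
        if not (h_min <= ch <= h_max and n_min <= cn <= n_max):
            raise ValueError(f"peak center ({ch}, {cn}) outside grid")
        lh = 1.0 / (1.0 + (2.0 * (h_axis - ch) / lwh) ** 2)
        ln = 1.0 / (1.0 + (2.0 * (n_axis - cn) / lwn) ** 2)
        values += amp * np.outer(lh, ln)
    return PeakGrid(values=values, h_axis=h_axis, n_axis=n_axis)


def generate_toy_structure(sequence: str, geometry: str = "helix",
                           include_cb: bool = False) -> Structure:
    """Ideal-geometry peptide: 'helix' (phi=-57, psi=-47) or 'extended'."""
    if len(sequence) < 4:
        raise ValueError("sequence must have at least 4 residues")
    if geometry == "helix":
        phi_psi = HELIX_PHI_PSI
    elif geometry == "extended":
        phi_psi = EXTENDED_PHI_PSI
    else:
        raise ValueError("geometry must be 'helix' or 'extended'")
    return build_peptide(sequence, phi_psi, include_cb=include_cb)


# -- synthetic four-helix bundle --------------------------------------


def _aligned_helix(sequence: str, first_residue: int, center: np.ndarray,
                   direction: np.ndarray) -> Structure:
    helix = build_peptide(sequence, HELIX_PHI_PSI, include_cb=True,
                          first_residue=first_residue)
    centroid, axis = helix_axis(helix)
    R = _rotation_between(axis, direction / np.linalg.norm(direction))
    t = center - R @ centroid
    return helix.transformed(R, t)


def _loop_atoms(seq: str, first_residue: int, p0: np.ndarray, p1: np.ndarray,
                outward: np.ndarray) -> list[Atom]:
    """Pseudo-backbone for a connecting loop along a bowed Bezier path."""
    k = len(seq)
    bow = 4.0 + 0.5 * k
    ctrl = 0.5 * (p0 + p1) + bow * outward
    atoms: list[Atom] = []
    from .structure import AA_3LETTER

    for j in range(k):
        s = (j + 1) / (k + 1)
        ca = (1 - s) ** 2 * p0 + 2 * (1 - s) * s * ctrl + s**2 * p1
        tangent = 2 * (1 - s) * (ctrl - p0) + 2 * s * (p1 - ctrl)
        tangent /= np.linalg.norm(tangent)
        normal = outward - np.dot(outward, tangent) * tangent
        nn = np.linalg.norm(normal)
        normal = normal / nn if nn > 1e-8 else np.array([0.0, 0.0, 1.0])
        resi = first_residue + j
        resname = AA_3LETTER[seq[j]]
        for name, elem, pos in (
            ("N", "N", ca - 1.2 * tangent + 0.3 * normal),
            ("CA", "C", ca),
            ("C", "C", ca + 1.2 * tangent + 0.3 * normal),
            ("O", "O", ca + 1.5 * tangent + 1.4 * normal),
            ("H", "H", ca - 1.5 * tangent - 0.6 * normal),
        ):
            atoms.append(Atom(1, "A", resi, resname, name, elem,
                              float(pos[0]), float(pos[1]), float(pos[2])))
    return atoms


def synthetic_four_helix_bundle(
    sequence: str = SYNTHETIC_SEQUENCE_114,
    helix_spacing: float = 11.0,
) -> Structure:
    """SYNTHETIC stand-in for a small 2S-albumin-like four-helix bundle.

    Not a deposited structure: four ideal helices (22, 17, 16 and 20
    residues) packed antiparallel on a square of side `helix_spacing`,
    connected by bowed loops, with semi-extended N- and C-terminal tails.
    Residues number 1-114.  Intended for structure-derived annotation and
    hydrodynamics on a realistically sized, realistically shaped chain
    when no experimental coordinates are available.
    """
    if len(sequence) != 114:
        raise ValueError("the bundle layout is defined for exactly 114 residues")
    seg = {
        "n_tail": (1, 8),
        "h1": (9, 24),
        "l1": (25, 32),
        "h2": (33, 48),
        "l2": (49, 56),
        "h3": (57, 72),
        "l3": (73, 84),  # hypervariable-like loop
        "h4": (85, 100),
        "c_tail": (101, 114),
    }

    def subseq(name: str) -> str:
        a, b = seg[name]
        return sequence[a - 1 : b]

    d = helix_spacing
    bundle_center = np.array([d / 2, d / 2, 0.0])
    placements = {
        "h1": (np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])),
        "h2": (np.array([d, 0.0, 0.0]), np.array([0.0, 0.0, -1.0])),
        "h3": (np.array([d, d, 0.0]), np.array([0.0, 0.0, 1.0])),
        "h4": (np.array([0.0, d, 0.0]), np.array([0.0, 0.0, -1.0])),
    }
    helices = {
        name: _aligned_helix(subseq(name), seg[name][0], center, direction)
        for name, (center, direction) in placements.items()
    }

    # disordered termini are modelled as compact random-coil stubs (a real
    # deposited model has wiggly, not rod-like, tails)
    coil_cycle = [(-80.0, -40.0), (-150.0, 100.0), (-70.0, 140.0)]

    def coil(seq: str, first_residue: int):
        torsions = [coil_cycle[j % 3] for j in range(len(seq))]
        return build_peptide(seq, torsions, include_cb=True, first_residue=first_residue)

    def place_tail(tail, direction: np.ndarray, attach: np.ndarray, inward: bool):
        direction = direction / np.linalg.norm(direction)
        cen, axis = helix_axis(tail)
        R = _rotation_between(axis, -direction if inward else direction)
        ca = tail.select(atom_names=["CA"]).coords()
        length = float(np.linalg.norm(ca[-1] - ca[0]))
        t = (attach + direction * (length / 2 + 3.0)) - R @ cen
        return tail.transformed(R, t)

    atoms: list[Atom] = []
    # N-terminal tail points down-and-out from the start of helix 1
    u = np.array([-0.5, -0.5, -0.7])
    attach = helices["h1"].atom(seg["h1"][0], "N").position
    atoms += place_tail(coil(subseq("n_tail"), 1), u, attach, inward=True).atoms

    for name in ("h1", "h2", "h3", "h4"):
        atoms += helices[name].atoms

    # loops between consecutive helices
    for loop, prev, nxt in (("l1", "h1", "h2"), ("l2", "h2", "h3"), ("l3", "h3", "h4")):
        p0 = helices[prev].atom(seg[prev][1], "CA").position
        p1 = helices[nxt].atom(seg[nxt][0], "CA").position
        mid = 0.5 * (p0 + p1)
        outward = mid - bundle_center
        outward[2] = 0.0
        n = np.linalg.norm(outward)
        outward = outward / n if n > 1e-8 else np.array([1.0, 0.0, 0.0])
        atoms += _loop_atoms(subseq(loop), seg[loop][0], p0, p1, outward)

    # C-terminal tail from the end of helix 4
    v = np.array([-0.5, 0.5, -0.7])
    attach = helices["h4"].atom(seg["h4"][1], "C").position
    atoms += place_tail(coil(subseq("c_tail"), seg["c_tail"][0]), v, attach,
                        inward=False).atoms

    return Structure(atoms)
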