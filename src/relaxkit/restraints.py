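"""NOE restraint taxonomy and metal:protein stoichiometry arithmetic."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RestraintRecord", "classify_restraints", "stoichiometry_ratio"]


@dataclass(frozen=True)
class RestraintRecord:
    """One NOE distance restraint between residues i and j."""

    residue_i: int
    residue_j: int
    atom_i: str | None = None
    atom_j: str | None = None

    def __post_init__(self) -> None:
        if self.residue_i < 1 or self.residue_j < 1:
            raise ValueError("residue indices are 1-based (>= 1)")


def classify_restraints(restraints: list[RestraintRecord]) -> dict[str, int]:
    """Partition restraints by sequence separation.

    intra: i = j; sequential: |i - j| = 1; short: 1 < |i - j| <= 4;
    long: |i - j| > 4.  The four categories are disjoint and exhaustive.
    """
    counts = {"intra": 0, "sequential": 0, "short": 0, "long": 0}
    for r in restraints:
        sep = abs(r.residue_i - r.residue_j)
        if sep == 0:
            counts["intra"] += 1
        elif sep == 1:
            counts["sequential"] += 1
        elif sep <= 4:
            counts["short"] += 1
        else:
            counts["long"] += 1
    return counts


def stoichiometry_ratio(
    protein_conc: float, metal_conc: float, rel_tol: float = 0.025, max_denominator: int = 10
) -> tuple[float, str]:
    """Protein:metal stoichiometry from concentrations (same units).

    Returns the raw ratio and its smallest-integer form "p:q": the
    smallest denominator q <= max_denominator for which p/q (p = round
    of ratio * q) reproduces the ratio within `rel_tol`; if none does,
    the best q <= max_denominator is used.  Small denominators are
    preferred over marginally closer fractions because stoichiometries
    are physically small-integer ratios.
    """
    if protein_conc <= 0 or metal_conc <= 0:
        raise ValueError("concentrations must be positive")
    ratio = protein_conc / metal_conc
    best: tuple[float, int, int] | None = None
    for q in range(1, max_denominator + 1):
        p = max(1, round(ratio * q))
        err = abs(p / q - ratio) / ratio
        if err <= rel_tol:
            return ratio, f"{p}:{q}"
        if best is None or err < best[0]:
            best = (err, p, q)
    assert best is not None
    return ratio, f"{best[1]}:{best[2]}"
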