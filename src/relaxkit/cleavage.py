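"""Pepsin cleavage-site prediction and surface-exposure filtering.

The specificity model follows the PeptideCutter documentation for pepsin:
cleavage is scored between positions P1 and P1' of the substrate, with
preference for Phe/Leu (and additionally Trp/Tyr at pH > 2) on either
side of the scissile bond, and documented blocking by Pro at P2/P2',
by His/Lys/Arg at P3 and by Arg at P1.  The rule matrix below is data
captured from that documentation, not code.
"""

from __future__ import annotations

from dataclasses import dataclass

from .structure import AA_3LETTER, Structure
from .surface import shrake_rupley_sasa

__all__ = ["CleavageMap", "PEPSIN_RULES", "pepsin_sites", "exposed_cleavage_sites"]

# Rule matrix: each rule set is a list of alternative clauses; a clause maps
# substrate position -> ("in" | "not_in", residue set).  Positions P3..P2'
# are offsets -2..+2 from P1 (cleavage occurs after P1).  Every referenced
# position must exist in the sequence for a clause to apply.
_PH13_PREFERRED = frozenset("FL")
_PH2_PREFERRED = frozenset("FLWY")


def _pepsin_clauses(preferred: frozenset) -> list[dict[str, tuple[str, frozenset]]]:
    return [
        {  # preferred residue at P1'
            "P3": ("not_in", frozenset("HKR")),
            "P2": ("not_in", frozenset("P")),
            "P1": ("not_in", frozenset("R")),
            "P1'": ("in", preferred),
            "P2'": ("not_in", frozenset("P")),
        },
        {  # preferred residue at P1
            "P3": ("not_in", frozenset("HKR")),
            "P2": ("not_in", frozenset("P")),
            "P1": ("in", preferred),
            "P1'": ("in", frozenset(AA_3LETTER)),
            "P2'": ("not_in", frozenset("P")),
        },
    ]


PEPSIN_RULES: dict[str, list[dict[str, tuple[str, frozenset]]]] = {
    "pepsin_pH1.3": _pepsin_clauses(_PH13_PREFERRED),
    "pepsin_pH>2": _pepsin_clauses(_PH2_PREFERRED),
}

_OFFSETS = {"P3": -2, "P2": -1, "P1": 0, "P1'": 1, "P2'": 2}


@dataclass(frozen=True)
class CleavageMap:
    """Predicted cleavage positions: the bond after residue p is cut."""

    sequence: str
    sites: tuple[int, ...]
    rule_set: str

    def __post_init__(self) -> None:
        for p in self.sites:
            if not (1 <= p < len(self.sequence)):
                raise ValueError(f"site {p} outside 1..{len(self.sequence) - 1}")


def pepsin_sites(sequence: str, rule_set: str = "pepsin_pH1.3") -> CleavageMap:
    """Positions p (1-based) where pepsin cuts between residues p and p+1."""
    sequence = sequence.strip().upper()
    bad = [c for c in sequence if c not in AA_3LETTER]
    if bad:
        raise ValueError(f"unknown residue letter(s): {sorted(set(bad))}")
    if rule_set not in PEPSIN_RULES:
        raise ValueError(f"unknown rule set {rule_set!r}; choose from {sorted(PEPSIN_RULES)}")
    clauses = PEPSIN_RULES[rule_set]
    sites = []
    for p in range(1, len(sequence)):  # P1 at index p-1
        for clause in clauses:
            ok = True
            for pos, (mode, residues) in clause.items():
                idx = (p - 1) + _OFFSETS[pos]
                if idx < 0 or idx >= len(sequence):
                    ok = False
                    break
                aa = sequence[idx]
                if mode == "in" and aa not in residues:
                    ok = False
                    break
                if mode == "not_in" and aa in residues:
                    ok = False
                    break
            if ok:
                sites.append(p)
                break
    return CleavageMap(sequence=sequence, sites=tuple(sites), rule_set=rule_set)


def exposed_cleavage_sites(
    structure: Structure,
    cleavage_map: CleavageMap,
    sasa_threshold: float,
    atoms: tuple[str, ...] = ("N", "H"),
    probe: float = 1.4,
    n_points: int = 480,
) -> tuple[int, ...]:
    """Cleavage sites whose P1-residue backbone N/H exposure exceeds the threshold.

    The accessibility of the configured atoms (default the backbone amide
    N and H) of the P1 residue is summed and compared against
    `sasa_threshold` (A^2); there is deliberately no default threshold.
    """
    seq = structure.sequence()
    if seq != cleavage_map.sequence:
        raise ValueError("structure sequence does not match the cleavage map sequence")
    include_h = any(a.startswith("H") for a in atoms)
    sasa = shrake_rupley_sasa(structure, probe=probe, n_points=n_points,
                              include_hydrogens=include_h)
    resis = structure.model().residue_indices()
    exposed = []
    for p in cleavage_map.sites:
        resi = resis[p - 1]
        area = 0.0
        for name in atoms:
            area += sasa.areas.get((resi, name), 0.0)
        if area > sasa_threshold:
            exposed.append(p)
    return tuple(exposed)
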