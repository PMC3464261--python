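"""Plain-text tables exchanged between the pipeline stages.

All tables are tab-separated with a header row: decay tables
(residue, delay_ms, volume, sigma), rate tables (residue, R1, R1_err,
R2, R2_err, NOE, NOE_err), model-free result tables and two-column
bleach lists.  Ground truth is written as a key-value table so a
simulation can be audited later.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .modelfree import ModelFreeResult, RelaxationTriple
from .rates import DecaySeries
from .synthetic import GroundTruthProfile, SyntheticDataset

__all__ = [
    "write_decay_table",
    "read_decay_table",
    "write_noe_table",
    "read_noe_table",
    "write_rates_table",
    "read_rates_table",
    "write_modelfree_table",
    "write_truth_table",
    "read_bleach_list",
    "write_bleach_list",
    "write_dataset",
]


def write_decay_table(decays: dict[int, DecaySeries], path: str | Path) -> None:
    rows = []
    for resi in sorted(decays):
        s = decays[resi]
        for d, v in zip(s.delays, s.volumes):
            rows.append({"residue": resi, "delay_ms": d * 1e3, "volume": v, "sigma": s.sigma})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_decay_table(path: str | Path) -> dict[int, DecaySeries]:
    df = pd.read_csv(path, sep="\t")
    out: dict[int, DecaySeries] = {}
    for resi, grp in df.groupby("residue"):
        out[int(resi)] = DecaySeries(
            residue_index=int(resi),
            delays=tuple(grp["delay_ms"] * 1e-3),
            volumes=tuple(grp["volume"]),
            sigma=float(grp["sigma"].iloc[0]),
        )
    return out


def write_noe_table(noe_pairs: dict[int, tuple[float, float, float]], path: str | Path) -> None:
    rows = [
        {"residue": resi, "saturated": s, "unsaturated": u, "sigma": sd}
        for resi, (s, u, sd) in sorted(noe_pairs.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_noe_table(path: str | Path) -> dict[int, tuple[float, float, float]]:
    df = pd.read_csv(path, sep="\t")
    return {
        int(r.residue): (float(r.saturated), float(r.unsaturated), float(r.sigma))
        for r in df.itertuples()
    }


def write_rates_table(triples: list[RelaxationTriple], path: str | Path) -> None:
    rows = [
        {
            "residue": t.residue_index,
            "R1": t.r1, "R1_err": t.r1_err,
            "R2": t.r2, "R2_err": t.r2_err,
            "NOE": t.noe, "NOE_err": t.noe_err,
        }
        for t in triples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rates_table(path: str | Path) -> list[RelaxationTriple]:
    df = pd.read_csv(path, sep="\t")
    return [
        RelaxationTriple(
            residue_index=int(r.residue),
            r1=float(r.R1), r1_err=float(r.R1_err),
            r2=float(r.R2), r2_err=float(r.R2_err),
            noe=float(r.NOE), noe_err=float(r.NOE_err),
        )
        for r in df.itertuples()
    ]


def write_modelfree_table(results: list[ModelFreeResult], path: str | Path) -> None:
    rows = [
        {
            "residue": r.residue_index, "model": r.model, "S2": r.s2,
            "tau_e_ps": r.tau_e, "rex": r.rex, "chi2": r.chi2, "dof": r.dof,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth_table(truth: list[GroundTruthProfile] | tuple, path: str | Path) -> None:
    rows = [
        {
            "residue": p.residue_index, "s2": p.s2, "tau_e_ps": p.tau_e,
            "rex": p.rex, "class": p.class_label,
        }
        for p in truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bleach_list(entries: tuple[tuple[int, str], ...], path: str | Path) -> None:
    pd.DataFrame([{"residue": r, "atom": a} for r, a in entries]).to_csv(
        path, sep="\t", index=False
    )


def read_bleach_list(path: str | Path) -> tuple[tuple[int, str], ...]:
    df = pd.read_csv(path, sep="\t")
    return tuple((int(r.residue), str(r.atom)) for r in df.itertuples())


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write every observable of a synthetic dataset into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_decay_table(dataset.decays_r1, out / "decays_r1.tsv")
    write_decay_table(dataset.decays_r1rho, out / "decays_r1rho.tsv")
    write_noe_table(dataset.noe_pairs, out / "noe_pairs.tsv")
    write_truth_table(dataset.truth, out / "truth.tsv")
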