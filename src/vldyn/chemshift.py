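"""Chemical-shift tables, amide shift perturbations and ¹³C correlations.

Comparing a mutant's backbone shifts with the reference protein answers two
questions: where does the amide environment change (combined ¹H/¹⁵N
perturbation, Delta_delta_amide = sqrt(ddH^2 + (ddN/5)^2), with the ¹⁵N
difference down-weighted by its larger shift range), and does the backbone
conformation change (¹³Ca/¹³Cb shifts are conformation-sensitive, so a
near-unity correlation with the mutated sites excluded indicates a
preserved fold).

Shift tables are plain tab-separated text: residue_id, atom, shift_ppm.
Residue identifiers are strings so that insertion-code numbering such as
"27d" survives a round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ShiftTable",
    "CSPProfile",
    "read_shift_table",
    "write_shift_table",
    "amide_csp",
    "carbon_correlation",
]

ATOMS = ("N", "H", "CA", "CB")
N_WEIGHT = 5.0  # 15N differences scaled by 1/5 in the combined CSP


@dataclass
class ShiftTable:
    """Per-residue, per-atom chemical shifts (ppm) for one protein."""

    protein_name: str
    records: dict[str, dict[str, float]] = field(default_factory=dict)
    unassigned: set[str] = field(default_factory=set)

    def add(self, residue_id: str, atom: str, shift: float) -> None:
        if atom not in ATOMS:
            raise ValueError(f"unknown atom name {atom!r}; expected one of {ATOMS}")
        per_res = self.records.setdefault(str(residue_id), {})
        if atom in per_res:
            raise ValueError(
                f"duplicate shift entry for residue {residue_id}, atom {atom}"
            )
        per_res[atom] = float(shift)

    def get(self, residue_id: str, atom: str) -> float | None:
        return self.records.get(str(residue_id), {}).get(atom)

    @property
    def residues(self) -> list[str]:
        return list(self.records)


@dataclass
class CSPProfile:
    """Combined amide chemical-shift perturbations versus a reference."""

    dd_amide: dict[str, float]  # ppm, per residue
    dd_h: dict[str, float]
    dd_n: dict[str, float]
    mean: float
    sd: float


def read_shift_table(path: str | Path, protein_name: str | None = None) -> ShiftTable:
    """Read a tab-separated shift table (residue_id, atom, shift_ppm)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"residue_id": str})
    required = {"residue_id", "atom", "shift_ppm"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    table = ShiftTable(protein_name or path.stem)
    for row in df.itertuples():
        shift = float(row.shift_ppm)  # raises on non-numeric
        if not math.isfinite(shift):
            raise ValueError(f"non-finite shift for residue {row.residue_id}")
        table.add(str(row.residue_id), str(row.atom), shift)
    return table


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    rows = [
        {"residue_id": rid, "atom": atom, "shift_ppm": shift}
        for rid, atoms in table.records.items()
        for atom, shift in atoms.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def amide_csp(ref: ShiftTable, mut: ShiftTable) -> CSPProfile:
    """Combined amide CSP per residue common to both tables.

    Delta_delta_amide = sqrt(ddH^2 + (ddN/5)^2).  Residues missing an N or H
    assignment in either table are omitted (not zero-filled), so the mean
    and sd run over detectable residues only.
    """
    dd_amide: dict[str, float] = {}
    dd_h: dict[str, float] = {}
    dd_n: dict[str, float] = {}
    for rid in ref.records:
        h_r, n_r = ref.get(rid, "H"), ref.get(rid, "N")
        h_m, n_m = mut.get(rid, "H"), mut.get(rid, "N")
        if None in (h_r, n_r, h_m, n_m):
            continue
        ddh = h_m - h_r
        ddn = n_m - n_r
        dd_h[rid] = ddh
        dd_n[rid] = ddn
        dd_amide[rid] = math.sqrt(ddh**2 + (ddn / N_WEIGHT) ** 2)
    if not dd_amide:
        raise ValueError("no residues with amide assignments common to both tables")
    vals = np.array(list(dd_amide.values()))
    return CSPProfile(
        dd_amide=dd_amide,
        dd_h=dd_h,
        dd_n=dd_n,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
    )


def carbon_correlation(
    ref: ShiftTable,
    mut: ShiftTable,
    atom: str = "CA",
    exclude: set[str] | None = None,
) -> tuple[float, float, float, int]:
    """OLS correlation of mutant vs reference ¹³C shifts.

    Returns (R^2, slope, intercept, n).  ``exclude`` removes residues (the
    mutated sites) from the regression; at least three common residues must
    remain.
    """
    if atom not in ("CA", "CB"):
        raise ValueError("carbon correlation is defined for CA or CB")
    exclude = {str(r) for r in (exclude or set())}
    x, y = [], []
    for rid in ref.records:
        if rid in exclude:
            continue
        a, b = ref.get(rid, atom), mut.get(rid, atom)
        if a is None or b is None:
            continue
        x.append(a)
        y.append(b)
    if len(x) < 3:
        raise ValueError(f"only {len(x)} common {atom} residues; need >= 3")
    x = np.array(x)
    y = np.array(y)
    if np.allclose(x, y):
        # exact identity short-circuits linregress round-off
        return 1.0, 1.0, 0.0, len(x)
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.slope), float(res.intercept), len(x)


def csp_to_frame(profile: CSPProfile) -> pd.DataFrame:
    """CSP profile as a tidy table (one row per residue)."""
    return pd.DataFrame(
        {
            "residue_id": list(profile.dd_amide),
            "dd_amide_ppm": list(profile.dd_amide.values()),
            "dd_h_ppm": [profile.dd_h[r] for r in profile.dd_amide],
            "dd_n_ppm": [profile.dd_n[r] for r in profile.dd_amide],
        }
    )
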