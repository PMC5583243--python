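"""Structural comparison of point-mutant models of a two-chain dimer.

Given two coordinate sets of the same homodimer (e.g. an energy-minimised
reference and a point-mutant model), this module quantifies what changed:
the least-squares superposition RMS, the hydrogen bonds gained, lost or
altered in length, and which residues belong to the dimer interface by a
heavy-atom distance-contact criterion.

Hydrogen bonds are detected geometrically: a donor N/O and acceptor N/O
from different residues within 3.5 A (heavy-atom distance), with a
donor-H...acceptor angle of at least 120 degrees whenever the donor
hydrogen is present in the model.  Bond lengths are reported as
donor-acceptor distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Structure",
    "HBond",
    "read_pdb",
    "write_pdb",
    "superpose_rms",
    "transform_rms",
    "hbond_inventory",
    "diff_hbonds",
    "interface_residues",
]

BACKBONE = ("N", "CA", "C", "O")
HBOND_MAX_DA = 3.5  # A, donor-acceptor heavy-atom cutoff
HBOND_MIN_ANGLE = 120.0  # degrees, D-H...A when H present
INTERFACE_CUTOFF = 5.0  # A, heavy-atom contact distance


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_id: str  # string, supports insertion codes
    residue_name: str
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class Structure:
    """Atomic model of a (usually two-chain) protein."""

    atoms: list[Atom]
    name: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for a in self.atoms:
            key = (a.chain, a.residue_id, a.name)
            if key in self._index:
                raise ValueError(f"duplicate atom {key}")
            if not all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates for {key}")
            self._index[key] = a

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def get(self, chain: str, residue_id: str, name: str) -> Atom | None:
        return self._index.get((chain, str(residue_id), name))

    def atoms_of(self, chain: str | None = None, heavy_only: bool = False):
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if heavy_only and a.element == "H":
                continue
            yield a

    def coords(self, atoms) -> np.ndarray:
        return np.array([a.xyz for a in atoms], dtype=float)


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name.lstrip("0123456789")
    if name.startswith("H"):
        return "H"
    return name[:1]


def read_pdb(path: str | Path, name: str | None = None) -> Structure:
    """Read ATOM/HETATM records from a PDB file via Bio.PDB.

    Alternate locations keep the highest-occupancy conformer; waters are
    skipped.  Residue ids include insertion codes ("27d"-style lowercase).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = parser.get_structure(name or Path(path).stem, str(path))[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip() and res.resname in ("HOH", "WAT"):
                continue
            rid = f"{resseq}{icode.strip().lower()}"
            for atom in res:
                if atom.is_disordered():
                    atom = max(atom, key=lambda a: a.get_occupancy() or 0.0)
                element = (atom.element or "").strip() or _guess_element(atom.get_name())
                atoms.append(
                    Atom(
                        chain=chain.id.strip() or "A",
                        residue_id=rid,
                        residue_name=res.resname,
                        name=atom.get_name(),
                        element=element,
                        xyz=tuple(float(x) for x in atom.coord),
                    )
                )
    return Structure(atoms=atoms, name=name or Path(path).stem)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write plain ATOM records (enough for round-trips and visualisation)."""
    lines = []
    serial = 1
    for a in structure.atoms:
        num = "".join(ch for ch in a.residue_id if ch.isdigit())
        icode = "".join(ch for ch in a.residue_id if ch.isalpha()).upper()[:1] or " "
        nm = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {nm:<4.4s} {a.residue_name:<3.3s} {a.chain:1.1s}"
            f"{int(num):4d}{icode}   "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _matched_atoms(ref: Structure, mob: Structure, selection) -> list[tuple[Atom, Atom]]:
    sel = set(selection) if selection is not None else None
    pairs = []
    for a in ref.atoms:
        if sel is not None and a.name not in sel:
            continue
        b = mob.get(a.chain, a.residue_id, a.name)
        if b is not None:
            pairs.append((a, b))
    return pairs


def superpose_rms(
    ref: Structure,
    mob: Structure,
    selection=BACKBONE,
    align_on=None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares (Kabsch) superposition of matched atoms.

    Atoms are matched by (chain, residue, atom-name) key and filtered by
    ``selection`` (atom names; None selects everything).  The optimal
    rotation/translation is computed on ``align_on`` (defaults to
    ``selection``) and the RMS is reported over ``selection`` after the
    transform.  Returns (rms A, rotation 3x3, translation 3).
    """
    align_pairs = _matched_atoms(ref, mob, align_on if align_on is not None else selection)
    if len(align_pairs) < 3:
        raise ValueError(f"only {len(align_pairs)} matched atoms; need >= 3 to align")
    x = np.array([a.xyz for a, _ in align_pairs])
    y = np.array([b.xyz for _, b in align_pairs])
    spread = np.linalg.svd(x - x.mean(axis=0), compute_uv=False)
    if spread[1] < 1e-6:
        warnings.warn("alignment selection is (near-)collinear; rotation ill-determined")

    from Bio.SVDSuperimposer import SVDSuperimposer

    sup = SVDSuperimposer()
    sup.set(x, y)  # rotates y onto x
    sup.run()
    rot, tran = sup.get_rotran()

    rms_pairs = _matched_atoms(ref, mob, selection)
    xr = np.array([a.xyz for a, _ in rms_pairs])
    yr = np.array([b.xyz for _, b in rms_pairs]) @ rot + tran
    rms = float(np.sqrt(np.mean(np.sum((xr - yr) ** 2, axis=1))))
    return rms, rot, tran


def transform_rms(ref: Structure, mob: Structure, rot, tran, selection=None) -> float:
    """RMS over matched ``selection`` atoms after applying a given transform."""
    pairs = _matched_atoms(ref, mob, selection)
    x = np.array([a.xyz for a, _ in pairs])
    y = np.array([b.xyz for _, b in pairs]) @ np.asarray(rot) + np.asarray(tran)
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


@dataclass(frozen=True)
class HBond:
    donor: tuple[str, str, str]  # (chain, residue_id, atom)
    acceptor: tuple[str, str, str]
    length: float  # donor-acceptor heavy-atom distance, A
    interchain: bool

    @property
    def key(self) -> tuple:
        return (self.donor, self.acceptor)


def _donor_hydrogens(structure: Structure) -> dict[tuple, list[Atom]]:
    """Map heavy atom key -> bonded hydrogens (within 1.25 A, same residue)."""
    out: dict[tuple, list[Atom]] = {}
    hydrogens = [a for a in structure.atoms if a.element == "H"]
    if not hydrogens:
        return out
    heavies = [a for a in structure.atoms if a.element in ("N", "O")]
    if not heavies:
        return out
    tree = cKDTree(structure.coords(heavies))
    for h in hydrogens:
        dist, idx = tree.query(h.xyz)
        heavy = heavies[idx]
        if dist <= 1.25 and heavy.chain == h.chain and heavy.residue_id == h.residue_id:
            out.setdefault((heavy.chain, heavy.residue_id, heavy.name), []).append(h)
    return out


def hbond_inventory(
    structure: Structure,
    max_da: float = HBOND_MAX_DA,
    min_angle: float = HBOND_MIN_ANGLE,
) -> list[HBond]:
    """Geometric hydrogen-bond inventory (N/O donors and acceptors).

    Every N/O is considered a potential donor (the geometry filter with the
    attached hydrogen, when present, removes non-donating pairs) and every
    N/O a potential acceptor.  Pairs within the same residue are skipped.
    """
    polar = [a for a in structure.atoms if a.element in ("N", "O")]
    if not polar:
        return []
    h_by_heavy = _donor_hydrogens(structure)
    tree = cKDTree(structure.coords(polar))
    bonds: list[HBond] = []
    for i, j in sorted(tree.query_pairs(max_da)):
        for d, a in ((polar[i], polar[j]), (polar[j], polar[i])):
            if (d.chain, d.residue_id) == (a.chain, a.residue_id):
                continue
            dist = float(np.linalg.norm(np.subtract(d.xyz, a.xyz)))
            hs = h_by_heavy.get((d.chain, d.residue_id, d.name), [])
            if hs:
                ok = False
                for h in hs:
                    v1 = np.subtract(d.xyz, h.xyz)
                    v2 = np.subtract(a.xyz, h.xyz)
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                    if ang >= min_angle:
                        ok = True
                        break
                if not ok:
                    continue
            elif d.element == "O" and not hs:
                # carbonyl/carboxyl O without H cannot donate
                continue
            bonds.append(
                HBond(
                    donor=(d.chain, d.residue_id, d.name),
                    acceptor=(a.chain, a.residue_id, a.name),
                    length=dist,
                    interchain=d.chain != a.chain,
                )
            )
    return bonds


def diff_hbonds(
    ref: Structure,
    mut: Structure,
    length_tol: float = 0.1,
    **hbond_kwargs,
) -> dict[str, list]:
    """Hydrogen bonds lost, gained or changed in length between two models.

    Bonds are matched by their (donor, acceptor) atom keys; matched bonds
    whose donor-acceptor distance moved by more than ``length_tol`` A are
    reported as changed with the signed delta.
    """
    ref_bonds = {b.key: b for b in hbond_inventory(ref, **hbond_kwargs)}
    mut_bonds = {b.key: b for b in hbond_inventory(mut, **hbond_kwargs)}
    lost = [ref_bonds[k] for k in sorted(set(ref_bonds) - set(mut_bonds))]
    gained = [mut_bonds[k] for k in sorted(set(mut_bonds) - set(ref_bonds))]
    changed = []
    for k in sorted(set(ref_bonds) & set(mut_bonds)):
        delta = mut_bonds[k].length - ref_bonds[k].length
        if abs(delta) > length_tol:
            changed.append((ref_bonds[k], round(delta, 3)))
    return {"lost": lost, "gained": gained, "changed": changed}


def interface_residues(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    cutoff: float = INTERFACE_CUTOFF,
) -> dict[str, set[str]]:
    """Residues with any heavy atom within ``cutoff`` of the partner chain."""
    for ch in (chain_a, chain_b):
        if ch not in structure.chains:
            raise ValueError(f"chain {ch!r} not present in structure")
    atoms_a = list(structure.atoms_of(chain_a, heavy_only=True))
    atoms_b = list(structure.atoms_of(chain_b, heavy_only=True))
    out = {chain_a: set(), chain_b: set()}
    if not atoms_a or not atoms_b:
        return out
    tree_b = cKDTree(structure.coords(atoms_b))
    pairs = cKDTree(structure.coords(atoms_a)).query_ball_tree(tree_b, cutoff)
    for i, hits in enumerate(pairs):
        if hits:
            out[chain_a].add(atoms_a[i].residue_id)
            for j in hits:
                out[chain_b].add(atoms_b[j].residue_id)
    return out
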