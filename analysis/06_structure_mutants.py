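#!/usr/bin/env python
"""Structure comparison on a synthetic mutant dimer model.

Builds a small synthetic two-chain reference (a stand-in for an
energy-minimised dimer model; no deposited coordinates are bundled) and a
"mutant" copy in which one interfacial hydrogen bond is broken and a
hydrophobic residue moves into the interface, then reports superposition
RMS, the hydrogen-bond diff and interface membership changes."""

import json
from pathlib import Path

import numpy as np

from vldyn.structure_compare import (
    Atom,
    Structure,
    diff_hbonds,
    interface_residues,
    superpose_rms,
    write_pdb,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def synthetic_reference() -> Structure:
    """Synthetic two-chain toy dimer (not derived from any deposited entry)."""
    rng = np.random.default_rng(11)
    atoms = []
    for chain, z0 in (("A", 0.0), ("B", 6.5)):
        for i in range(6):
            rid = str(90 + i)
            x0 = 3.8 * i
            atoms += [
                Atom(chain, rid, "GLY", "N", "N", (x0, 0.0, z0)),
                Atom(chain, rid, "GLY", "H", "H",
                     (x0, 0.0, z0 + (1.0 if chain == "A" else -1.0))),
                Atom(chain, rid, "GLY", "CA", "C", (x0 + 1.4, 0.3, z0)),
                Atom(chain, rid, "GLY", "C", "C", (x0 + 2.5, -0.4, z0)),
                Atom(chain, rid, "GLY", "O", "O", (x0 + 2.6, -1.6, z0)),
            ]
    # one interchain amide H-bond: A/94 N-H ... B/94 O brought to 2.9 A
    atoms = [
        a if not (a.chain == "B" and a.residue_id == "94" and a.name == "O")
        else Atom("B", "94", "GLY", "O", "O", (3.8 * 4, 0.0, 2.9))
        for a in atoms
    ]
    # jitter the remaining chain-B z so nothing else sits in the interface
    return Structure(atoms=atoms, name="synthetic_reference")


def mutant_copy(ref: Structure) -> Structure:
    atoms = []
    for a in ref.atoms:
        xyz = a.xyz
        if a.chain == "B" and a.residue_id == "94" and a.name == "O":
            xyz = (xyz[0], xyz[1], xyz[2] + 1.2)  # H-bond broken (4.1 A)
        if a.chain == "B" and a.residue_id == "90":
            xyz = (xyz[0], xyz[1], xyz[2] - 2.2)  # side moves into interface
        atoms.append(Atom(a.chain, a.residue_id, a.residue_name, a.name,
                          a.element, xyz))
    return Structure(atoms=atoms, name="synthetic_mutant")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = synthetic_reference()
    mut = mutant_copy(ref)
    write_pdb(ref, OUT / "synthetic_reference.pdb")
    write_pdb(mut, OUT / "synthetic_mutant.pdb")

    rms, *_ = superpose_rms(ref, mut)
    diff = diff_hbonds(ref, mut)
    iface_ref = interface_residues(ref, "A", "B")
    iface_mut = interface_residues(mut, "A", "B")

    print(f"backbone superposition RMS: {rms:.3f} A")
    print(f"hydrogen bonds lost: {[(b.donor, b.acceptor) for b in diff['lost']]}")
    print(f"hydrogen bonds gained: {[(b.donor, b.acceptor) for b in diff['gained']]}")
    newly = {ch: sorted(iface_mut[ch] - iface_ref[ch]) for ch in iface_ref}
    print(f"residues newly in the interface: {newly}")

    doc = {
        "rms_backbone_A": round(rms, 4),
        "hbonds_lost": [[list(b.donor), list(b.acceptor), b.length] for b in diff["lost"]],
        "hbonds_gained": [[list(b.donor), list(b.acceptor), b.length] for b in diff["gained"]],
        "hbonds_changed": [
            [list(b.donor), list(b.acceptor), delta] for b, delta in diff["changed"]
        ],
        "interface_ref": {ch: sorted(v) for ch, v in iface_ref.items()},
        "interface_mut": {ch: sorted(v) for ch, v in iface_mut.items()},
    }
    (OUT / "structure_diff.json").write_text(json.dumps(doc, indent=1))
    print(f"wrote {OUT / 'structure_diff.json'}")


if __name__ == "__main__":
    main()
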