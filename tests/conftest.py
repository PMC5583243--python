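import numpy as np
import pytest

from vldyn.exchange import DispersionCurve, ExchangeParams, r2eff_two_site
from vldyn.structure_compare import Atom, Structure
from vldyn.synthetic import NU_CPMG_DEFAULT

NU = np.array(NU_CPMG_DEFAULT)
FIELDS = (600.0, 800.0)


@pytest.fixture(scope="session")
def nu_grid():
    return NU.copy()


@pytest.fixture(scope="session")
def moderate_truth():
    """A detectable, comfortably fittable exchange parameter set."""
    return ExchangeParams(pb=0.04, kex=1500.0, dw=2.0, r20={600.0: 12.0, 800.0: 13.0})


def make_curves(params, noise_sd=0.0, rng=None, rid="42", nu=None, fields=FIELDS):
    nu = NU if nu is None else np.asarray(nu, dtype=float)
    out = {}
    for f in fields:
        clean = r2eff_two_site(params, nu, f)
        if noise_sd and rng is not None:
            clean = clean + rng.normal(0.0, noise_sd, size=nu.shape)
        out[f] = DispersionCurve(
            residue_id=rid, field=f, nu=nu.copy(), r2eff=clean,
            sigma=np.full_like(nu, max(noise_sd, 1e-6)),
        )
    return out


@pytest.fixture
def curve_factory():
    return make_curves


def _res(chain, rid, rname, atoms):
    return [
        Atom(chain=chain, residue_id=str(rid), residue_name=rname, name=n,
             element=e, xyz=tuple(map(float, xyz)))
        for n, e, xyz in atoms
    ]


@pytest.fixture
def toy_dimer():
    """Two short chains: one backbone H-bond across the interface.

    Chain A residue 94 donates its amide (N-H) to the chain B residue 55
    carbonyl O at 2.9 A with a collinear hydrogen.
    """
    atoms = []
    atoms += _res("A", 94, "THR", [
        ("N", "N", (0.0, 0.0, 0.0)),
        ("H", "H", (0.0, 0.0, 1.0)),
        ("CA", "C", (1.4, 0.2, -0.6)),
        ("C", "C", (2.6, -0.5, 0.0)),
        ("O", "O", (2.7, -1.7, 0.1)),
    ])
    atoms += _res("A", 95, "GLY", [
        ("N", "N", (3.6, 0.3, 0.4)),
        ("CA", "C", (4.9, -0.2, 0.7)),
        ("C", "C", (6.0, 0.8, 0.6)),
        ("O", "O", (7.1, 0.5, 1.0)),
    ])
    atoms += _res("B", 55, "GLU", [
        ("C", "C", (0.4, -0.9, 3.6)),
        ("O", "O", (0.0, 0.0, 2.9)),  # acceptor, 2.9 A from A/94/N along z
        ("N", "N", (1.0, -2.0, 4.0)),
        ("CA", "C", (2.2, -2.6, 4.5)),
    ])
    atoms += _res("B", 56, "ALA", [
        ("N", "N", (-30.0, 0.0, 0.0)),
        ("CA", "C", (-31.4, 0.1, 0.2)),
        ("C", "C", (-32.3, -1.1, 0.0)),
        ("O", "O", (-33.5, -1.0, 0.2)),
    ])
    return Structure(atoms=atoms, name="toy_dimer")


def rigid_transform(structure, rot, tran, name=None):
    rot = np.asarray(rot)
    tran = np.asarray(tran)
    moved = [
        Atom(chain=a.chain, residue_id=a.residue_id, residue_name=a.residue_name,
             name=a.name, element=a.element,
             xyz=tuple(np.asarray(a.xyz) @ rot + tran))
        for a in structure.atoms
    ]
    return Structure(atoms=moved, name=name or structure.name + "_moved")


@pytest.fixture
def rigid_transformer():
    return rigid_transform


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.cos(angle / 2.0)
    b, c, d = -axis * np.sin(angle / 2.0)
    return np.array(
        [
            [a*a + b*b - c*c - d*d, 2*(b*c + a*d), 2*(b*d - a*c)],
            [2*(b*c - a*d), a*a + c*c - b*b - d*d, 2*(c*d + a*b)],
            [2*(b*d + a*c), 2*(c*d - a*b), a*a + d*d - b*b - c*c],
        ]
    )


@pytest.fixture
def rot_factory():
    return rotation_matrix
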