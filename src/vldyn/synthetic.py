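"""Ground-truth protein models and seeded synthetic NMR/CD datasets.

The generator emulates the study system: a 114-residue immunoglobulin
light-chain variable domain present as a homodimer (tumbling at
tauc ~ 13-15 ns), with three contiguous regions of millisecond-timescale
two-site exchange — the N-terminal stretch (residues 1-9), the FR2/CDR2
segment (~35-60) and the CDR3 segment (~88-102).  Within a region all
residues share one minor-state population and one exchange rate (partial
unfolding of a contiguous stretch is cooperative), while the ¹⁵N shift
difference to the minor state varies per residue.  Residue numbering
includes one insertion code ("27d", a CDR1 insertion of the kappa
numbering convention) so that downstream code must treat identifiers as
strings, and six prolines which carry no amide signals.

Profiles
--------
``LEN-like``   quiescent-dimer conditions: minor-state populations of
               2-4% in the three regions, none outside.
``SMA-like``   destabilised-dimer conditions: populations of 8-15% with
               larger shift differences, so that a subset of region
               residues is exchange-broadened beyond detection.
``quenched``   dynamics suppressed everywhere (the T94H-like phenotype).

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemshift import ShiftTable
from .dimer_cd import CDTitration, DimerModel, predict_ellipticity
from .exchange import DispersionCurve, ExchangeParams, r2eff_two_site, rex_from_params
from .fast_relax import rates_isotropic

__all__ = [
    "GroundTruthProtein",
    "SyntheticDataset",
    "make_truth",
    "default_residue_ids",
    "simulate_dispersion_dataset",
    "simulate_relaxation_table",
    "simulate_cd_titration",
    "simulate_shift_tables",
    "NU_CPMG_DEFAULT",
    "FIELDS_DEFAULT",
]

#: Default CPMG frequency grid, Hz: 12 points spanning the experimental
#: endpoints 33.3 and 1000 Hz.
NU_CPMG_DEFAULT = (
    33.3, 66.7, 100.0, 150.0, 200.0, 300.0,
    400.0, 500.0, 600.0, 700.0, 850.0, 1000.0,
)

#: Static fields, ¹H MHz (14.1 and 18.8 T).
FIELDS_DEFAULT = (600.0, 800.0)

REGIONS_DEFAULT = (("region1", 1, 9), ("region2", 35, 60), ("region3", 88, 102))
PROLINES_DEFAULT = frozenset({"8", "40", "43", "59", "80", "95"})
DETECT_LIMIT_DEFAULT = 25.0  # s^-1 R_ex at the lower field; beyond it the
#                              peak is taken as broadened beyond detection


def default_residue_ids(n_residues: int = 114) -> list[str]:
    """Sequential ids 1..n-1 with one inserted residue '27d'."""
    ids = [str(i) for i in range(1, 28)]
    ids.append("27d")
    ids.extend(str(i) for i in range(28, n_residues))
    assert len(ids) == n_residues
    return ids


def _numeric(residue_id: str) -> int:
    digits = "".join(ch for ch in residue_id if ch.isdigit())
    return int(digits)


@dataclass
class GroundTruthProtein:
    """Known-parameter protein model from which datasets are simulated."""

    n_residues: int
    residue_ids: list[str]
    proline_positions: set[str]
    regions: list[tuple[str, int, int]]
    per_residue_truth: dict[str, ExchangeParams]
    detect_limit: float = DETECT_LIMIT_DEFAULT
    tauc_true: float = 13.5  # ns
    profile: str = "custom"
    region_truth: dict[str, tuple[float, float]] = field(default_factory=dict)
    # region name -> shared (p_B, k_ex)

    def __post_init__(self) -> None:
        if len(self.residue_ids) != self.n_residues:
            raise ValueError("residue_ids length disagrees with n_residues")
        spans = sorted((lo, hi, name) for name, lo, hi in self.regions)
        prev_hi = 0
        for lo, hi, name in spans:
            if lo > hi or lo < 1 or hi > self.n_residues:
                raise ValueError(f"region {name} [{lo},{hi}] out of bounds")
            if lo <= prev_hi:
                raise ValueError(f"region {name} overlaps its predecessor")
            prev_hi = hi
        missing = set(self.residue_ids) - set(self.per_residue_truth)
        if missing:
            raise ValueError(f"residues without truth entries: {sorted(missing)}")

    def region_of(self, residue_id: str) -> str | None:
        num = _numeric(residue_id)
        for name, lo, hi in self.regions:
            if lo <= num <= hi:
                return name
        return None

    def in_region(self, residue_id: str) -> bool:
        return self.region_of(residue_id) is not None

    def region_members(self, name: str) -> list[str]:
        return [r for r in self.residue_ids if self.region_of(r) == name]


@dataclass
class SyntheticDataset:
    """Noisy dispersion + relaxation data simulated from one truth model."""

    dispersion: dict[str, dict[float, DispersionCurve]]
    undetectable: set[str]
    seed: int
    fields: tuple[float, ...]


_PROFILES = {
    "LEN-like": dict(pb_range=(0.02, 0.04), dw_range=(1.0, 3.0), tauc=13.5),
    "SMA-like": dict(pb_range=(0.08, 0.15), dw_range=(1.5, 5.0), tauc=15.0),
    "quenched": dict(pb_range=(0.0, 0.0), dw_range=(0.0, 0.0), tauc=13.5),
}


def make_truth(
    profile_name: str = "LEN-like",
    seed: int = 0,
    overrides: dict | None = None,
) -> GroundTruthProtein:
    """Build a ground-truth protein for one of the named profiles.

    ``overrides`` may replace top-level fields (``detect_limit``,
    ``tauc_true``, ``regions``, ``kex_range``, ``pb_range``, ``dw_range``,
    ``r20_base``) before the per-residue truth is drawn.
    """
    profiles = dict(_PROFILES)
    profiles["custom"] = dict(_PROFILES["LEN-like"])
    if profile_name not in profiles:
        raise ValueError(
            f"unknown profile {profile_name!r}; expected one of {sorted(profiles)}"
        )
    cfg = dict(profiles[profile_name])
    cfg.setdefault("kex_range", (1000.0, 2500.0))
    cfg.setdefault("regions", REGIONS_DEFAULT)
    cfg.setdefault("detect_limit", DETECT_LIMIT_DEFAULT)
    cfg.setdefault("n_residues", 114)
    cfg.setdefault("r20_base", {600.0: 12.0, 800.0: 13.0})
    known = set(cfg) | {"tauc"}
    for key, val in (overrides or {}).items():
        if key == "tauc_true":
            key = "tauc"
        if key not in known:
            raise ValueError(f"override references unknown field {key!r}")
        cfg[key] = val

    regions = [tuple(r) for r in cfg["regions"]]
    rng = np.random.default_rng(seed)
    residue_ids = default_residue_ids(cfg["n_residues"])

    def region_of(rid: str) -> str | None:
        num = _numeric(rid)
        for name, lo, hi in regions:
            if lo <= num <= hi:
                return name
        return None

    # shared (p_B, k_ex) per region: partial unfolding of a contiguous
    # stretch is modelled as a single cooperative process
    pb_lo, pb_hi = cfg["pb_range"]
    kx_lo, kx_hi = cfg["kex_range"]
    region_truth = {
        name: (float(rng.uniform(pb_lo, pb_hi)), float(rng.uniform(kx_lo, kx_hi)))
        for name, _, _ in regions
    }

    dw_lo, dw_hi = cfg["dw_range"]
    r20_base = dict(cfg["r20_base"])
    per_residue: dict[str, ExchangeParams] = {}
    for rid in residue_ids:
        r20 = {
            f: float(base + rng.normal(0.0, 0.5))
            for f, base in r20_base.items()
        }
        region = region_of(rid)
        if region is None or profile_name == "quenched":
            params = ExchangeParams(pb=0.0, kex=1000.0, dw=0.0, r20=r20)
        else:
            pb, kex = region_truth[region]
            dw = float(rng.uniform(dw_lo, dw_hi))
            params = ExchangeParams(pb=pb, kex=kex, dw=dw, r20=r20)
        per_residue[rid] = params

    return GroundTruthProtein(
        n_residues=cfg["n_residues"],
        residue_ids=residue_ids,
        proline_positions=set(PROLINES_DEFAULT),
        regions=regions,
        per_residue_truth=per_residue,
        detect_limit=cfg["detect_limit"],
        tauc_true=cfg["tauc"],
        profile=profile_name,
        region_truth=region_truth,
    )


def simulate_dispersion_dataset(
    truth: GroundTruthProtein,
    fields=FIELDS_DEFAULT,
    nu_grid=NU_CPMG_DEFAULT,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate dual-field R2,eff(nu_cpmg) trajectories for every residue.

    The noise-free curve comes from the two-site closed form; Gaussian
    noise of ``noise_sd`` (s^-1) is added per point.  Prolines yield no
    data.  A residue whose noise-free R_ex at the lowest field exceeds
    ``truth.detect_limit`` is recorded as broadened beyond detection and
    carries no curves.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    fields = tuple(float(f) for f in fields)
    if not fields:
        raise ValueError("need at least one static field")
    nu = np.asarray(nu_grid, dtype=float)
    if np.any(np.diff(nu) <= 0) or nu[0] < 10.0 or nu[-1] > 2000.0:
        raise ValueError("nu_grid must ascend within [10, 2000] Hz")

    rng = np.random.default_rng(seed)
    low_field = min(fields)
    dispersion: dict[str, dict[float, DispersionCurve]] = {}
    undetectable: set[str] = set()
    for rid in truth.residue_ids:
        if rid in truth.proline_positions:
            continue
        params = truth.per_residue_truth[rid]
        if rex_from_params(params, low_field) > truth.detect_limit:
            undetectable.add(rid)
            continue
        per_field: dict[float, DispersionCurve] = {}
        for f in fields:
            clean = r2eff_two_site(params, nu, f)
            noisy = clean + rng.normal(0.0, noise_sd, size=nu.shape) if noise_sd else clean
            per_field[f] = DispersionCurve(
                residue_id=rid,
                field=f,
                nu=nu.copy(),
                r2eff=noisy,
                sigma=np.full_like(nu, max(noise_sd, 1e-6)),
            )
        dispersion[rid] = per_field
    return SyntheticDataset(
        dispersion=dispersion, undetectable=undetectable, seed=seed, fields=fields
    )


def simulate_relaxation_table(
    truth: GroundTruthProtein,
    field: float = 600.0,
    noise_fraction: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-residue R1/R2/NOE table at one field.

    Rates follow the rigid isotropic rotor at ``truth.tauc_true``;
    exchange-region residues have their R2 inflated by the noise-free R_ex
    at this field.  Multiplicative Gaussian noise of ``noise_fraction`` is
    applied to each observable.  Prolines and broadened-beyond-detection
    residues are absent.
    """
    if truth.tauc_true <= 0:
        raise ValueError("tauc_true must be positive")
    if not 300.0 <= field <= 1200.0:
        raise ValueError("field outside [300, 1200] MHz")
    rng = np.random.default_rng(seed)
    r1_0, r2_0, noe_0 = rates_isotropic(truth.tauc_true * 1e-9, field)
    low_field = min(field, 600.0)
    rows = []
    for rid in truth.residue_ids:
        if rid in truth.proline_positions:
            continue
        params = truth.per_residue_truth[rid]
        rex_here = rex_from_params(params, field)
        if rex_from_params(params, low_field) > truth.detect_limit:
            continue  # peak lost to exchange broadening
        r1 = r1_0
        r2 = r2_0 + rex_here
        noe = noe_0
        if noise_fraction:
            r1 *= 1.0 + rng.normal(0.0, noise_fraction)
            r2 *= 1.0 + rng.normal(0.0, noise_fraction)
            noe *= 1.0 + rng.normal(0.0, noise_fraction)
        rows.append(
            {
                "residue_id": rid,
                "r1": r1,
                "r2": r2,
                "noe": noe,
                "has_exchange": params.pb > 0 and params.dw > 0,
            }
        )
    return pd.DataFrame(rows)


def simulate_cd_titration(
    model: DimerModel,
    conc_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CDTitration:
    """Noisy CD titration (ellipticity vs mg/mL) from a dimer model."""
    conc = np.asarray(conc_grid, dtype=float)
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise ValueError("conc_grid must be positive and ascending")
    theta = np.asarray(predict_ellipticity(model, conc), dtype=float)
    if noise_sd:
        rng = np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise_sd, size=theta.shape)
    return CDTitration(conc_mg_ml=conc, theta_obs=theta, mw=model.mw)


def simulate_shift_tables(
    truth: GroundTruthProtein,
    mutated: tuple[str, ...] = ("94",),
    perturbation_ppm: float = 0.3,
    seed: int = 0,
) -> tuple[ShiftTable, ShiftTable]:
    """Reference and mutant shift tables with localised amide perturbations.

    Amide shifts are perturbed around the mutated residues (decaying with
    sequence separation) while CA shifts stay essentially unchanged, the
    signature of a preserved backbone fold.  Residues broadened beyond
    detection in the mutant are left unassigned there.
    """
    rng = np.random.default_rng(seed)
    ref = ShiftTable(protein_name="reference")
    mut = ShiftTable(protein_name="mutant")
    mut_pos = [_numeric(m) for m in mutated]
    for rid in truth.residue_ids:
        ca = float(rng.normal(56.0, 2.5))
        n15 = float(rng.normal(119.0, 3.5))
        h1 = float(rng.normal(8.2, 0.45))
        ref.add(rid, "CA", ca)
        ref.add(rid, "N", n15)
        if rid not in truth.proline_positions:
            ref.add(rid, "H", h1)
        # perturbation decays over ~5 residues from each mutation site
        num = _numeric(rid)
        w = sum(np.exp(-abs(num - m) / 5.0) for m in mut_pos)
        mut.add(rid, "CA", ca + float(rng.normal(0.0, 0.02)))
        if rex_from_params(truth.per_residue_truth[rid], 600.0) > truth.detect_limit:
            mut.unassigned.add(rid)
            continue
        mut.add(rid, "N", n15 + 5.0 * perturbation_ppm * w * float(rng.normal(1.0, 0.3)))
        if rid not in truth.proline_positions:
            mut.add(rid, "H", perturbation_ppm * w * float(rng.normal(1.0, 0.3)) + h1)
    return ref, mut


# ---------------------------------------------------------------------------
# plain-text writers: TSV tables plus a JSON truth sidecar for harnesses

def write_dispersion_tsv(dataset: SyntheticDataset, path: str | Path) -> None:
    rows = [
        {
            "residue_id": rid,
            "field_mhz": f,
            "nu_cpmg_hz": float(nu),
            "r2eff": float(r),
            "sigma": float(s),
        }
        for rid, per_field in dataset.dispersion.items()
        for f, curve in per_field.items()
        for nu, r, s in zip(curve.nu, curve.r2eff, curve.sigma)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dispersion_tsv(path: str | Path) -> dict[str, dict[float, DispersionCurve]]:
    df = pd.read_csv(path, sep="\t", dtype={"residue_id": str})
    out: dict[str, dict[float, DispersionCurve]] = {}
    for (rid, f), grp in df.groupby(["residue_id", "field_mhz"], sort=False):
        grp = grp.sort_values("nu_cpmg_hz")
        out.setdefault(str(rid), {})[float(f)] = DispersionCurve(
            residue_id=str(rid),
            field=float(f),
            nu=grp["nu_cpmg_hz"].to_numpy(),
            r2eff=grp["r2eff"].to_numpy(),
            sigma=grp["sigma"].to_numpy(),
        )
    return out


def truth_to_json(truth: GroundTruthProtein, path: str | Path) -> None:
    payload = {
        "profile": truth.profile,
        "n_residues": truth.n_residues,
        "residue_ids": truth.residue_ids,
        "prolines": sorted(truth.proline_positions),
        "regions": [list(r) for r in truth.regions],
        "detect_limit": truth.detect_limit,
        "tauc_true_ns": truth.tauc_true,
        "region_truth": {k: list(v) for k, v in truth.region_truth.items()},
        "per_residue": {
            rid: {
                "pb": p.pb,
                "kex": p.kex,
                "dw_ppm": p.dw,
                "r20": {str(k): v for k, v in p.r20.items()}
                if isinstance(p.r20, dict)
                else {"all": p.r20},
            }
            for rid, p in truth.per_residue_truth.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))
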