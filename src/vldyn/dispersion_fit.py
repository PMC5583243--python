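"""Fitting CPMG relaxation dispersion to the two-site exchange model.

Per residue, the dual-field trajectories are fit jointly with shared
(p_B, k_ex, dw) and one intrinsic rate per field.  Region-global fits tie
(p_B, k_ex) across all residues of a contiguous dynamic region — the
model of cooperative partial unfolding of a protein stretch — while each
residue keeps its own shift difference and intrinsic rates.

All fits are weighted least squares over both fields simultaneously, with
a deterministic multi-start over a coarse (k_ex, p_B) grid to escape the
many local minima of the dispersion surface; ties in chi-square resolve to
the smaller minor-state population.  Parameter uncertainties come from
seeded parametric Monte-Carlo resampling (refitting noise-perturbed copies
of the best-fit curves), which stays honest near parameter bounds where
covariance-matrix estimates do not.

Residues are classified as dynamic when their fitted R_ex at the lower
field exceeds a cutoff (3 s^-1 at 600 MHz), or when their peak is
exchange-broadened beyond detection; contiguous dynamic segments are then
extracted with an explicit gap rule replacing by-eye inspection of the
R_ex profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import optimize

from .exchange import DispersionCurve, ExchangeParams, dw_rad_per_s, rex_from_params
from .exchange import _r2eff_carver_richards
from .residues import order_residues, sort_key

__all__ = [
    "ResidueFit",
    "RegionFit",
    "DynamicsMap",
    "fit_residue",
    "fit_region",
    "classify_and_segment",
    "FitBounds",
]

KEX_STARTS = (200.0, 500.0, 1000.0, 2000.0, 4000.0)
PB_STARTS = (0.01, 0.05, 0.15)
REX_CUTOFF_DEFAULT = 3.0  # s^-1 at the lower field
CLASSIFY_FIELD_DEFAULT = 600.0


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the exchange parameters.

    Defaults cover minor-state populations up to 30% and exchange rates of
    50-10^4 s^-1, with the shift difference kept off zero so the model
    stays identifiable.
    """

    pb: tuple[float, float] = (0.001, 0.3)
    kex: tuple[float, float] = (50.0, 1.0e4)
    dw: tuple[float, float] = (0.1, 12.0)
    r20: tuple[float, float] = (0.1, 200.0)


@dataclass
class ResidueFit:
    residue_id: str
    params: ExchangeParams  # r20 is a per-field dict
    chi2: float
    rex: dict[float, float]  # field MHz -> R_ex s^-1
    uncertainties: dict[str, float] = dfield(default_factory=dict)
    no_significant_dispersion: bool = False


@dataclass
class RegionFit:
    name: str
    pb: float
    kex: float
    dw: dict[str, float]  # residue -> ppm
    r20: dict[str, dict[float, float]]  # residue -> field -> s^-1
    chi2: float
    members: list[str]
    excluded: list[str]
    uncertainties: dict[str, float] = dfield(default_factory=dict)

    def params_for(self, residue_id: str) -> ExchangeParams:
        return ExchangeParams(
            pb=self.pb, kex=self.kex, dw=self.dw[residue_id], r20=self.r20[residue_id]
        )


@dataclass
class DynamicsMap:
    status: dict[str, str]  # residue -> dynamic|quiescent|undetectable|unassigned|proline
    segments: list[tuple[str, str]]  # (first_id, last_id) per dynamic region
    segment_members: list[list[str]] = dfield(default_factory=list)


def _as_field_dict(curves) -> dict[float, DispersionCurve]:
    if isinstance(curves, dict):
        return {float(f): c for f, c in curves.items()}
    return {float(c.field): c for c in curves}


def _stack(curves: dict[float, DispersionCurve]):
    fields = sorted(curves)
    nu = [curves[f].nu for f in fields]
    y = [curves[f].r2eff for f in fields]
    s = [curves[f].sigma for f in fields]
    return fields, nu, y, s


def _model_residuals(theta, fields, nu, y, s):
    """theta = (pb, kex, dw, r20_f0, r20_f1, ...)."""
    pb, kex, dw = theta[0], theta[1], theta[2]
    out = []
    for i, f in enumerate(fields):
        dom = dw_rad_per_s(dw, f)
        pred = _r2eff_carver_richards(pb, kex, dom, theta[3 + i], nu[i])
        out.append((pred - y[i]) / s[i])
    return np.concatenate(out)


def _multistart_ls(resid_fn, build_theta, bounds_lo, bounds_hi, starts):
    """Run least-squares from every start; lowest chi2 wins, ties -> smaller pb."""
    best = None
    for start in starts:
        theta0 = np.clip(build_theta(start), bounds_lo, bounds_hi)
        try:
            res = optimize.least_squares(
                resid_fn, theta0, bounds=(bounds_lo, bounds_hi), method="trf",
                xtol=1e-10, ftol=1e-10,
            )
        except Exception:
            continue
        if best is None:
            best = res
            continue
        if res.cost < best.cost * (1.0 - 1e-9):
            best = res
        elif abs(res.cost - best.cost) <= 1e-9 * max(best.cost, 1e-30):
            if res.x[0] < best.x[0]:  # tie: smaller minor population
                best = res
    if best is None:
        raise RuntimeError("dispersion fit failed to converge from every start")
    return best


def fit_residue(
    curves,
    bounds: FitBounds = FitBounds(),
    n_mc: int = 150,
    seed: int = 0,
) -> ResidueFit:
    """Fit one residue's dual-field dispersion to two-site exchange.

    Parameters
    ----------
    curves : mapping {field MHz -> DispersionCurve} or list of curves;
        both fields are fit simultaneously with shared (p_B, k_ex, dw)
        and a per-field intrinsic rate.
    n_mc : Monte-Carlo draws for parameter uncertainties (0 to skip).
    """
    curves = _as_field_dict(curves)
    if len(curves) < 2:
        raise ValueError("need curves at both static fields")
    for f, c in curves.items():
        if len(c.nu) < 6:
            raise ValueError(f"need >= 6 points per field, got {len(c.nu)} at {f} MHz")
    fields, nu, y, s = _stack(curves)
    rid = curves[fields[0]].residue_id

    n_par = 3 + len(fields)
    n_pts = sum(len(v) for v in y)
    if n_pts <= n_par:
        raise ValueError("fewer data points than parameters")

    lo = np.array([bounds.pb[0], bounds.kex[0], bounds.dw[0]] + [bounds.r20[0]] * len(fields))
    hi = np.array([bounds.pb[1], bounds.kex[1], bounds.dw[1]] + [bounds.r20[1]] * len(fields))
    r20_starts = [float(np.min(yy)) for yy in y]

    def build(start):
        kex0, pb0 = start
        return np.array([pb0, kex0, 2.0] + r20_starts)

    starts = [(k, p) for k in KEX_STARTS for p in PB_STARTS]
    best = _multistart_ls(
        lambda th: _model_residuals(th, fields, nu, y, s), build, lo, hi, starts
    )
    theta = best.x
    chi2 = float(2.0 * best.cost)

    params = ExchangeParams(
        pb=float(theta[0]),
        kex=float(theta[1]),
        dw=float(theta[2]),
        r20={f: float(theta[3 + i]) for i, f in enumerate(fields)},
    )
    rex = {f: rex_from_params(params, f) for f in fields}

    # amplitude significance: drop in R2,eff across the profile vs noise
    amp = max(float(np.max(yy) - np.min(yy)) for yy in y)
    sig = float(np.mean(np.concatenate(s)))
    flat = amp < 2.0 * sig

    unc: dict[str, float] = {}
    if n_mc > 0:
        rng = np.random.default_rng(seed)
        pred = [
            _r2eff_carver_richards(
                theta[0], theta[1], dw_rad_per_s(theta[2], f), theta[3 + i], nu[i]
            )
            for i, f in enumerate(fields)
        ]
        draws = []
        for _ in range(n_mc):
            y_mc = [p + rng.normal(0.0, s[i]) for i, p in enumerate(pred)]
            try:
                res = optimize.least_squares(
                    lambda th: _model_residuals(th, fields, nu, y_mc, s),
                    np.clip(theta, lo, hi),
                    bounds=(lo, hi),
                    method="trf",
                )
                draws.append(res.x)
            except Exception:
                continue
        if draws:
            arr = np.array(draws)
            unc = {
                "pb": float(arr[:, 0].std(ddof=1)),
                "kex": float(arr[:, 1].std(ddof=1)),
                "dw": float(arr[:, 2].std(ddof=1)),
            }
            for i, f in enumerate(fields):
                unc[f"r20_{f:g}"] = float(arr[:, 3 + i].std(ddof=1))

    return ResidueFit(
        residue_id=rid,
        params=params,
        chi2=chi2,
        rex=rex,
        uncertainties=unc,
        no_significant_dispersion=flat,
    )


def fit_region(
    curves_by_residue: dict[str, dict[float, DispersionCurve]],
    members: list[str],
    name: str = "region",
    undetectable: set[str] | None = None,
    bounds: FitBounds = FitBounds(),
    n_mc: int = 150,
    seed: int = 0,
) -> RegionFit:
    """Region-global fit: one (p_B, k_ex) shared by all member residues.

    Residues listed in ``members`` but lacking usable dual-field curves
    (or flagged undetectable) are excluded and reported as such.
    """
    undetectable = undetectable or set()
    usable, excluded = [], []
    for rid in members:
        rid = str(rid)
        cs = curves_by_residue.get(rid)
        if rid in undetectable or cs is None or len(cs) < 2:
            excluded.append(rid)
        else:
            usable.append(rid)
    if not usable:
        raise ValueError(f"region {name}: every member is undetectable or missing")

    stacks = {rid: _stack(_as_field_dict(curves_by_residue[rid])) for rid in usable}
    fields = stacks[usable[0]][0]
    nf = len(fields)
    m = len(usable)

    # theta = [pb, kex, dw_1..dw_m, r20_{1,f1}, r20_{1,f2}, ..., r20_{m,fn}]
    lo = np.concatenate(
        [[bounds.pb[0], bounds.kex[0]], [bounds.dw[0]] * m, [bounds.r20[0]] * (m * nf)]
    )
    hi = np.concatenate(
        [[bounds.pb[1], bounds.kex[1]], [bounds.dw[1]] * m, [bounds.r20[1]] * (m * nf)]
    )

    def resid(theta):
        pb, kex = theta[0], theta[1]
        out = []
        for j, rid in enumerate(usable):
            _, nu, y, s = stacks[rid]
            dw = theta[2 + j]
            for i, f in enumerate(fields):
                dom = dw_rad_per_s(dw, f)
                r20 = theta[2 + m + j * nf + i]
                out.append((_r2eff_carver_richards(pb, kex, dom, r20, nu[i]) - y[i]) / s[i])
        return np.concatenate(out)

    r20_starts = np.concatenate(
        [[float(np.min(yy)) for yy in stacks[rid][2]] for rid in usable]
    )

    def build(start):
        kex0, pb0 = start
        return np.concatenate([[pb0, kex0], [2.0] * m, r20_starts])

    starts = [(k, p) for k in KEX_STARTS for p in PB_STARTS]
    best = _multistart_ls(resid, build, lo, hi, starts)
    theta = best.x

    dw = {rid: float(theta[2 + j]) for j, rid in enumerate(usable)}
    r20 = {
        rid: {f: float(theta[2 + m + j * nf + i]) for i, f in enumerate(fields)}
        for j, rid in enumerate(usable)
    }

    unc: dict[str, float] = {}
    if n_mc > 0:
        rng = np.random.default_rng(seed)
        preds = {}
        for j, rid in enumerate(usable):
            _, nu, y, s = stacks[rid]
            preds[rid] = [
                _r2eff_carver_richards(
                    theta[0], theta[1], dw_rad_per_s(theta[2 + j], f),
                    theta[2 + m + j * nf + i], nu[i],
                )
                for i, f in enumerate(fields)
            ]
        draws = []
        for _ in range(n_mc):
            perturbed = {
                rid: [p + rng.normal(0.0, stacks[rid][3][i]) for i, p in enumerate(preds[rid])]
                for rid in usable
            }

            def resid_mc(th):
                pb, kex = th[0], th[1]
                out = []
                for j, rid in enumerate(usable):
                    _, nu, _, s = stacks[rid]
                    for i, f in enumerate(fields):
                        dom = dw_rad_per_s(th[2 + j], f)
                        r = th[2 + m + j * nf + i]
                        out.append(
                            (_r2eff_carver_richards(pb, kex, dom, r, nu[i]) - perturbed[rid][i]) / s[i]
                        )
                return np.concatenate(out)

            try:
                res = optimize.least_squares(
                    resid_mc, np.clip(theta, lo, hi), bounds=(lo, hi), method="trf"
                )
                draws.append(res.x[:2])
            except Exception:
                continue
        if draws:
            arr = np.array(draws)
            unc = {
                "pb": float(arr[:, 0].std(ddof=1)),
                "kex": float(arr[:, 1].std(ddof=1)),
            }

    return RegionFit(
        name=name,
        pb=float(theta[0]),
        kex=float(theta[1]),
        dw=dw,
        r20=r20,
        chi2=float(2.0 * best.cost),
        members=usable,
        excluded=excluded,
        uncertainties=unc,
    )


def classify_and_segment(
    fits: dict[str, ResidueFit] | list[ResidueFit],
    undetectable: set[str] | None = None,
    cutoff: float = REX_CUTOFF_DEFAULT,
    field: float = CLASSIFY_FIELD_DEFAULT,
    residue_order: list[str] | None = None,
    prolines: set[str] | None = None,
    max_gap: int = 2,
    min_length: int = 3,
) -> DynamicsMap:
    """Classify residues and extract contiguous dynamic segments.

    A residue is *dynamic* when its fitted R_ex at ``field`` exceeds
    ``cutoff`` (3 s^-1 at 600 MHz) or when it is broadened beyond
    detection.  Segments are maximal runs of dynamic residues tolerating
    gaps of up to ``max_gap`` intervening non-dynamic (quiescent,
    unassigned or proline) residues, and must contain at least
    ``min_length`` dynamic residues.
    """
    undetectable = {str(r) for r in (undetectable or set())}
    prolines = {str(r) for r in (prolines or set())}
    if not isinstance(fits, dict):
        fits = {f.residue_id: f for f in fits}
    fits = {str(k): v for k, v in fits.items()}
    overlap = set(fits) & undetectable
    if overlap:
        raise ValueError(f"residues both fit and undetectable: {sorted(overlap)}")

    if residue_order is None:
        residue_order = order_residues(set(fits) | undetectable | prolines)
    else:
        residue_order = [str(r) for r in residue_order]

    status: dict[str, str] = {}
    for rid in residue_order:
        if rid in prolines:
            status[rid] = "proline"
        elif rid in undetectable:
            status[rid] = "undetectable"
        elif rid in fits:
            status[rid] = (
                "dynamic" if fits[rid].rex.get(field, 0.0) > cutoff else "quiescent"
            )
        else:
            status[rid] = "unassigned"

    is_dyn = [status[r] in ("dynamic", "undetectable") for r in residue_order]
    hits = [i for i, d in enumerate(is_dyn) if d]
    segments: list[tuple[str, str]] = []
    members: list[list[str]] = []
    if hits:
        group = [hits[0]]
        groups = []
        for i in hits[1:]:
            if i - group[-1] <= max_gap + 1:
                group.append(i)
            else:
                groups.append(group)
                group = [i]
        groups.append(group)
        for g in groups:
            if len(g) >= min_length:
                segments.append((residue_order[g[0]], residue_order[g[-1]]))
                members.append([residue_order[i] for i in g])

    return DynamicsMap(status=status, segments=segments, segment_members=members)
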