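"""Per-residue and region-global dispersion fitting, classification, segmentation."""

import numpy as np
import pytest

from vldyn.exchange import DispersionCurve, ExchangeParams
from vldyn.dispersion_fit import (
    DynamicsMap,
    ResidueFit,
    classify_and_segment,
    fit_region,
    fit_residue,
)


class TestResidueFit:
    def test_flat_curves_report_negligible_rex(self, nu_grid):
        curves = {
            f: DispersionCurve("7", f, nu_grid, np.full(len(nu_grid), 12.0),
                               np.full(len(nu_grid), 0.3))
            for f in (600.0, 800.0)
        }
        fit = fit_residue(curves, n_mc=0)
        assert fit.rex[600.0] <= 0.01
        assert fit.no_significant_dispersion

    def test_noise_free_round_trip(self, moderate_truth, curve_factory):
        curves = curve_factory(moderate_truth)
        fit = fit_residue(curves, n_mc=0)
        assert fit.params.pb == pytest.approx(moderate_truth.pb, rel=1e-3)
        assert fit.params.kex == pytest.approx(moderate_truth.kex, rel=1e-3)
        assert fit.params.dw == pytest.approx(moderate_truth.dw, rel=1e-3)
        for f in (600.0, 800.0):
            assert fit.params.r20_at(f) == pytest.approx(
                moderate_truth.r20_at(f), rel=1e-3
            )

    def test_cross_backend_consistency(self, moderate_truth, nu_grid):
        """Curves from the Bloch-McConnell train, fit with the closed form.

        A long commensurate train keeps the startup transient negligible,
        so the closed-form fit must recover the generating parameters.
        """
        from vldyn.exchange import r2eff_two_site

        t_relax = 0.6
        nu = np.round(nu_grid * 2 * t_relax) / (2 * t_relax)
        curves = {}
        for f in (600.0, 800.0):
            clean = r2eff_two_site(moderate_truth, nu, f, backend="numerical",
                                   t_relax=t_relax)
            curves[f] = DispersionCurve("9", f, nu, clean, np.full(len(nu), 0.3))
        fit = fit_residue(curves, n_mc=0)
        assert fit.params.pb == pytest.approx(moderate_truth.pb, rel=0.05)
        assert fit.params.kex == pytest.approx(moderate_truth.kex, rel=0.05)

    def test_noisy_recovery_is_unbiased_in_median(self, moderate_truth, curve_factory):
        rng = np.random.default_rng(12)
        pbs, kexs = [], []
        for _ in range(20):
            fit = fit_residue(
                curve_factory(moderate_truth, noise_sd=0.3, rng=rng), n_mc=0
            )
            pbs.append(fit.params.pb)
            kexs.append(fit.params.kex)
        assert np.median(pbs) == pytest.approx(moderate_truth.pb, rel=0.20)
        assert np.median(kexs) == pytest.approx(moderate_truth.kex, rel=0.15)

    def test_uncertainties_are_seeded_and_reproducible(self, moderate_truth, curve_factory):
        curves = curve_factory(moderate_truth, noise_sd=0.3,
                               rng=np.random.default_rng(5))
        a = fit_residue(curves, n_mc=40, seed=3)
        b = fit_residue(curves, n_mc=40, seed=3)
        assert a.uncertainties == b.uncertainties
        assert a.uncertainties["pb"] > 0

    def test_single_field_rejected(self, moderate_truth, curve_factory):
        curves = curve_factory(moderate_truth)
        with pytest.raises(ValueError, match="both"):
            fit_residue({600.0: curves[600.0]}, n_mc=0)

    def test_too_few_points_rejected(self, moderate_truth, curve_factory):
        curves = curve_factory(moderate_truth, nu=[33.3, 100.0, 300.0, 600.0, 1000.0])
        with pytest.raises(ValueError, match=">= 6 points"):
            fit_residue(curves, n_mc=0)


class TestRegionFit:
    def shared_truth_curves(self, rng, pb=0.04, kex=1500.0, dws=(1.2, 1.8, 2.4, 3.0),
                            noise=0.3):
        from tests.conftest import make_curves

        out = {}
        for j, dw in enumerate(dws):
            p = ExchangeParams(pb=pb, kex=kex, dw=dw, r20={600.0: 12.0, 800.0: 13.0})
            rid = str(40 + j)
            out[rid] = make_curves(p, noise_sd=noise, rng=rng, rid=rid)
        return out

    def test_shared_truth_recovery_and_tighter_pb(self):
        rng = np.random.default_rng(21)
        curves = self.shared_truth_curves(rng)
        region = fit_region(curves, list(curves), name="region2", n_mc=40, seed=2)
        assert region.pb == pytest.approx(0.04, abs=3 * max(region.uncertainties["pb"], 1e-3))
        assert region.kex == pytest.approx(1500.0, rel=0.15)
        single = fit_residue(curves["40"], n_mc=40, seed=2)
        assert region.uncertainties["pb"] < single.uncertainties["pb"]

    def test_single_member_region_matches_residue_fit(self, moderate_truth, curve_factory):
        curves = {"50": curve_factory(moderate_truth, rid="50")}
        region = fit_region(curves, ["50"], n_mc=0)
        single = fit_residue(curves["50"], n_mc=0)
        assert region.pb == pytest.approx(single.params.pb, rel=1e-4)
        assert region.kex == pytest.approx(single.params.kex, rel=1e-4)
        assert region.chi2 == pytest.approx(single.chi2, abs=1e-9)

    def test_undetectable_member_excluded_not_fatal(self):
        rng = np.random.default_rng(22)
        curves = self.shared_truth_curves(rng)
        region = fit_region(curves, list(curves) + ["99"], undetectable={"99"},
                            n_mc=0)
        assert "99" in region.excluded
        assert set(region.members) == set(curves)

    def test_all_members_undetectable_errors(self):
        with pytest.raises(ValueError, match="undetectable or missing"):
            fit_region({}, ["1", "2"], undetectable={"1", "2"}, n_mc=0)

    def test_region_chi2_not_catastrophically_worse(self):
        """On shared-truth data the global fit costs at most ~2x per dof."""
        rng = np.random.default_rng(23)
        curves = self.shared_truth_curves(rng)
        region = fit_region(curves, list(curves), n_mc=0)
        pooled_chi2 = sum(fit_residue(c, n_mc=0).chi2 for c in curves.values())
        n_pts = 4 * 2 * 12
        region_dof = n_pts - (2 + 4 + 8)
        pooled_dof = n_pts - 4 * 5
        assert (region.chi2 / region_dof) <= 2.0 * max(pooled_chi2 / pooled_dof, 0.5)


class TestClassifyAndSegment:
    def fits_with_rex(self, rex_by_id):
        out = {}
        for rid, rex in rex_by_id.items():
            p = ExchangeParams(pb=0.03, kex=1500.0, dw=1.0, r20=12.0)
            out[rid] = ResidueFit(residue_id=rid, params=p, chi2=1.0,
                                  rex={600.0: rex, 800.0: rex * 1.5})
        return out

    def test_cutoff_boundary(self):
        fits = self.fits_with_rex({"10": 3.2, "11": 2.9})
        dm = classify_and_segment(fits, set())
        assert dm.status["10"] == "dynamic"
        assert dm.status["11"] == "quiescent"

    def test_undetectable_counts_as_dynamic(self):
        fits = self.fits_with_rex({"1": 5.0, "3": 5.0})
        dm = classify_and_segment(fits, {"2"}, residue_order=["1", "2", "3"])
        assert dm.status["2"] == "undetectable"
        assert dm.segments == [("1", "3")]

    def test_gap_rule_and_min_length(self):
        # two dynamic runs separated by 3 quiescent residues stay separate;
        # a lone pair below min length is dropped
        rex = {str(i): 8.0 for i in [1, 2, 3, 7, 8, 9, 20, 21]}
        rex.update({str(i): 0.5 for i in [4, 5, 6, 10, 11, 12, 13, 19, 22]})
        fits = self.fits_with_rex(rex)
        order = [str(i) for i in range(1, 23)]
        dm = classify_and_segment(fits, set(), residue_order=order)
        # gap of 3 splits the run; the lone pair 20-21 is below min length
        assert dm.segments == [("1", "3"), ("7", "9")]
        rex["5"] = 8.0  # shrink both gaps to <= 2 -> one merged segment
        dm2 = classify_and_segment(self.fits_with_rex(rex), set(), residue_order=order)
        assert dm2.segments == [("1", "9")]

    def test_order_invariance_and_idempotence(self):
        rex = {str(i): (8.0 if i < 5 else 0.1) for i in range(1, 10)}
        fits = self.fits_with_rex(rex)
        order = [str(i) for i in range(1, 10)]
        dm1 = classify_and_segment(fits, set(), residue_order=order)
        shuffled = dict(reversed(list(fits.items())))
        dm2 = classify_and_segment(shuffled, set(), residue_order=order)
        assert dm1.status == dm2.status
        assert dm1.segments == dm2.segments

    def test_overlapping_fit_and_undetectable_rejected(self):
        fits = self.fits_with_rex({"5": 4.0})
        with pytest.raises(ValueError, match="both fit and undetectable"):
            classify_and_segment(fits, {"5"})
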