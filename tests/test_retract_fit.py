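import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from forcemap import (
    FitError,
    RetractTruth,
    detect_regions,
    fit_fjc_region,
    fjc_extension,
    fjc_force,
    process_retract,
    pull_from_rupture,
    rupture_statistics,
    segment_curve,
    simulate_retract_curve,
)
from forcemap.constants import thermal_energy

from conftest import make_curve


# ---------------------------------------------------------------------------
# FJC extension law
# ---------------------------------------------------------------------------

class TestFJCExtension:
    def test_saturates_at_contour_length(self):
        x = fjc_extension(1e6, 312.0, 0.27)
        assert x > 312.0 * (1 - 1e-6)
        assert x < 312.0

    def test_small_force_langevin_series(self):
        kbt = thermal_energy(298.15)
        u = 1e-5
        F = u * kbt / 0.27
        x = fjc_extension(F, 312.0, 0.27)
        assert abs(x / 312.0 - u / 3.0) < 1e-8 * (u / 3.0) + 1e-15

    def test_reference_value(self):
        # Lc=312 nm, lk=0.27 nm, F=100 pN -> u ~ 6.56, x ~ 264.5 nm
        x = fjc_extension(0.1, 312.0, 0.27)
        assert x == pytest.approx(264.5, abs=0.2)

    def test_nonpositive_force_rejected(self):
        with pytest.raises(FitError):
            fjc_extension(0.0, 312.0, 0.27)
        with pytest.raises(FitError):
            fjc_extension(-0.1, 312.0, 0.27)

    @settings(derandomize=True, max_examples=50)
    @given(Lc=st.floats(50, 1000), lk=st.floats(0.05, 2.0),
           F=st.floats(1e-4, 10.0))
    def test_monotone_and_bounded(self, Lc, lk, F):
        x1 = fjc_extension(F, Lc, lk)
        x2 = fjc_extension(F * 1.5, Lc, lk)
        assert 0 < x1 < x2 < Lc

    def test_force_extension_inverse_consistency(self):
        for x in (50.0, 150.0, 290.0):
            F = fjc_force(x, 312.0, 0.27)
            assert fjc_extension(F, 312.0, 0.27) == pytest.approx(x, abs=1e-6)


# ---------------------------------------------------------------------------
# region detection
# ---------------------------------------------------------------------------

def sawtooth_curve(pull_bounds, slope=-0.004, n=900, z_max=900.0, noise=0.0,
                   seed=0):
    """Piecewise-affine sawtooth: linear adhesive pulls between given z
    bounds, zero force elsewhere."""
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, z_max, n)
    F = np.zeros(n)
    for za, zb in pull_bounds:
        m = (z >= za) & (z <= zb)
        F[m] = slope * (z[m] - za) - 0.02
    if noise > 0:
        F = F + rng.normal(0, noise, n)
    return make_curve(z, F, direction="retract")


class TestDetectRegions:
    def test_three_affine_pulls_found(self):
        bounds = [(150, 300), (400, 520), (600, 800)]
        c = sawtooth_curve(bounds)
        seg = segment_curve(c, r=1, k_max=20, eps=0.0)
        # noise-free construction: pass the noise tolerance explicitly since
        # the last-quarter noise window overlaps the deepest pull here
        regions, dropped = detect_regions(c, seg, Zc=0.0, merge_jump_tol=0.005)
        assert len(regions) == 3
        for (a, b), (za, zb) in zip(regions, bounds):
            assert abs(c.z[a] - za) < 5.0
            assert abs(c.z[b - 1] - zb) < 5.0

    def test_pull_inside_skip_zone_dropped(self):
        c = sawtooth_curve([(20, 95)])
        seg = segment_curve(c, r=1, k_max=20, eps=0.0)
        regions, _ = detect_regions(c, seg, Zc=0.0)
        assert regions == []

    def test_positive_force_sample_drops_region(self):
        # a decreasing ramp that starts above zero force fails the sign rule
        z = np.linspace(0.0, 900.0, 900)
        F = np.zeros(900)
        m = (z >= 300) & (z <= 450)
        F[m] = 0.05 - 0.004 * (z[m] - 300)  # decreasing but positive at first
        c = make_curve(z, F, direction="retract")
        seg = segment_curve(c, r=1, k_max=20, eps=0.0)
        regions, dropped = detect_regions(c, seg, Zc=0.0)
        assert regions == []
        assert dropped >= 1

    def test_quadratic_interval_split_at_vertex(self):
        # one smooth parabola: only its decreasing side is a candidate region
        z = np.linspace(0.0, 900.0, 900)
        F = np.zeros(900)
        m = (z >= 300) & (z <= 500)
        F[m] = -0.3 + 2e-5 * (z[m] - 400) ** 2  # vertex at z=400
        c = make_curve(z, F, direction="retract")
        seg = segment_curve(c, r=2, k_max=8, eps=0.0)
        regions, _ = detect_regions(c, seg, Zc=0.0)
        assert len(regions) >= 1
        a, b = regions[0]
        assert c.z[b - 1] <= 405.0  # stops at the vertex


# ---------------------------------------------------------------------------
# FJC region fit
# ---------------------------------------------------------------------------

def fjc_region_data(Lc=312.0, lk=0.27, z_lo=120.0, z_hi=300.0, dz=0.8,
                    sigma=0.0, seed=0, Zc=0.0):
    rng = np.random.default_rng(seed)
    z = np.arange(z_lo, z_hi, dz)
    F = -np.array([fjc_force(x - Zc, Lc, lk) for x in z])
    if sigma > 0:
        F = F + rng.normal(0, sigma, z.size)
    return z, F


class TestFitFJCRegion:
    def test_noise_free_recovery(self):
        z, F = fjc_region_data()
        fit = fit_fjc_region(z, F, 0.0)
        assert abs(fit.Lc - 312.0) / 312.0 < 0.005
        assert abs(fit.lk - 0.27) / 0.27 < 0.005

    def test_monomer_count_arithmetic(self):
        z, F = fjc_region_data(Lc=100.0, lk=0.5, z_lo=40.0, z_hi=95.0)
        fit = fit_fjc_region(z, F, 0.0)
        assert fit.N == pytest.approx(fit.Lc / fit.lk)
        assert fit.N == pytest.approx(200.0, rel=0.02)

    def test_residual_not_worse_than_truth(self):
        z, F = fjc_region_data(sigma=0.01, seed=3)
        keep = F < 0
        z, F = z[keep], F[keep]
        fit = fit_fjc_region(z, F, 0.0)
        from forcemap.retract_fit import langevin_factor
        g = langevin_factor(np.abs(F) * 0.27 / thermal_energy(298.15))
        sse_truth = float(np.sum((z - 312.0 * g) ** 2))
        assert fit.sse <= sse_truth + 1e-9

    def test_rigid_translation_invariance(self):
        z, F = fjc_region_data(sigma=0.01, seed=6)
        keep = F < 0
        z, F = z[keep], F[keep]
        f1 = fit_fjc_region(z, F, 0.0)
        f2 = fit_fjc_region(z + 500.0, F, 500.0)
        assert f1.Lc == pytest.approx(f2.Lc, rel=1e-9)
        assert f1.lk == pytest.approx(f2.lk, rel=1e-9)

    def test_positive_force_rejected(self):
        z = np.arange(100.0, 200.0, 1.0)
        F = np.full(z.size, 0.01)
        with pytest.raises(FitError):
            fit_fjc_region(z, F, 0.0)


# ---------------------------------------------------------------------------
# end-to-end retraction pipeline
# ---------------------------------------------------------------------------

def three_pull_truth(noise_sd=0.0):
    pulls = [pull_from_rupture(150.0, 0.15, 0.27, 110.0),
             pull_from_rupture(215.0, 0.20, 0.27, 160.0),
             pull_from_rupture(300.0, 0.30, 0.27, 225.0)]
    return RetractTruth(pulls=pulls, noise_sd=noise_sd)


class TestProcessRetract:
    def test_three_pulls_recovered(self):
        truth = three_pull_truth()
        curve, _ = simulate_retract_curve(truth, seed=5)
        res = process_retract(curve, Zc=0.0)
        assert res.status == "ok"
        assert len(res.regions) == 3
        assert res.n_ruptures == 4
        for fit, (Lc, lk, _f, _a) in zip(res.regions, truth.pulls):
            assert abs(fit.Lc - Lc) / Lc < 0.02
            assert abs(fit.lk - lk) / lk < 0.05

    def test_rupture_statistics_spacings(self):
        # ruptures planted at 150/215/300 nm -> spacings 65 and 85 nm
        truth = three_pull_truth()
        curve, _ = simulate_retract_curve(truth, seed=5)
        res = process_retract(curve, Zc=0.0)
        deltaL, n_rupt, last_F, last_d = rupture_statistics(res)
        assert n_rupt == 4
        assert deltaL == pytest.approx([65.0, 85.0], abs=1.0)
        assert last_F == pytest.approx(0.30, abs=0.02)
        assert last_d == pytest.approx(300.0, abs=1.0)

    def test_flat_noise_gives_no_regions(self):
        truth = RetractTruth(pulls=[], noise_sd=0.01)
        curve, _ = simulate_retract_curve(truth, seed=8)
        res = process_retract(curve, Zc=0.0)
        assert res.status == "no_regions"
        assert res.regions == []
        assert res.n_ruptures == 0
        assert res.last_adhesion_force == 0.0

    def test_single_pull_degenerate_statistics(self):
        truth = RetractTruth(pulls=[pull_from_rupture(250.0, 0.2, 0.27, 140.0)],
                             noise_sd=0.0)
        curve, _ = simulate_retract_curve(truth, seed=9)
        res = process_retract(curve, Zc=0.0)
        assert len(res.regions) == 1
        assert res.deltaL == []
        assert res.last_adhesion_force == pytest.approx(0.2, abs=0.02)

    def test_auto_contact_point_close_to_truth(self):
        truth = three_pull_truth(noise_sd=0.005)
        curve, _ = simulate_retract_curve(truth, seed=10)
        res = process_retract(curve)  # Zc estimated from the curve
        assert abs(res.Zc - 0.0) < 5.0
        assert len(res.regions) == 3

    def test_sign_violation_reports_excluded(self):
        # decreasing region sits above zero force: dropped by the sign test,
        # and with nothing else to fit the curve is excluded
        z = np.linspace(0.0, 900.0, 900)
        F = np.zeros(900)
        m = (z >= 300) & (z <= 500)
        F[m] = 0.4 - 0.0015 * (z[m] - 300)
        curve = make_curve(z, F, direction="retract")
        res = process_retract(curve, Zc=0.0, eps=0.0)
        assert res.status == "excluded"
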