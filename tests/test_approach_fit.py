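import math

import numpy as np
import pytest

from forcemap import (
    ApproachTruth,
    FitError,
    compute_indentation,
    debye_length_theoretical,
    fit_contact,
    fit_electrostatic,
    hertz_prefactor,
    process_approach,
    simulate_approach_curve,
)
from forcemap.constants import (
    FARADAY,
    GAS_CONSTANT,
    VACUUM_PERMITTIVITY,
)

from conftest import make_curve


# ---------------------------------------------------------------------------
# Debye length
# ---------------------------------------------------------------------------

class TestDebyeLength:
    def test_one_millimolar_room_temperature(self):
        # the standard textbook value for a 1 mM 1:1 electrolyte
        lam = debye_length_theoretical(1e-3)
        assert abs(lam - 9.8) / 9.8 < 0.05

    def test_square_root_concentration_scaling(self):
        lam1 = debye_length_theoretical(1e-3)
        lam2 = debye_length_theoretical(1e-1)
        assert abs(lam1 / lam2 - 10.0) < 1e-12

    def test_matches_independent_evaluation(self):
        # second, inline evaluation of the closed form at 0.1 M
        c, T, eps_r = 0.1, 298.15, 78.5
        ref = math.sqrt(VACUUM_PERMITTIVITY * eps_r * GAS_CONSTANT * T
                        / (2 * FARADAY ** 2 * c * 1e3)) * 1e9
        val = debye_length_theoretical(c, T, eps_r)
        assert abs(val - ref) / ref < 1e-6

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(FitError):
            debye_length_theoretical(0.0)


# ---------------------------------------------------------------------------
# electrostatic fit
# ---------------------------------------------------------------------------

def exp_window_curve(A, kappa, Z1, sigma=0.0, seed=0, span=100.0, dz=0.8,
                     pad_contact=True):
    """Exponential window plus a short dummy contact tail (no far field,
    so the local-offset correction is skipped)."""
    rng = np.random.default_rng(seed)
    z = np.arange(Z1 - span, Z1, dz)
    F = A * np.exp(-kappa * (Z1 - z))
    if sigma > 0:
        F = F + rng.normal(0, sigma, z.size)
    if pad_contact:
        zc = np.arange(Z1, Z1 + 8 * dz, dz)
        z = np.concatenate([z, zc])
        F = np.concatenate([F, np.full(zc.size, A)])
    return make_curve(z, F)


class TestFitElectrostatic:
    def test_noise_free_recovery(self):
        c = exp_window_curve(0.05, 0.1, -300.0)
        A, kappa, sse = fit_electrostatic(c, -400.0, -300.0)
        assert abs(A - 0.05) / 0.05 < 0.005
        assert abs(1 / kappa - 10.0) / 10.0 < 0.005

    def test_constant_force_pins_kappa_at_lower_bound(self):
        # kappa -> 0 limit: over a window much shorter than the slowest
        # admissible decay the fit pins kappa at the lower bound, A at the level
        z = np.arange(-320.0, -300.0, 1.0)
        c = make_curve(z, np.full(z.size, 0.04))
        A, kappa, _ = fit_electrostatic(c, -320.0, -300.0)
        assert kappa == pytest.approx(1.0 / 200.0, rel=1e-3)
        assert A == pytest.approx(0.04, rel=0.06)

    def test_all_nonpositive_forces_rejected(self):
        z = np.arange(-400.0, -300.0, 1.0)
        c = make_curve(z, np.full(z.size, -0.01))
        with pytest.raises(FitError):
            fit_electrostatic(c, -400.0, -300.0)

    def test_monte_carlo_recovery(self):
        # direct-fit recovery study at moderate noise
        errs = []
        for i in range(100):
            c = exp_window_curve(0.05, 0.1, -300.0, sigma=0.005, seed=500 + i)
            _, kappa, _ = fit_electrostatic(c, -400.0, -300.0)
            errs.append(abs(1 / kappa - 10.0) / 10.0)
        assert np.median(errs) < 0.10

    def test_z_translation_equivariance(self):
        c = exp_window_curve(0.05, 0.1, -300.0, sigma=0.005, seed=9)
        A1, k1, s1 = fit_electrostatic(c, -400.0, -300.0)
        shifted = make_curve(c.z + 1234.5, c.F)
        A2, k2, s2 = fit_electrostatic(shifted, -400.0 + 1234.5, -300.0 + 1234.5)
        assert abs(A1 - A2) < 1e-9
        assert abs(k1 - k2) < 1e-9

    def test_cost_at_fit_not_worse_than_truth(self):
        c = exp_window_curve(0.05, 0.1, -300.0, sigma=0.01, seed=4)
        A, kappa, sse = fit_electrostatic(c, -400.0, -300.0)
        w = (c.z >= -400.0) & (c.z < -300.0)
        s = -300.0 - c.z[w]
        sse_truth = float(np.sum((c.F[w] - 0.05 * np.exp(-0.1 * s)) ** 2))
        assert sse <= sse_truth + 1e-12


# ---------------------------------------------------------------------------
# indentation
# ---------------------------------------------------------------------------

class TestComputeIndentation:
    def test_rigid_surface_gives_zero_indentation(self, config):
        # infinitely stiff sample: all piezo travel goes into deflection
        z = np.linspace(-10, 50, 200)
        F = config.k_c * (z - 0.0)
        delta, _, _ = compute_indentation(make_curve(z, F), 0.0, config.k_c)
        assert np.allclose(delta, 0.0, atol=1e-9)

    def test_constant_force_gives_full_travel(self, config):
        z = np.linspace(-10, 50, 200)
        F = np.full(z.size, 0.5)
        delta, _, _ = compute_indentation(make_curve(z, F), 0.0, config.k_c)
        zc = z[z >= 0]
        assert np.allclose(np.sort(delta), np.sort(zc), atol=1e-9)

    def test_forward_inverse_round_trip(self, config):
        # generate a Hertz branch in delta, map to z, recover delta
        a = hertz_prefactor(1e6)
        delta_true = np.linspace(0, 80, 300)
        F = a * delta_true ** 2
        z = delta_true + F / config.k_c
        delta, Fc, F1 = compute_indentation(make_curve(z - 0.0, F), 0.0, config.k_c)
        assert np.max(np.abs(np.sort(delta) - np.sort(delta_true))) < 1e-9

    def test_too_few_contact_points_rejected(self, config):
        z = np.linspace(-100, 100, 50)
        with pytest.raises(FitError):
            compute_indentation(make_curve(z, np.zeros(50)), 99.0, config.k_c)


# ---------------------------------------------------------------------------
# contact fit
# ---------------------------------------------------------------------------

def contact_data(E=1e6, k_cell=0.1, delta0=0.0, Delta1=50.0, F1=0.05,
                 dmax=150.0, n=600, sigma=0.0, seed=0):
    rng = np.random.default_rng(seed)
    delta = np.linspace(0, dmax, n)
    a = hertz_prefactor(E)
    d = np.clip(delta, delta0, Delta1) - delta0
    F = F1 + a * d ** 2 + k_cell * np.maximum(delta - Delta1, 0.0)
    if sigma > 0:
        F = F + rng.normal(0, sigma, n)
    return delta, F


class TestFitContact:
    def test_hertz_prefactor_unit_conversion(self):
        # a = 2 E tan(alpha) / (pi (1 - nu^2)) at E=1 MPa, nu=0.5, alpha=35
        assert hertz_prefactor(1e6, 0.5, 35.0) == pytest.approx(5.94e-4, rel=2e-3)

    def test_noise_free_recovery(self, config):
        delta, F = contact_data()
        E, k_cell, d0, D1, sse, ok = fit_contact(delta, F, 0.05, 60.0, config)
        assert abs(E - 1e6) / 1e6 < 0.005
        assert abs(k_cell - 0.1) / 0.1 < 0.005
        assert abs(D1 - 50.0) < 0.5
        assert ok

    def test_pure_linear_data_recovers_slope(self, config):
        delta = np.linspace(0, 100, 200)
        F = 0.02 + 0.08 * delta
        E, k_cell, d0, D1, sse, ok = fit_contact(delta, F, 0.02, 1.0, config)
        assert abs(k_cell - 0.08) < 1e-6

    def test_noisy_recovery_monte_carlo(self, config):
        errsE, errsK = [], []
        for i in range(100):
            delta, F = contact_data(sigma=0.02, seed=700 + i)
            E, k_cell, *_ = fit_contact(delta, F, 0.05, 60.0, config)
            errsE.append(abs(E - 1e6) / 1e6)
            errsK.append(abs(k_cell - 0.1) / 0.1)
        assert np.median(errsE) < 0.10
        assert np.median(errsK) < 0.10

    def test_subsampling_invariance(self, config):
        delta, F = contact_data(sigma=0.02, seed=77)
        E1, k1, *_ = fit_contact(delta, F, 0.05, 60.0, config)
        E2, k2, *_ = fit_contact(delta[::2], F[::2], 0.05, 60.0, config)
        assert abs(E1 - E2) / E1 < 0.10
        assert abs(k1 - k2) / k1 < 0.05

    def test_cost_at_fit_not_worse_than_truth(self, config):
        delta, F = contact_data(sigma=0.02, seed=5)
        a = hertz_prefactor(1e6)
        model = 0.05 + a * np.clip(delta, 0, 50.0) ** 2 \
            + 0.1 * np.maximum(delta - 50.0, 0.0)
        sse_truth = float(np.sum((F - model) ** 2))
        *_, sse, _ok = fit_contact(delta, F, 0.05, 60.0, config)
        assert sse <= sse_truth + 1e-9


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------

class TestProcessApproach:
    def test_noise_free_full_recovery(self):
        truth = ApproachTruth(noise_sd=0.0)
        curve, _ = simulate_approach_curve(truth, seed=1)
        res = process_approach(curve)
        assert res.status == "ok"
        assert abs(res.Z1 - truth.Z1) < 0.05
        assert abs(res.A - truth.A) / truth.A < 0.01
        assert abs(res.kappa_inv - 10.0) / 10.0 < 0.01
        assert abs(res.E - truth.E) / truth.E < 0.01
        assert abs(res.k_cell - truth.k_cell) / truth.k_cell < 0.01

    def test_flat_noise_reports_no_electrostatic(self, noise_curve):
        res = process_approach(noise_curve)
        assert res.status == "no_electrostatic"
        assert math.isnan(res.A)

    def test_zero_prefactor_reports_no_electrostatic(self):
        truth = ApproachTruth(A=0.0, noise_sd=0.0)
        curve, _ = simulate_approach_curve(truth, seed=2)
        res = process_approach(curve)
        assert res.status == "no_electrostatic"
        # the mechanical parameters are still recovered from the contact part
        assert abs(res.E - truth.E) / truth.E < 0.02

    def test_status_ok_under_noise(self):
        truth = ApproachTruth(noise_sd=0.01)
        curve, _ = simulate_approach_curve(truth, seed=3)
        res = process_approach(curve)
        assert res.status == "ok"
        assert res.Z0 < res.Z1
        assert 0 <= res.delta0 <= res.Delta1
        assert res.kappa > 0 and res.E >= 0 and res.k_cell >= 0
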