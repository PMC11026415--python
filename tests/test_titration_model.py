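"""Direct and Predictive calculation models, curve prediction and the
pre-nucleation regime analysis."""

from dataclasses import replace

import numpy as np
import pytest

from capspec import (
    BindingConstants,
    EmptyPrenucleationRegime,
    IonInventory,
    TitrationCurve,
    direct_free_calcium,
    equilibrate,
    predict_curve,
    predictive_solve,
    prenucleation_slope,
    truncate_prenucleation,
)
from capspec.chem_core import activities
from capspec.synthetic import ArtifactModel, TitrationProtocol, simulate_titration


def one_pair_activity_oracle(n_ca, n_p, ph, V, k1, acid, aset):
    """Closed-form single-equilibrium solution for the [CaH2PO4]+ pair.

    With only K1 active the bound amount solves the quadratic
    A nb^2 - (A(Ca+P)+1) nb + A Ca P = 0 with A = K1 g2 g1 f1 / (g1 V);
    returns the free-calcium activity.
    """
    from capspec.chem_core import _fraction_arrays

    g = aset.gamma
    fr = _fraction_arrays(ph, acid, aset.ionic_strength)
    A = k1 * g[2] * fr[1] / V  # anion gamma1 cancels against the pair's
    b = A * (n_ca + n_p) + 1.0
    nb = 2 * A * n_ca * n_p / (b + np.sqrt(b * b - 4 * A * A * n_ca * n_p))
    return g[2] * (n_ca - nb) / V


class TestCurveValidation:
    def test_free_above_no_binding_line_rejected(self):
        with pytest.raises(ValueError, match="zero-binding"):
            TitrationCurve(
                added_ca=[1e-6, 2e-6],
                free_ca=[1e-6 / 0.05, 4.1e-5],
                volume=[0.05, 0.05],
                ph=9.8,
            )

    def test_non_monotone_dose_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TitrationCurve(
                added_ca=[2e-6, 1e-6],
                free_ca=[1e-8, 1e-8],
                volume=[0.05, 0.05],
                ph=9.8,
            )

    def test_empty_curve_allowed(self):
        c = TitrationCurve(added_ca=[], free_ca=[], volume=[], ph=9.8)
        assert c.n_points == 0


class TestDirectCalculation:
    def test_no_binding_limit(self, acid):
        K0 = BindingConstants(0.0, 0.0, 0.0)
        curve = TitrationCurve(
            added_ca=np.array([1e-6, 2e-6, 3e-6]),
            free_ca=np.array([1e-6, 2e-6, 3e-6]) / 0.05,
            volume=np.full(3, 0.05),
            ph=9.8,
            n_p_total=5e-4,
        )
        pred = direct_free_calcium(curve, K0, acid)
        assert np.allclose(pred.free_ca_conc, curve.added_ca / 0.05, rtol=1e-12)
        assert np.all(pred.free_ca_activity < pred.free_ca_conc)  # gamma < 1

    def test_round_trip_with_predictive_curve(self, acid, revised, protocol):
        """On a noise-free model curve the measured bound equals the model
        bound, so the Direct model must reproduce the curve pointwise."""
        clean = predict_curve(protocol(9.8), revised, acid)
        pred = direct_free_calcium(clean, revised, acid)
        assert np.allclose(pred.free_ca_conc, clean.free_ca, rtol=1e-8)
        # pair amounts satisfy the bound-calcium balance
        assert np.allclose(
            pred.n_bound, clean.bound_amount(), rtol=1e-6
        )

    def test_low_ph_single_pair_closed_form(self, acid):
        K = BindingConstants(4.5, 0.0, 0.0)
        proto = TitrationProtocol(target_ph=4.3)
        clean = predict_curve(proto, K, acid)
        pred = direct_free_calcium(clean, K, acid)
        # evaluate the closed form at the model's converged ionic strength
        aset = activities(
            IonInventory(volume=float(clean.volume[-1])),
            I=float(pred.ionic_strength[-1]),
        )
        oracle = one_pair_activity_oracle(
            float(clean.added_ca[-1]), clean.n_p_total, 4.3,
            float(clean.volume[-1]), 4.5, acid, aset,
        )
        assert float(pred.free_ca_activity[-1]) == pytest.approx(oracle, rel=1e-6)

    def test_inconsistent_measurement_rejected(self, acid, revised):
        curve = TitrationCurve(
            added_ca=np.array([1e-3, 2e-3, 3e-3]),
            free_ca=np.zeros(3),
            volume=np.full(3, 0.05),
            ph=9.8,
            n_p_total=5e-4,  # bound (3e-3) exceeds total phosphate
        )
        from capspec import InconsistentMeasurementError

        with pytest.raises(InconsistentMeasurementError):
            direct_free_calcium(curve, revised, acid)


class TestPredictiveCalculation:
    def test_zero_constants_no_pairs(self, acid):
        inv, aset = equilibrate(
            5e-4, 1e-2, IonInventory(volume=1.0), 9.8,
            BindingConstants(0, 0, 0), acid,
        )
        mp = predictive_solve(5e-4, 1e-2, 9.8, 1.0, BindingConstants(0, 0, 0),
                              acid, aset)
        assert mp.n_bound == 0.0
        assert float(mp.free_ca_conc) == pytest.approx(5e-4, rel=1e-14)

    def test_single_pair_matches_quadratic(self, acid):
        K = BindingConstants(4.5, 0.0, 0.0)
        inv, aset = equilibrate(5e-4, 1e-2, IonInventory(volume=1.0), 4.3, K, acid)
        mp = predictive_solve(5e-4, 1e-2, 4.3, 1.0, K, acid, aset)
        oracle = one_pair_activity_oracle(5e-4, 1e-2, 4.3, 1.0, 4.5, acid, aset)
        assert float(mp.free_ca_activity) == pytest.approx(oracle, rel=1e-10)

    @pytest.mark.parametrize("ph", [8.3, 9.3, 9.8, 10.8, 11.3])
    def test_matches_equilibrate_formulation(self, acid, revised, ph):
        """The multivariate root solve and the damped fixed point are two
        independent formulations of the same equilibrium."""
        inv, aset = equilibrate(5e-4, 1e-2, IonInventory(volume=1.0), ph,
                                revised, acid)
        mp = predictive_solve(5e-4, 1e-2, ph, 1.0, revised, acid, aset)
        assert mp.n_bound == pytest.approx(inv.bound_calcium(), rel=1e-8)
        assert np.allclose(
            mp.n_pairs,
            [inv.cah2po4, inv.cahpo4, inv.capo4],
            rtol=1e-6, atol=1e-20,
        )

    def test_mass_balance_over_random_draws(self, acid):
        rng = np.random.default_rng(11)
        for _ in range(100):
            k = BindingConstants(*(10.0 ** rng.uniform(-1, 5, size=3)))
            ca = float(rng.uniform(1e-6, 2e-3))
            p = float(rng.uniform(1e-4, 2e-2))
            ph = float(rng.uniform(4.0, 11.5))
            inv, aset = equilibrate(ca, p, IonInventory(volume=1.0), ph, k, acid)
            mp = predictive_solve(ca, p, ph, 1.0, k, acid, aset)
            assert float(mp.free_ca_conc) + mp.n_bound == pytest.approx(ca, rel=1e-12)
            assert np.all(mp.n_pairs >= -1e-30)
            assert mp.n_bound <= min(ca, p) * (1 + 1e-9)

    def test_monotone_in_each_constant(self, acid, revised):
        """Strengthening any association weakly lowers the free calcium."""
        base_inv, aset = equilibrate(5e-4, 1e-2, IonInventory(volume=1.0), 9.8,
                                     revised, acid)
        for name in ("k1", "k2", "k3"):
            stronger = replace(revised, **{name: getattr(revised, name) * 3})
            inv, _ = equilibrate(5e-4, 1e-2, IonInventory(volume=1.0), 9.8,
                                 stronger, acid)
            assert inv.ca <= base_inv.ca + 1e-18


class TestPredictCurve:
    def test_zero_doses_empty_curve(self, acid, revised):
        proto = TitrationProtocol(target_ph=9.8, n_steps=0)
        curve = predict_curve(proto, revised, acid)
        assert curve.n_points == 0

    def test_quasi_static_rate_invariance(self, acid, revised):
        """Doubling the dose rate cannot change the curve as a function of
        added calcium: each point is an independent equilibrium."""
        slow = predict_curve(TitrationProtocol(target_ph=9.8), revised, acid)
        fast = predict_curve(
            TitrationProtocol(target_ph=9.8, dose_rate_ml_min=0.02), revised, acid
        )
        assert np.array_equal(slow.added_ca, fast.added_ca)
        assert np.array_equal(slow.free_ca, fast.free_ca)

    def test_curve_below_no_binding_line(self, acid, revised):
        curve = predict_curve(TitrationProtocol(target_ph=9.8), revised, acid)
        assert np.all(curve.free_amount() < curve.added_ca)


class TestPrenucleationRegime:
    def _curve(self, free_fraction):
        added = np.linspace(1e-6, 5e-5, 20)
        return TitrationCurve(
            added_ca=added,
            free_ca=free_fraction * added / 0.05,
            volume=np.full(20, 0.05),
            ph=9.8,
        )

    def test_identity_slope(self):
        assert prenucleation_slope(self._curve(1.0)).slope == pytest.approx(1.0)

    def test_all_bound_slope(self):
        assert prenucleation_slope(self._curve(0.0)).slope == pytest.approx(0.0, abs=1e-15)

    def test_too_few_points(self):
        c = self._curve(1.0).head(2)
        with pytest.raises(ValueError, match=">= 3"):
            prenucleation_slope(c)

    def test_slope_matches_one_pair_analytic_derivative(self, acid):
        """Single-pair curve at pH 4.3: the fitted slope agrees with the
        analytic derivative of the closed-form free calcium."""
        K = BindingConstants(4.5, 0.0, 0.0)
        curve = predict_curve(TitrationProtocol(target_ph=4.3), K, acid)
        fit = prenucleation_slope(curve)
        # analytic derivative via the oracle at two nearby dose amounts
        inv, aset = equilibrate(
            float(curve.added_ca[-1]) / 2, curve.n_p_total,
            IonInventory(volume=float(np.median(curve.volume))), 4.3, K, acid,
        )
        V = float(np.median(curve.volume))
        n_mid = float(curve.added_ca[-1]) / 2
        h = 1e-9
        f = lambda n: one_pair_activity_oracle(
            n, curve.n_p_total, 4.3, V, 4.5, acid, aset
        ) / aset.gamma[2] * V
        analytic = (f(n_mid + h) - f(n_mid - h)) / (2 * h)
        assert fit.slope == pytest.approx(analytic, rel=0.02)

    def test_slope_decreases_with_ph(self, acid, revised):
        """More deprotonated phosphate binds more calcium: the
        pre-nucleation slope falls as pH rises."""
        slopes = []
        for ph in (7.3, 8.3, 9.3, 9.8, 10.8, 11.3):
            c = predict_curve(TitrationProtocol(target_ph=ph), revised, acid)
            slopes.append(prenucleation_slope(c).slope)
        assert all(a > b for a, b in zip(slopes, slopes[1:]))
        assert 0 <= slopes[-1] <= slopes[0] <= 1

    def test_linear_curve_unchanged(self):
        c = self._curve(0.6)
        out = truncate_prenucleation(c, window=10, threshold=0.01)
        assert out.n_points == c.n_points

    def test_truncation_finds_nucleation_drop(self, acid, revised):
        clean = predict_curve(TitrationProtocol(target_ph=9.8), revised, acid)
        free = clean.free_ca.copy()
        k_drop = 35
        free[k_drop:] *= np.linspace(0.95, 0.4, free.size - k_drop)
        dropped = replace(clean, free_ca=free)
        out = truncate_prenucleation(dropped, window=10, threshold=0.01)
        assert abs(out.n_points - k_drop) <= 10

    def test_convex_artifact_curve_has_no_linear_regime(self, acid, revised):
        art = simulate_titration(
            TitrationProtocol(target_ph=9.8), revised, acid, noise_cv=0.0,
            artifact=ArtifactModel(mode="premature_separation"), seed=0,
        )[0]
        with pytest.raises(EmptyPrenucleationRegime):
            truncate_prenucleation(art)

    def test_insufficient_points_rejected(self):
        c = self._curve(0.6).head(8)
        with pytest.raises(ValueError, match="window"):
            truncate_prenucleation(c, window=10)
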