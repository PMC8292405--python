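"""Sequential-chain solution, global surface fitting and rate reporting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

import photocyclekit as pk
from photocyclekit.kinetics import rate_report


def _rates_well_separated(taus, min_rel_gap=1e-3):
    """Exclude near-degenerate chains, handled by explicit perturbation."""
    k = sorted(1.0 / t for t in taus)
    return all(b - a > min_rel_gap * k[-1] for a, b in zip(k, k[1:]))


def ode_occupancies(taus, times, excited_fraction=1.0):
    """Numerical integration of the irreversible chain (independent oracle)."""
    k = 1.0 / np.asarray(taus, dtype=float)

    def rhs(_, y):
        dy = np.empty_like(y)
        dy[0] = -k[0] * y[0]
        for i in range(1, k.size):
            dy[i] = k[i - 1] * y[i - 1] - k[i] * y[i]
        return dy

    y0 = np.zeros(k.size)
    y0[0] = excited_fraction
    sol = solve_ivp(
        rhs, (times[0] * 1e-6, times[-1]), y0, t_eval=times,
        method="LSODA", rtol=1e-10, atol=1e-12,
    )
    return sol.y


class TestSequentialOccupancies:
    def test_single_intermediate_is_plain_exponential(self):
        model = pk.SequentialModel([1.0], labels=("P1",))
        t = np.linspace(0.1, 5, 40)
        occ, ground = pk.sequential_occupancies(model, t)
        np.testing.assert_allclose(occ[0], np.exp(-t), rtol=1e-14)
        np.testing.assert_allclose(ground, 1 - np.exp(-t), rtol=1e-12)

    def test_matches_ode_integration(self):
        t = np.geomspace(0.01, 50, 60)
        occ, _ = pk.sequential_occupancies(pk.SequentialModel([1.0, 2.0, 4.0]), t)
        np.testing.assert_allclose(occ, ode_occupancies([1.0, 2.0, 4.0], t), atol=1e-8)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(min_value=-2.0, max_value=2.0), min_size=3, max_size=3)
        .map(lambda xs: [10.0**x for x in xs])
        .filter(_rates_well_separated)
    )
    def test_bateman_equals_matrix_exponential_over_four_decades(self, taus):
        """The closed form must agree with the exact linear-ODE propagator."""
        t = np.geomspace(0.01, 100, 40)
        occ, _ = pk.sequential_occupancies(pk.SequentialModel(taus), t)
        k = 1.0 / np.asarray(taus)
        A = np.diag(-k) + np.diag(k[:-1], -1)
        oracle = np.column_stack([expm(A * ti)[:, 0] for ti in t])
        np.testing.assert_allclose(occ, oracle, atol=1e-8)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=1, max_size=4)
        .filter(_rates_well_separated),
        st.floats(min_value=0.05, max_value=1.0),
    )
    def test_conservation_and_monotonicity(self, taus, excited):
        t = np.geomspace(0.01, 1000, 80)
        occ, ground = pk.sequential_occupancies(pk.SequentialModel(taus), t, excited)
        np.testing.assert_allclose(occ.sum(axis=0) + ground, excited, atol=1e-12)
        # strict monotonicity up to float roundoff/saturation of the exp terms
        assert np.all(np.diff(occ[0]) <= 1e-13) and occ[0][0] > occ[0][-1]
        assert np.all(np.diff(ground) >= -1e-13) and ground[-1] > ground[0]
        assert occ.min() > -1e-12 and occ.max() <= excited + 1e-12

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            pk.SequentialModel([1.0, -2.0])
        with pytest.raises(ValueError):
            pk.sequential_occupancies(pk.SequentialModel([1.0]), [-0.1, 1.0])

    def test_near_degenerate_taus_warn_but_stay_finite(self):
        with pytest.warns(RuntimeWarning, match="near-degenerate"):
            occ, _ = pk.sequential_occupancies(
                pk.SequentialModel([1.0, 1.0 + 1e-12]), np.geomspace(0.1, 10, 20)
            )
        assert np.all(np.isfinite(occ))


class TestComposeSurface:
    def test_zero_sads_gives_zero_surface_and_linearity(self):
        t = np.geomspace(0.1, 100, 30)
        wl = np.arange(400.0, 600.0, 10.0)
        occ, _ = pk.sequential_occupancies(pk.SequentialModel([1.0, 5.0]), t)
        sads = np.vstack([np.sin(wl / 50), np.cos(wl / 70)])
        assert not np.any(pk.compose_surface(occ, np.zeros_like(sads), wl, t).delta_A)
        one = pk.compose_surface(occ, sads, wl, t).delta_A
        two = pk.compose_surface(2 * occ, sads, wl, t).delta_A
        np.testing.assert_allclose(two, 2 * one, rtol=1e-14)

    def test_dimension_mismatch_raises(self):
        occ = np.zeros((2, 5))
        with pytest.raises(ValueError):
            pk.compose_surface(occ, np.zeros((3, 4)), np.arange(4.0), np.arange(1.0, 6.0))


class TestGlobalFit:
    def test_noiseless_recovery_is_exact(self, noiseless_surface):
        fit = pk.fit_global_sequential(noiseless_surface)
        np.testing.assert_allclose(
            fit.model.decay_taus, [0.015, 6.4, 30.0], rtol=1e-6
        )
        assert fit.converged

    def test_refit_of_own_output_is_idempotent(self, noiseless_surface):
        fit = pk.fit_global_sequential(noiseless_surface)
        occ, _ = pk.sequential_occupancies(fit.model, noiseless_surface.times)
        refit = pk.fit_global_sequential(
            pk.compose_surface(occ, fit.sads, fit.wavelengths, noiseless_surface.times)
        )
        np.testing.assert_allclose(
            refit.model.decay_taus, fit.model.decay_taus, rtol=1e-6
        )

    def test_init_order_does_not_change_sorted_result(self, noiseless_surface):
        a = pk.fit_global_sequential(noiseless_surface, init_taus=[0.05, 5.0, 50.0])
        b = pk.fit_global_sequential(noiseless_surface, init_taus=[50.0, 0.05, 5.0])
        np.testing.assert_allclose(a.model.decay_taus, b.model.decay_taus, rtol=1e-8)
        assert np.all(np.diff(a.model.decay_taus) > 0)

    def test_noisy_recovery_within_ten_percent(self):
        gt = pk.PhotocycleGroundTruth(noise_sigma=0.05, seed=0)
        fit = pk.fit_global_sequential(pk.generate_transient_surface(gt))
        np.testing.assert_allclose(
            fit.model.decay_taus, [0.015, 6.4, 30.0], rtol=0.10
        )

    def test_three_wavelength_restricted_fit_recovers_taus(self, noiseless_surface):
        fit = pk.fit_global_sequential(noiseless_surface, wavelengths=(400, 540, 600))
        assert fit.wavelengths.size == 3
        np.testing.assert_allclose(fit.model.decay_taus, [0.015, 6.4, 30.0], rtol=1e-6)

    def test_too_many_intermediates_is_an_error(self, noiseless_surface):
        with pytest.raises(Exception):
            pk.fit_global_sequential(noiseless_surface, n_intermediates=30)

    def test_short_time_span_rejected(self):
        t = np.linspace(1.0, 5.0, 20)
        wl = np.arange(400.0, 500.0, 10.0)
        surf = pk.TransientSurface(wl, t, np.zeros((wl.size, t.size)))
        with pytest.raises(ValueError, match="two decades"):
            pk.fit_global_sequential(surf)


class TestAssignment:
    def test_default_synthetic_sads_label_k_m_o_in_tau_order(self, noiseless_surface):
        fit = pk.assign_intermediates(pk.fit_global_sequential(noiseless_surface))
        assert fit.model.labels == ("K", "M", "O")
        assert not fit.assignments["non_canonical"]

    def test_spectrally_silent_components_stay_unassigned(self, noiseless_surface):
        fit = pk.fit_global_sequential(noiseless_surface)
        fit.sads = np.zeros_like(fit.sads)
        out = pk.assign_intermediates(fit)
        assert all(lab.startswith("unassigned") for lab in out.model.labels)
        assert out.assignments["non_canonical"]

    def test_blue_band_on_fastest_component_flagged_non_canonical(self):
        gt = pk.PhotocycleGroundTruth(
            noise_sigma=0.0,
            sads_templates={
                "K": (pk.GaussianBand(400.0, 0.8, 30.0), pk.GaussianBand(540.0, -1.0, 35.0)),
                "M": (pk.GaussianBand(600.0, 0.6, 40.0), pk.GaussianBand(540.0, -1.0, 35.0)),
                "O": (pk.GaussianBand(600.0, 0.9, 45.0), pk.GaussianBand(540.0, -1.0, 35.0)),
            },
        )
        fit = pk.assign_intermediates(
            pk.fit_global_sequential(pk.generate_transient_surface(gt))
        )
        assert fit.model.labels[0] == "M"
        assert fit.assignments["non_canonical"]


class TestRatesAndTraces:
    @pytest.mark.parametrize(
        "tau, expected", [(6.4, 0.16), (30.0, 0.03), (1.0, 1.0)]
    )
    def test_rounded_rates_match_reporting_convention(self, tau, expected):
        raw, rounded = pk.tau_to_rate(tau)
        assert raw * tau == 1.0
        assert rounded == expected

    def test_rate_report_covers_all_intermediates(self):
        rep = rate_report(pk.SequentialModel([0.015, 6.4, 30.0]))
        np.testing.assert_allclose(rep.raw_rates * [0.015, 6.4, 30.0], 1.0, rtol=1e-15)
        assert list(rep.decay_rates[1:]) == [0.16, 0.03]

    def test_tau_to_rate_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            pk.tau_to_rate(0.0)

    def test_nearest_gridpoint_extraction(self, noiseless_surface):
        traces = pk.traces_at(noiseless_surface, [540.0, 541.0])
        assert set(traces) == {540.0}
        np.testing.assert_array_equal(
            traces[540.0],
            noiseless_surface.delta_A[list(noiseless_surface.wavelengths).index(540.0)],
        )
        with pytest.raises(ValueError):
            pk.traces_at(noiseless_surface, [4000.0])

    def test_blue_trace_peaks_after_early_red_trace(self, noiseless_surface):
        traces = pk.traces_at(noiseless_surface, [400.0, 600.0])
        t = noiseless_surface.times
        early_red_peak = t[np.argmax(traces[600.0][t < 1.0])]
        blue_peak = t[np.argmax(traces[400.0])]
        assert blue_peak > early_red_peak
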