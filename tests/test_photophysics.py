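"""Spectra, GP, radiative lifetimes, anisotropy, TCSPC simulation and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laurdanscope.photophysics import (
    anisotropy_from_vectors,
    band_intensity,
    convolve_spectrum,
    decay_time_histogram,
    find_peak_and_shoulders,
    fit_anisotropy_exponential,
    fit_exponential_decay,
    generalized_polarization,
    gp_from_spectrum,
    radiative_lifetime,
    simulate_tcspc_decay,
    steady_state_anisotropy,
    two_population_anisotropy,
)
from laurdanscope.records import Curve, EmissionRecord
from laurdanscope.synthetic import simulate_dipole_wobble, wobble_plateau_ratio


def _rec(lam, f=0.5, conf="I", i=0):
    return EmissionRecord.from_wavelength(i, conf, lam, f)


class TestSpectralConvolution:
    def test_single_record_gaussian_shape(self):
        spec = convolve_spectrum([_rec(400.0)], fwhm=15.0,
                                 grid=np.arange(350.0, 450.0, 0.25))
        x, y = spec.wavelength_grid, spec.intensity
        assert x[np.argmax(y)] == pytest.approx(400.0, abs=0.3)
        half_idx = np.argmin(np.abs(x - (400.0 - 7.5)))
        assert y[half_idx] == pytest.approx(y.max() / 2.0, rel=0.01)

    def test_two_separated_records_two_maxima(self):
        spec = convolve_spectrum([_rec(400.0), _rec(430.0)], fwhm=15.0)
        peak, shoulders = find_peak_and_shoulders(spec)
        kinds = {s["kind"] for s in shoulders}
        assert peak is not None
        assert len(shoulders) >= 1 and "local_max" in kinds

    def test_matches_per_record_summation_oracle(self):
        rng = np.random.default_rng(6)
        recs = [_rec(float(rng.uniform(350, 480)), float(rng.uniform(0.1, 1)),
                     "I" if i % 2 else "II", i) for i in range(50)]
        grid = np.arange(300.0, 530.0, 0.5)
        spec = convolve_spectrum(recs, fwhm=15.0, grid=grid)
        sigma = 15.0 / (2 * np.sqrt(2 * np.log(2)))
        oracle = np.zeros_like(grid)
        for r in recs:
            oracle += r.oscillator_strength * np.exp(
                -0.5 * ((grid - r.wavelength) / sigma) ** 2)
        np.testing.assert_allclose(spec.intensity, oracle, rtol=1e-12)

    def test_linear_in_record_list(self):
        grid = np.arange(350.0, 450.0, 0.5)
        a = [_rec(390.0, 0.4)]
        b = [_rec(410.0, 0.7)]
        sa = convolve_spectrum(a, grid=grid).intensity
        sb = convolve_spectrum(b, grid=grid).intensity
        sab = convolve_spectrum(a + b, grid=grid).intensity
        np.testing.assert_allclose(sab, sa + sb, rtol=1e-12)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            convolve_spectrum([])


class TestPeakAndShoulders:
    def test_single_gaussian_no_shoulders(self):
        spec = convolve_spectrum([_rec(400.0)], fwhm=15.0,
                                 grid=np.arange(340.0, 460.0, 0.5))
        peak, shoulders = find_peak_and_shoulders(spec)
        assert peak == pytest.approx(400.0, abs=0.5)
        assert shoulders == []

    def test_red_shoulder_of_dominant_peak(self):
        # dominant component at 360 plus a 40% component 15 nm to the red
        recs = [_rec(360.0, 1.0, "I"), _rec(375.0, 0.4, "II")]
        spec = convolve_spectrum(recs, fwhm=15.0,
                                 grid=np.arange(310.0, 440.0, 0.5))
        peak, shoulders = find_peak_and_shoulders(spec)
        assert peak == pytest.approx(360.0, abs=1.0)
        assert any(370.0 <= s["wavelength_nm"] <= 385.0 for s in shoulders)

    def test_flat_spectrum_flagged(self):
        from laurdanscope.photophysics import Spectrum
        spec = Spectrum(wavelength_grid=np.arange(400.0, 410.0, 0.5),
                        intensity=np.ones(20))
        assert find_peak_and_shoulders(spec) == (None, [])


class TestGeneralizedPolarization:
    @pytest.mark.parametrize("blue, red, gp", [
        (1.0, 1.0, 0.0), (1.0, 0.0, 1.0), (0.0, 1.0, -1.0)])
    def test_degenerate_cases(self, blue, red, gp):
        assert generalized_polarization(blue, red) == pytest.approx(gp)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            generalized_polarization(0.0, 0.0)

    def test_band_integration_from_spectrum(self):
        spec = convolve_spectrum([_rec(440.0)], fwhm=15.0,
                                 grid=np.arange(380.0, 560.0, 0.5))
        gp = gp_from_spectrum(spec)
        assert 0.9 < gp <= 1.0  # all intensity in the blue channel
        assert band_intensity(spec, 440.0) > band_intensity(spec, 490.0)


class TestRadiativeLifetime:
    def test_reference_value(self):
        # f = 1 at 25000 cm^-1 (400 nm): tau = 1.499/25000^2 s = 2.398 ns
        rec = _rec(400.0, 1.0)
        assert radiative_lifetime(rec) == pytest.approx(2.3984, abs=1e-3)

    def test_frequency_squared_scaling(self):
        assert radiative_lifetime(_rec(400.0, 1.0)) / \
            radiative_lifetime(_rec(200.0, 1.0)) == pytest.approx(4.0, rel=1e-9)

    def test_inverse_in_oscillator_strength(self):
        assert radiative_lifetime(_rec(400.0, 0.5)) == pytest.approx(
            2 * radiative_lifetime(_rec(400.0, 1.0)), rel=1e-12)

    def test_zero_strength_rejected(self):
        with pytest.raises(ValueError, match="oscillator"):
            radiative_lifetime(EmissionRecord(0, "I", 3.0, 0.0))

    def test_histogram_normalized_with_consistent_mean(self):
        rng = np.random.default_rng(7)
        recs = [_rec(float(rng.uniform(380, 460)), float(rng.uniform(0.2, 1)),
                     "I", i) for i in range(200)]
        hists = decay_time_histogram(recs, bins=25)
        edges, dens = hists["I"]
        widths = np.diff(edges)
        assert np.sum(dens * widths) == pytest.approx(1.0, abs=1e-12)
        centers = 0.5 * (edges[:-1] + edges[1:])
        hist_mean = np.sum(dens * widths * centers)
        direct = np.mean([radiative_lifetime(r) for r in recs])
        assert hist_mean == pytest.approx(direct, abs=widths[0] / 2)


class TestAnisotropyDecay:
    def test_frozen_dipole_stays_at_r0(self):
        v = np.tile([0.0, 0.0, 1.0], (50, 1))
        c = anisotropy_from_vectors(v, 0.1, 2.0)
        np.testing.assert_allclose(c.y, 0.4, atol=1e-12)

    def test_uncorrelated_dipoles_decay_to_zero(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal((30000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        c = anisotropy_from_vectors(v, 0.1, 0.5)
        assert c.y[0] == pytest.approx(0.4, abs=1e-12)
        np.testing.assert_allclose(c.y[1:], 0.0, atol=0.02)

    def test_free_diffusion_rate_is_6d(self):
        d_rot, dt = 0.3, 0.005
        rng = np.random.default_rng(9)
        ys = []
        for _ in range(12):
            v = simulate_dipole_wobble(8000, dt, d_rot, None, rng)
            ys.append(anisotropy_from_vectors(v, dt, 1.5, origin_stride=9).y)
        curve = Curve(t=np.arange(0, 1.5 + dt / 2, dt), y=np.mean(ys, axis=0),
                      kind="anisotropy")
        _, theta, _, _ = fit_anisotropy_exponential(curve, with_offset=False)
        assert 1.0 / theta == pytest.approx(6 * d_rot, rel=0.05)

    def test_cone_plateau_closed_form(self):
        rng = np.random.default_rng(10)
        v = simulate_dipole_wobble(20000, 0.01, 2.0, 40.0, rng)
        c = anisotropy_from_vectors(v, 0.01, 40.0, origin_stride=5)
        plateau = np.mean(c.y[-len(c.y) // 5:]) / 0.4
        assert plateau == pytest.approx(wobble_plateau_ratio(40.0), abs=0.03)

    def test_max_lag_beyond_span_rejected(self):
        v = np.tile([0.0, 0.0, 1.0], (10, 1))
        with pytest.raises(ValueError, match="max_lag"):
            anisotropy_from_vectors(v, 0.1, 2.0)


class TestTCSPCSimulation:
    def test_total_counts_conserved(self):
        c = simulate_tcspc_decay([(4.0, 100.0)], 20000, seed=1)
        assert c.y.sum() == 20000

    def test_mono_exponential_mean_arrival(self):
        tau, n = 3.0, 200000
        c = simulate_tcspc_decay([(tau, 100.0)], n, bin_width=0.02, seed=2)
        mean = np.sum(c.t * c.y) / n
        assert mean == pytest.approx(tau, abs=3 * tau / np.sqrt(n) + 0.02)

    def test_irf_shifts_mean_by_its_center(self):
        tau, mu, n = 3.0, 1.5, 200000
        c = simulate_tcspc_decay([(tau, 100.0)], n, irf=(mu, 0.2),
                                 bin_width=0.02, seed=3)
        mean = np.sum(c.t * c.y) / n
        assert mean == pytest.approx(tau + mu, abs=3 * tau / np.sqrt(n) + 0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_tcspc_decay([(4.0, 100.0)], 0)
        with pytest.raises(ValueError, match="sum"):
            simulate_tcspc_decay([(4.0, 60.0)], 100)


class TestExponentialFitting:
    def test_noiseless_mono_exponential_exact(self):
        tau = 5.0
        t = np.arange(0.025, 40.0, 0.05)
        y = 1e5 * 0.05 / tau * np.exp(-t / tau)
        res = fit_exponential_decay(Curve(t=t, y=y, kind="intensity"), 1)
        assert res.lifetimes[0] == pytest.approx(5.0, abs=2e-4)
        assert res.intensity_fractions[0] == pytest.approx(100.0, abs=1e-9)

    def test_fractions_sum_to_100_and_order_slow_fast(self):
        c = simulate_tcspc_decay([(6.0, 50.0), (2.0, 50.0)], 100000,
                                 bin_width=0.05, seed=4)
        res = fit_exponential_decay(c, 2)
        assert res.intensity_fractions.sum() == pytest.approx(100.0, abs=1e-6)
        assert res.lifetimes[0] >= res.lifetimes[1]

    def test_equivariant_under_count_rescaling(self):
        c = simulate_tcspc_decay([(4.0, 100.0)], 50000, bin_width=0.05, seed=5)
        res_a = fit_exponential_decay(c, 1)
        c10 = Curve(t=c.t, y=c.y * 10.0, kind="intensity")
        res_b = fit_exponential_decay(c10, 1)
        assert res_b.lifetimes[0] == pytest.approx(res_a.lifetimes[0], rel=1e-4)

    def test_matches_grid_search_oracle(self):
        """Bi-exponential MLE agrees with an exhaustive coarse grid search."""
        from scipy import stats as sps
        c = simulate_tcspc_decay([(6.0, 50.0), (2.0, 50.0)], 50000,
                                 bin_width=0.05, seed=6)
        res = fit_exponential_decay(c, 2)
        bw = c.t[1] - c.t[0]
        edges = np.concatenate([c.t - bw / 2, [c.t[-1] + bw / 2]])
        total = c.y.sum()

        def nll(t1, t2, f1):
            q = (f1 / 100.0) * np.diff(sps.expon.cdf(edges, scale=t1)) + \
                (1 - f1 / 100.0) * np.diff(sps.expon.cdf(edges, scale=t2))
            amp = total / q.sum()
            m = np.clip(amp * q, 1e-12, None)
            return np.sum(m - c.y * np.log(m))

        grid_t1 = np.arange(5.0, 7.01, 0.25)
        grid_t2 = np.arange(1.5, 2.51, 0.25)
        grid_f1 = np.arange(35.0, 65.1, 5.0)
        best = min(((nll(a, b, f), a, b, f) for a in grid_t1 for b in grid_t2
                    for f in grid_f1))
        assert res.lifetimes[0] == pytest.approx(best[1], abs=0.25)
        assert res.lifetimes[1] == pytest.approx(best[2], abs=0.25)
        assert res.intensity_fractions[0] == pytest.approx(best[3], abs=5.0)

    def test_too_few_bins_rejected(self):
        t = np.arange(0.05, 0.4, 0.05)
        with pytest.raises(ValueError, match="bins"):
            fit_exponential_decay(Curve(t=t, y=np.ones_like(t),
                                        kind="intensity"), 1)


class TestTwoPopulationAnisotropy:
    def test_equal_components_collapse(self):
        t = np.linspace(0.0, 20.0, 100)
        c, trunc = two_population_anisotropy(
            [(30.0, 7.0, {"r": 0.3}), (70.0, 3.0, {"r": 0.3})], t)
        assert not trunc
        np.testing.assert_allclose(c.y, 0.3, atol=1e-12)

    def test_value_at_time_zero(self):
        pops = [(43.0, 7.46, {"r": 0.35}), (57.0, 3.58, {"r": 0.1})]
        t = np.array([0.0, 1.0])
        c, _ = two_population_anisotropy(pops, t)
        w1, w2 = 43.0 / 7.46, 57.0 / 3.58
        expected = (w1 * 0.35 + w2 * 0.1) / (w1 + w2)
        assert c.y[0] == pytest.approx(expected, abs=1e-12)

    def test_turn_up_from_slow_constant_plus_fast_decaying(self):
        # the slow population holds r high while the fast one decays:
        # as the fast component dies out the mixture anisotropy rises again
        t = np.linspace(0.0, 20.0, 500)
        c, _ = two_population_anisotropy(
            [(43.0, 7.46, {"r": 0.35}),
             (57.0, 3.58, {"r0": 0.35, "r_inf": 0.0, "theta": 1.39})], t)
        dy = np.diff(c.y)
        falls_then_rises = (dy[:50] < 0).all() and (dy > 1e-6).any()
        assert falls_then_rises

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            two_population_anisotropy([(50.0, 5.0, {"r": 0.3})],
                                      np.linspace(0, 1, 5))


class TestSteadyStateAnisotropy:
    def test_constant_anisotropy_passthrough(self):
        t = np.linspace(0.0, 30.0, 500)
        r = Curve(t=t, y=np.full_like(t, 0.25), kind="anisotropy")
        i = Curve(t=t, y=np.exp(-t / 3.0), kind="intensity")
        assert steady_state_anisotropy(r, i) == pytest.approx(0.25, abs=1e-12)

    def test_perrin_closed_form(self):
        tau, theta = 4.0, 2.5
        t = np.arange(0.0, 150.0, 0.001)
        r = Curve(t=t, y=0.4 * np.exp(-t / theta), kind="anisotropy")
        i = Curve(t=t, y=np.exp(-t / tau), kind="intensity")
        assert steady_state_anisotropy(r, i) == pytest.approx(
            0.4 / (1.0 + tau / theta), abs=1e-4)

    def test_zero_anisotropy_and_zero_intensity(self):
        t = np.linspace(0.0, 10.0, 100)
        r = Curve(t=t, y=np.zeros_like(t), kind="anisotropy")
        i = Curve(t=t, y=np.exp(-t / 2.0), kind="intensity")
        assert steady_state_anisotropy(r, i) == 0.0
        with pytest.raises(ValueError):
            steady_state_anisotropy(r, Curve(t=t, y=np.zeros_like(t),
                                             kind="intensity"))


@settings(deadline=None, max_examples=25)
@given(st.floats(0.5, 10.0), st.floats(10.0, 90.0))
def test_fraction_weights_and_plateau_invariants(tau, frac):
    """Intensity fractions always sum to 100; cone plateau ratio in [0, 1]."""
    pops = [(frac, tau, {"r": 0.3}), (100.0 - frac, tau / 2, {"r": 0.1})]
    t = np.linspace(0.0, 5.0, 50)
    c, _ = two_population_anisotropy(pops, t)
    assert np.all(c.y <= 0.3 + 1e-12) and np.all(c.y >= 0.1 - 1e-12)
    ratio = wobble_plateau_ratio(frac)  # reuse frac as an angle in degrees
    assert 0.0 <= ratio <= 1.0
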