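"""Core TF analysis: analytic signal, WVD, directional kernels, orientation
maps and adaptive smoothing."""

import numpy as np
import pytest
import scipy.ndimage
import scipy.signal

from oracles import brute_direction_map, brute_wvd
from tfseize import (
    ConfigError,
    InvalidInputError,
    KernelParams,
    SampledSignal,
    TimeFrequencyDistribution,
    adtfd,
    analytic_signal,
    compute_adtfd,
    direction_map,
    directional_kernel,
    top_energy_mask,
    wvd,
)
from tfseize.tfd import DirectionMap

FS = 32.0
N = 256


class TestAnalyticSignal:
    def test_cosine_has_unit_modulus(self, tone_signal):
        z = analytic_signal(tone_signal)
        interior = np.abs(z)[16:-16]
        assert np.allclose(interior, 1.0, atol=1e-2)

    def test_real_part_recovers_input(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(128)
        assert np.allclose(analytic_signal(x).real, x, atol=1e-10)

    def test_dc_passes_unchanged(self):
        z = analytic_signal(np.ones(64))
        assert np.allclose(z, 1.0, atol=1e-12)

    def test_negative_frequency_bins_vanish(self, tone_signal):
        spec = np.fft.fft(analytic_signal(tone_signal))
        neg = spec[N // 2 + 1 :]
        assert np.abs(neg).max() < 1e-8 * np.abs(spec).max()

    def test_nonfinite_input_rejected(self):
        with pytest.raises(InvalidInputError):
            analytic_signal(np.array([1.0, np.nan, 2.0]))


class TestWvd:
    def test_tone_peaks_at_its_frequency(self, tone_wvd):
        profile = np.abs(tone_wvd.values).mean(axis=0)
        peak_hz = tone_wvd.freq_axis[np.argmax(profile)]
        assert abs(peak_hz - 4.0) <= tone_wvd.df

    def test_time_marginal_identity(self, tone_signal, tone_wvd):
        z = analytic_signal(tone_signal)
        marginal = tone_wvd.values.sum(axis=1) * tone_wvd.df
        expected = np.abs(z) ** 2
        err = np.abs(marginal[5:-5] - expected[5:-5]) / expected[5:-5]
        assert err.max() < 0.02

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        n = 64
        z = scipy.signal.hilbert(rng.standard_normal(n))
        got = wvd(z, FS).values
        expected = brute_wvd(z, FS, lag_window_len=n - 1)
        assert np.abs(got - expected).max() < 1e-8

    def test_two_tone_cross_term_sits_midway(self):
        t = np.arange(N) / FS
        z = np.exp(2j * np.pi * 2 * t) + np.exp(2j * np.pi * 6 * t)
        w = wvd(z, FS)
        mid_bin = np.argmin(np.abs(w.freq_axis - 4.0))
        cross_col = w.values[:, mid_bin]
        # oscillating cross-term: large magnitude, near-zero time average
        assert np.abs(cross_col).mean() > 10 * abs(cross_col.mean())

    def test_even_lag_window_rejected(self):
        with pytest.raises(ConfigError):
            wvd(np.ones(32, dtype=complex), FS, lag_window_len=4)

    def test_output_is_real_with_full_energy(self, tone_wvd):
        assert np.isfinite(np.abs(tone_wvd.values).sum())
        assert tone_wvd.values.shape == (N, N)


class TestDirectionalKernel:
    @pytest.mark.parametrize("kind", ["smooth", "ridge"])
    def test_matches_direct_formula(self, kind):
        params = KernelParams(support_halfwidth=4)
        theta = 33.0
        hw = 4
        t = np.arange(-hw, hw + 1)[:, None]
        f = np.arange(-hw, hw + 1)[None, :]
        rad = np.deg2rad(theta)
        t_th = t * np.cos(rad) + f * np.sin(rad)
        f_th = f * np.cos(rad) - t * np.sin(rad)
        g = (
            params.a * params.b / (2 * np.pi)
            * np.exp(-params.a**2 * t_th**2 - params.b**2 * f_th**2)
        )
        if kind == "ridge":
            g = g * (1 - 2 * params.b**2 * f_th**2)
            g = g - g.mean()
            g = g / np.abs(g).sum()
        else:
            g = g * (1 - params.a**2 * t_th**2)
            g = g / g.sum()
        assert np.allclose(directional_kernel(theta, params, kind), g, atol=1e-12)

    def test_theta_zero_is_even_in_both_axes(self):
        g = directional_kernel(0.0, KernelParams(support_halfwidth=6))
        assert np.allclose(g, g[::-1, ::-1], atol=1e-12)

    def test_rotation_by_90_swaps_axes(self):
        params = KernelParams(support_halfwidth=4)
        g0 = directional_kernel(0.0, params)
        g90 = directional_kernel(90.0, params)
        assert np.allclose(g90, g0.T[:, ::-1], atol=1e-10)

    def test_smooth_kernel_has_unit_dc_gain(self):
        g = directional_kernel(45.0, KernelParams())
        assert abs(g.sum() - 1.0) < 1e-12

    def test_ridge_kernel_has_zero_dc_gain(self):
        g = directional_kernel(45.0, KernelParams(), kind="ridge")
        assert abs(g.sum()) < 1e-12

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(ConfigError):
            directional_kernel(180.0, KernelParams())


class TestDirectionMap:
    def test_tone_ridge_is_time_aligned(self, tone_wvd):
        dmap = direction_map(tone_wvd, KernelParams())
        mask = top_energy_mask(tone_wvd.values)
        ang = dmap.values[mask]
        assert np.mean((ang < 10) | (ang > 170)) >= 0.9

    def test_spike_ridge_is_frequency_aligned(self, spike_wvd):
        dmap = direction_map(spike_wvd, KernelParams())
        mask = top_energy_mask(spike_wvd.values)
        ang = dmap.values[mask]
        assert np.mean((ang > 80) & (ang < 100)) >= 0.9

    def test_flat_tfd_interior_breaks_ties_to_zero(self):
        params = KernelParams(support_halfwidth=10)
        n = 48
        flat = TimeFrequencyDistribution(
            np.full((n, n), 3.1), np.arange(n) / FS, np.arange(n) * FS / (2 * n), FS
        )
        dmap = direction_map(flat, params)
        assert np.all(dmap.values[10:-10, 10:-10] == 0.0)

    def test_matches_convolve2d_oracle(self):
        rng = np.random.default_rng(5)
        params = KernelParams(support_halfwidth=6, theta_step=15.0)
        vals = rng.standard_normal((40, 40))
        tfd = TimeFrequencyDistribution(
            vals, np.arange(40) / FS, np.arange(40) * FS / 80, FS
        )
        kernels = {
            a: np.asarray(directional_kernel(a, params, "ridge"))
            for a in params.theta_grid
        }
        expected = brute_direction_map(vals, kernels)
        got = direction_map(tfd, params).values
        agree = np.mean(got == expected)
        assert agree > 0.99  # FFT vs direct conv can flip exact ties

    def test_transpose_equivariance_on_ridge(self, tone_wvd):
        params = KernelParams()
        dmap = direction_map(tone_wvd, params)
        flipped = TimeFrequencyDistribution(
            tone_wvd.values.T,
            np.arange(tone_wvd.values.shape[1]) / FS,
            np.arange(tone_wvd.values.shape[0]) * FS / (2 * tone_wvd.values.shape[0]),
            FS,
        )
        dmap_t = direction_map(flipped, params)
        mask = top_energy_mask(tone_wvd.values)
        diff = np.mod(dmap_t.values.T + dmap.values - 90.0, 180.0)
        diff = np.minimum(diff, 180.0 - diff)
        assert np.quantile(diff[mask], 0.9) <= params.theta_step


class TestAdtfd:
    def test_zero_input_gives_zero_output(self):
        n = 64
        zero = TimeFrequencyDistribution(
            np.zeros((n, n)), np.arange(n) / FS, np.arange(n) * FS / (2 * n), FS
        )
        params = KernelParams(support_halfwidth=8)
        dmap = direction_map(zero, params)
        out = adtfd(zero, dmap, params)
        assert np.all(out.values == 0.0)

    def test_fixed_angle_equals_plain_convolution(self):
        rng = np.random.default_rng(2)
        n = 64
        params = KernelParams(support_halfwidth=6)
        vals = rng.standard_normal((n, n))
        tfd = TimeFrequencyDistribution(
            vals, np.arange(n) / FS, np.arange(n) * FS / (2 * n), FS
        )
        theta = 45.0
        dmap = DirectionMap(np.full((n, n), theta), params.theta_grid)
        out = adtfd(tfd, dmap, params).values
        expected = scipy.signal.convolve2d(
            vals, directional_kernel(theta, params), mode="same"
        )
        assert np.abs(out - expected).max() < 1e-10

    def test_cross_term_suppression_between_two_tones(self):
        t = np.arange(N) / FS
        x = SampledSignal(np.cos(2 * np.pi * 2 * t) + np.cos(2 * np.pi * 6 * t), FS)
        w = wvd(analytic_signal(x), FS)
        rho, _ = compute_adtfd(x, KernelParams())
        band = (w.freq_axis >= 3.5) & (w.freq_axis <= 4.5)
        ratio = np.abs(rho.values[:, band]).sum() / np.abs(w.values[:, band]).sum()
        assert ratio < 0.2

    def test_concentration_beats_isotropic_smoothing(self, tone_signal):
        params = KernelParams()
        rho, _ = compute_adtfd(tone_signal, params)
        w = wvd(analytic_signal(tone_signal), FS)
        # isotropic Gaussian of matched area: std = sqrt(major*minor stds)
        s_major = 1 / (params.a * np.sqrt(2))
        s_minor = 1 / (params.b * np.sqrt(2))
        sigma = np.sqrt(s_major * s_minor)
        smoothed = scipy.ndimage.gaussian_filter(w.values, sigma)

        def concentration(m):
            a = np.abs(m[:, :])
            cols = a[32:-32]  # interior rows (time)
            return np.mean(cols.max(axis=1) / np.maximum(cols.sum(axis=1), 1e-30))

        assert concentration(rho.values) >= concentration(smoothed)

    def test_energy_preserved_within_band_for_tone(self, tone_signal, tone_chain):
        rho, _ = tone_chain
        w = wvd(analytic_signal(tone_signal), FS)
        interior = np.s_[40:-40, :]
        # signed integrals: the TFD's total integral is the signal energy,
        # and unit-DC smoothing must preserve it on interior regions
        ratio = rho.values[interior].sum() / w.values[interior].sum()
        assert 0.5 <= ratio <= 1.5

    def test_shape_mismatch_rejected(self, tone_wvd):
        params = KernelParams()
        bad = DirectionMap(np.zeros((4, 4)), params.theta_grid)
        with pytest.raises(InvalidInputError):
            adtfd(tone_wvd, bad, params)


class TestComputeAdtfdGating:
    @staticmethod
    def gate_fractions(rho, dmap):
        e = np.abs(rho.values)
        tot = e.sum()
        spike_gate = (dmap.values > 80) & (dmap.values < 100)
        tone_gate = (dmap.values < 10) | (dmap.values > 170)
        return e[spike_gate].sum() / tot, e[tone_gate].sum() / tot

    def test_spike_train_energy_is_frequency_axis_aligned(self, spike_chain):
        spike_frac, _ = self.gate_fractions(*spike_chain)
        assert spike_frac >= 0.7

    def test_chirp_energy_is_time_axis_aligned(self, chirp_chain):
        _, tone_frac = self.gate_fractions(*chirp_chain)
        assert tone_frac >= 0.7

    def test_noise_energy_less_gate_aligned_than_seizure_models(
        self, spike_chain, chirp_chain
    ):
        spike_union = sum(self.gate_fractions(*spike_chain))
        chirp_union = sum(self.gate_fractions(*chirp_chain))
        noise_unions = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x = SampledSignal(rng.standard_normal(N), FS)
            rho, dmap = compute_adtfd(x, KernelParams())
            noise_unions.append(sum(self.gate_fractions(rho, dmap)))
        med = np.median(noise_unions)
        assert med < spike_union
        assert med < chirp_union
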