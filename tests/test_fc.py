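"""fc_observables: CSD, GIM/MIM/PLV, filters, BOLD, dFC, comparison stats."""

import numpy as np
import pytest

from ngnmm.fc import (
    DEFAULT_BANDS,
    Band,
    band_filter,
    bold_fc,
    bold_forward,
    compute_csd,
    get_band,
    gim,
    gim_matrix,
    mim,
    mim_matrix,
    pearson_distance,
    pearson_distance_vec,
    phase_dfc_bold,
    plv,
    rescale_unit,
    sf_clustering,
    sliding_dfc,
)
from ngnmm.params import BoldParameters


class TestBands:
    def test_default_band_table(self):
        assert len(DEFAULT_BANDS) == 8
        for b in DEFAULT_BANDS:
            assert b.f_low < b.f_high
        # non-overlapping except shared edges, in ascending order
        for a, b in zip(DEFAULT_BANDS, DEFAULT_BANDS[1:]):
            assert a.f_high <= b.f_low

    def test_get_band(self):
        assert get_band("alpha").f_low == 8.0
        with pytest.raises(KeyError):
            get_band("nosuchband")

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            Band("bad", 10.0, 5.0)


def _quadrature_signals(fs=250.0, T=30.0, noise=1e-3, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(T * fs)) / fs
    a = np.sin(2 * np.pi * 10.0 * t)
    b = np.sin(2 * np.pi * 10.0 * t - np.pi / 2)
    x = np.column_stack([a, b]) + noise * rng.standard_normal((t.size, 2))
    return x


class TestCSD:
    def test_identical_channels_have_zero_imaginary_part(self, rng):
        x = rng.standard_normal(2048)
        cs = compute_csd(np.column_stack([x, x]), fs=256.0)
        np.testing.assert_allclose(cs.csd[:, 0, 1].imag, 0.0, atol=1e-12)

    def test_hermitian(self, rng):
        x = rng.standard_normal((2048, 3))
        cs = compute_csd(x, fs=256.0)
        np.testing.assert_allclose(
            cs.csd, np.conj(np.swapaxes(cs.csd, 1, 2)), atol=1e-15
        )

    def test_quadrature_sinusoids_peak_imaginary(self):
        cs = compute_csd(_quadrature_signals(), fs=250.0)
        k = np.argmin(np.abs(cs.freqs - 10.0))
        cab = cs.csd[k, 0, 1]
        assert np.abs(cab) == pytest.approx(
            np.max(np.abs(cs.csd[:, 0, 1])), rel=1e-12
        )
        assert abs(cab.imag) > 10 * abs(cab.real)

    def test_autospectrum_integrates_to_variance(self, rng):
        # Welch with Hann taper: one-sided density integrates to signal power
        x = rng.standard_normal((8192, 1))
        cs = compute_csd(x, fs=256.0)
        df = cs.freqs[1] - cs.freqs[0]
        power = float(np.sum(cs.csd[:, 0, 0].real) * df)
        assert power == pytest.approx(1.0, rel=0.1)

    def test_independent_noise_coherence_bias(self, rng):
        # mean |c_AB|^2/(c_AA c_BB) ~ 1/n_windows for independent channels
        x = rng.standard_normal((60 * 128, 2))
        cs = compute_csd(x, fs=128.0)
        coh = (np.abs(cs.csd[:, 0, 1]) ** 2
               / (cs.csd[:, 0, 0].real * cs.csd[:, 1, 1].real))
        assert np.mean(coh) == pytest.approx(1.0 / cs.n_windows, rel=0.25)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            compute_csd(np.zeros((100, 2)), fs=256.0)


class TestGIM:
    def test_identical_signals_zero(self, rng):
        x = rng.standard_normal(4096)
        cs = compute_csd(np.column_stack([x, x]), fs=256.0)
        assert gim(cs, (0, 1)) == pytest.approx(0.0, abs=1e-20)

    def test_quadrature_peak(self):
        cs = compute_csd(_quadrature_signals(), fs=250.0)
        at_peak = gim(cs, (0, 1), freq=10.0)
        away = gim(cs, (0, 1), freq=60.0)
        assert at_peak > 0.9
        assert away < 0.1

    def test_bounded_by_one(self, rng):
        x = rng.standard_normal((4096, 4))
        x[:, 1] += 0.9 * x[:, 0]  # strongly correlated pair
        cs = compute_csd(x, fs=256.0)
        m = gim_matrix(cs)
        assert np.all(m.values <= 1.0 + 1e-12) and np.all(m.values >= 0.0)
        assert np.all(np.diag(m.values) == 0)

    def test_gim_at_least_imaginary_coherence(self, rng):
        # GIM >= (c^I)^2/(c_AA c_BB), equality iff c^R = 0
        x = rng.standard_normal((4096, 2))
        x[:, 1] = 0.5 * x[:, 1] + 0.5 * np.roll(x[:, 0], 3)
        cs = compute_csd(x, fs=256.0)
        caa = cs.csd[:, 0, 0].real
        cbb = cs.csd[:, 1, 1].real
        cab = cs.csd[:, 0, 1]
        icoh = float(np.mean(cab.imag**2 / (caa * cbb)))
        assert gim(cs, (0, 1)) >= icoh - 1e-15


class TestMIM:
    def test_one_component_identity_with_gim(self, rng):
        # MIM = GIM * (1 - (c^R)^2/(c_AA c_BB)) frequency-wise; holds after
        # band averaging only when compared bin by bin, so use freq queries
        x = rng.standard_normal((4096, 2))
        x[:, 1] = 0.6 * x[:, 1] + 0.4 * np.roll(x[:, 0], 2)
        cs = compute_csd(x, fs=256.0)
        caa = cs.csd[:, 0, 0].real
        cbb = cs.csd[:, 1, 1].real
        cab = cs.csd[:, 0, 1]
        from ngnmm.fc import _gim_freqwise

        gim_f = _gim_freqwise(caa, cbb, cab)
        mim_f = np.array([mim(cs, (0, 1), freq=f) for f in cs.freqs[1:20]])
        expect = gim_f[1:20] * (1.0 - cab.real[1:20] ** 2
                                / (caa[1:20] * cbb[1:20]))
        np.testing.assert_allclose(mim_f, expect, rtol=1e-12, atol=1e-15)

    def test_multicomponent_runs_and_is_nonnegative(self, rng):
        x = rng.standard_normal((4096, 2, 3))  # 2 channels, 3 components
        cs = compute_csd(x, fs=256.0)
        m = mim_matrix(cs)
        assert m.values.shape == (2, 2)
        assert np.all(m.values >= 0)


class TestPLV:
    def test_locked_is_one(self, rng):
        base = rng.uniform(-np.pi, np.pi, 5000)
        ph = np.column_stack([base, base + 0.7, base - 1.2])
        m = plv(ph)
        np.testing.assert_allclose(m.values, 1.0, atol=1e-12)

    def test_independent_is_small(self, rng):
        ph = rng.uniform(-np.pi, np.pi, (20000, 2))
        m = plv(ph)
        assert m.values[0, 1] < 0.05
        assert m.values[0, 0] == 1.0


class TestFilter:
    def test_passband_preserved_stopband_removed(self):
        fs = 256.0
        t = np.arange(int(20 * fs)) / fs
        band = get_band("alpha")  # 8-13 Hz
        inband = np.sin(2 * np.pi * 10.0 * t)
        outband = np.sin(2 * np.pi * 40.0 * t)
        y = band_filter((inband + outband)[:, None], band, fs)[:, 0]
        core = slice(int(2 * fs), int(18 * fs))  # ignore filter edges
        resid_in = np.sqrt(np.mean((y[core] - inband[core]) ** 2))
        assert resid_in < 0.05  # in-band kept, 40 Hz removed
        assert np.sqrt(np.mean(y[core] ** 2)) == pytest.approx(
            np.sqrt(0.5), rel=0.05
        )

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            band_filter(np.zeros((100, 1)), get_band("gamma3"), fs=100.0)


class TestBold:
    def test_rest_is_a_fixed_point(self):
        b, states = bold_forward(np.zeros(200), dt=0.05, return_states=True)
        np.testing.assert_allclose(states[-1], [0.0, 1.0, 1.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(b, 0.0, atol=1e-12)

    def test_constant_drive_steady_state(self):
        # analytic fixed point at S = 0.5: x = 0, f = 1 + S/gamma,
        # v = f^alpha, q = f^alpha (1 - (1-rho)^(1/f)) / rho
        p = BoldParameters()
        S = 0.5
        f = 1.0 + S / p.gamma
        v = f**p.alpha_grubb
        q = v * (1.0 - (1.0 - p.rho) ** (1.0 / f)) / p.rho
        assert f == pytest.approx(2.2195, abs=2e-4)
        assert v == pytest.approx(1.2906, abs=2e-4)
        assert q == pytest.approx(0.6481, abs=2e-4)
        _, states = bold_forward(
            np.full(2400, S), dt=0.05, params=p, return_states=True
        )
        np.testing.assert_allclose(states[-1], [0.0, f, v, q], atol=1e-6)

    def test_positivity_along_physiological_trajectories(self, rng):
        drive = 0.2 + 0.1 * rng.standard_normal((2000, 3))
        _, states = bold_forward(drive, dt=0.05, return_states=True)
        assert np.all(states[:, :, 1:] > 0)

    def test_bold_fc_unit_diagonal(self, rng):
        b = rng.standard_normal((500, 4))
        m = bold_fc(b)
        np.testing.assert_allclose(np.diag(m.values), 1.0, atol=1e-12)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)


class TestDynamicFC:
    def test_sliding_window_count(self, rng):
        fs = 100.0
        x = rng.standard_normal((int(30 * fs), 3))
        mats = sliding_dfc(x, fs, get_band("alpha"))
        # floor((T - win)/step) + 1 = floor((3000-1000)/100) + 1
        assert len(mats) == 21
        assert mats[0].values.shape == (3, 3)

    def test_overlap_validation(self, rng):
        with pytest.raises(ValueError):
            sliding_dfc(np.zeros((1000, 2)), 100.0, get_band("alpha"),
                        window_s=5.0, overlap_s=5.0)

    def test_phase_dfc_constant_offsets_recur(self):
        t = np.linspace(0, 20, 400)
        x = np.column_stack([
            np.sin(2 * np.pi * 0.25 * t),
            np.sin(2 * np.pi * 0.25 * t - 0.8),
            np.sin(2 * np.pi * 0.25 * t + 1.3),
        ])
        dfc, lead, ac_lead, ac_ut = phase_dfc_bold(x)
        assert dfc.shape == (400, 3, 3)
        np.testing.assert_allclose(np.diagonal(dfc, axis1=1, axis2=2), 1.0,
                                   atol=1e-12)
        # constant phase offsets: the pattern recurs at all times
        core = ac_lead[50:-50, 50:-50]
        assert np.min(core) > 0.97

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            phase_dfc_bold(np.ones((100, 2)))


class TestComparison:
    def test_distance_to_self_is_zero(self, rng):
        m = rng.standard_normal((6, 6))
        m = m + m.T
        assert pearson_distance(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_formula(self, rng):
        x = rng.standard_normal(50)
        y = 0.3 * x + rng.standard_normal(50)
        r = np.corrcoef(x, y)[0, 1]
        expect = 1.0 - (r - (y.mean() - x.mean()) ** 2)
        assert pearson_distance_vec(x, y) == pytest.approx(expect, rel=1e-12)

    def test_constant_target_is_named_failure(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_distance_vec(np.ones(10), np.arange(10.0))

    def test_rescale_unit(self, rng):
        m = rng.uniform(-3, 5, (5, 5))
        u = rescale_unit(m)
        off = ~np.eye(5, dtype=bool)
        assert u[off].min() == pytest.approx(0.0)
        assert u[off].max() == pytest.approx(1.0)
        assert np.all(np.diag(u) == 0)


class TestSFClustering:
    def test_brute_force_enumeration(self, rng):
        n = 5
        w1 = rescale_unit(rng.uniform(0, 1, (n, n)))
        w2 = rescale_unit(rng.uniform(0, 1, (n, n)))
        c, cbar = sf_clustering(w1, w2)
        for i in range(n):
            num = den = 0.0
            for j in range(n):
                for k in range(n):
                    if j == k:
                        continue
                    num += w1[i, j] * w2[j, k] * (1 - w1[j, k]) * w1[k, i]
                    den += w1[i, j] * (1 - w1[j, k]) * w1[k, i]
            assert c[i] == pytest.approx(num / den, rel=1e-12)
        assert cbar == pytest.approx(np.nanmean(c), rel=1e-12)

    def test_unit_functional_layer_gives_one(self, rng):
        n = 6
        w1 = rescale_unit(rng.uniform(0, 1, (n, n)))
        c, cbar = sf_clustering(w1, np.ones((n, n)) - np.eye(n))
        np.testing.assert_allclose(c[np.isfinite(c)], 1.0, atol=1e-12)

    def test_bounds(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            w1 = rescale_unit(r.uniform(0, 1, (7, 7)))
            w2 = rescale_unit(r.uniform(0, 1, (7, 7)))
            c, _ = sf_clustering(w1, w2)
            fin = c[np.isfinite(c)]
            assert np.all(fin >= -1e-12) and np.all(fin <= 1 + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sf_clustering(2 * np.ones((3, 3)), np.zeros((3, 3)))

    def test_isolated_node_is_nan(self):
        # triangle on nodes 0-2, node 3 structurally disconnected
        w1 = np.zeros((4, 4))
        for i, j in ((0, 1), (1, 2), (0, 2)):
            w1[i, j] = w1[j, i] = 0.5
        w2 = 0.5 * (np.ones((4, 4)) - np.eye(4))
        c, cbar = sf_clustering(w1, w2)
        assert np.isnan(c[3])
        assert np.all(np.isfinite(c[:3]))
        assert np.isfinite(cbar)
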