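"""Adaptive Hann-taper TFR: oracle equivalence, scaling, baselining, banding."""

import numpy as np
import pytest

from alphalat import TFRConfig, band_average, baseline_relative, compute_power
from alphalat.tfr import _window_samples
from conftest import make_epochs

SRATE = 256.0


def dft_projection_oracle(x, times, srate, freq, n_cycles, centers):
    """Independent single-point oracle: |Hann-windowed DFT coefficient|^2.

    Computed sample-by-sample from the definition, with the same
    normalization convention (unit-amplitude sinusoid -> power 1).
    """
    L = _window_samples(freq, n_cycles, srate)
    half = L // 2
    w = np.hanning(L)
    out = {}
    for c in centers:
        seg = x[c - half : c + half + 1]
        coef = 0.0 + 0.0j
        for m in range(L):
            coef += w[m] * seg[m] * np.exp(-2j * np.pi * freq * (m - half) / srate)
        out[c] = (2.0 * abs(coef) / w.sum()) ** 2
    return out


def test_pure_tone_peaks_at_its_frequency():
    t = np.arange(-1.0, 1.0, 1 / SRATE)
    x = np.sin(2 * np.pi * 10 * t)
    ep = make_epochs(x[None, None, :], srate=SRATE, t0=-1.0)
    pm = compute_power(ep, TFRConfig(freqs=np.arange(4.0, 21.0), time_step=0.05))
    v = pm.values[0, 0]
    interior = np.isfinite(v).all(axis=0)
    assert interior.sum() > 10
    peaks = pm.freqs[np.argmax(v[:, interior], axis=0)]
    assert (peaks == 10.0).all()
    assert np.allclose(v[pm.freqs == 10.0, interior], 1.0, atol=0.01)


def test_zero_signal_gives_zero_power():
    ep = make_epochs(np.zeros((2, 3, 512)), srate=SRATE)
    pm = compute_power(ep, TFRConfig(freqs=np.array([5.0, 10.0])))
    assert np.nanmax(pm.values) == 0.0


def test_matches_dft_projection_oracle():
    rng = np.random.default_rng(7)
    t = np.arange(0, 2.0, 1 / SRATE)
    x = np.sin(2 * np.pi * 10 * t) + 0.3 * rng.standard_normal(t.size)
    ep = make_epochs(x[None, None, :], srate=SRATE)
    cfg = TFRConfig(freqs=np.array([6.0, 10.0]), time_step=0.1)
    pm = compute_power(ep, cfg)
    step = int(round(0.1 * SRATE))
    for fi, f in enumerate(cfg.freqs):
        defined = np.flatnonzero(np.isfinite(pm.values[0, 0, fi]))
        centers = [int(k * step) for k in defined[:5]]
        oracle = dft_projection_oracle(x, t, SRATE, f, 3.0, centers)
        for k, c in zip(defined[:5], centers):
            assert pm.values[0, 0, fi, k] == pytest.approx(oracle[c], rel=1e-8)


def test_amplitude_scaling_is_quadratic():
    t = np.arange(0, 2.0, 1 / SRATE)
    rng = np.random.default_rng(0)
    x = rng.standard_normal(t.size)
    cfg = TFRConfig(freqs=np.array([8.0, 12.0]))
    p1 = compute_power(make_epochs(x[None, None, :], srate=SRATE), cfg)
    p3 = compute_power(make_epochs(3.0 * x[None, None, :], srate=SRATE), cfg)
    d = np.isfinite(p1.values)
    assert np.allclose(p3.values[d], 9.0 * p1.values[d], rtol=1e-8)


def test_time_shift_covariance():
    # Shifting a burst shifts its power ridge by the same amount.
    t = np.arange(0, 4.0, 1 / SRATE)
    cfg = TFRConfig(freqs=np.array([10.0]), time_step=1 / SRATE)

    def burst_peak(center):
        env = np.exp(-0.5 * ((t - center) / 0.15) ** 2)
        x = env * np.sin(2 * np.pi * 10 * t)
        pm = compute_power(make_epochs(x[None, None, :], srate=SRATE), cfg)
        v = pm.values[0, 0, 0]
        return pm.times[np.nanargmax(v)]

    shift = 64 / SRATE
    assert burst_peak(2.0 + shift) - burst_peak(2.0) == pytest.approx(shift, abs=1.5 / SRATE)


def test_two_tones_resolved_beyond_rayleigh():
    # Tones separated by more than 2/(window length) Hz give distinct ridges.
    t = np.arange(0, 3.0, 1 / SRATE)
    x = np.sin(2 * np.pi * 8 * t) + np.sin(2 * np.pi * 16 * t)
    cfg = TFRConfig(freqs=np.arange(5.0, 20.0))
    pm = compute_power(make_epochs(x[None, None, :], srate=SRATE), cfg)
    v = np.nanmean(pm.values[0, 0], axis=1)
    f8, f16 = np.flatnonzero(pm.freqs == 8)[0], np.flatnonzero(pm.freqs == 16)[0]
    f12 = np.flatnonzero(pm.freqs == 12)[0]
    # Two distinct ridges with a dip in between (resolution at three-cycle
    # windows is frequency dependent, so only a qualitative dip is expected).
    assert v[f8] > 1.5 * v[f12] and v[f16] > 1.5 * v[f12]
    assert v[f8] > v[f8 - 1] and v[f16] > v[f16 + 1]


def test_edges_are_masked():
    ep = make_epochs(np.ones((1, 1, 512)), srate=SRATE)
    pm = compute_power(ep, TFRConfig(freqs=np.array([4.0]), time_step=0.05))
    L = _window_samples(4.0, 3.0, SRATE)
    half_t = (L // 2) / SRATE
    v = pm.values[0, 0, 0]
    assert np.isnan(v[pm.times < pm.times[0] + half_t - 1e-9]).all()
    assert np.isfinite(v[(pm.times > pm.times[0] + half_t + 0.05) & (pm.times < pm.times[-1] - half_t - 0.05)]).all()


def test_too_low_frequency_fully_masked():
    ep = make_epochs(np.ones((1, 1, 256)), srate=SRATE)
    with pytest.warns(UserWarning):
        pm = compute_power(ep, TFRConfig(freqs=np.array([1.0, 10.0])))
    assert np.isnan(pm.values[:, :, 0]).all()
    assert np.isfinite(pm.values[:, :, 1]).any()


class TestBaseline:
    def test_stationary_signal_centers_on_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((60, 2, 1024))
        ep = make_epochs(x, srate=SRATE)
        pm = compute_power(ep, TFRConfig(freqs=np.array([10.0])))
        rel = baseline_relative(pm, (0.5, 1.0))
        post = rel.values[..., rel.times > 2.0]
        m = np.nanmean(post)
        se = np.nanstd(np.nanmean(post, axis=(1, 2, 3))) / np.sqrt(x.shape[0])
        assert abs(m) < 3 * se + 0.05

    def test_power_doubling_gives_relative_change_one(self):
        # Amplitude x sqrt(2) after t=2 doubles power: relative change -> 1.
        t = np.arange(0, 4.0, 1 / SRATE)
        x = np.sin(2 * np.pi * 10 * t) * np.where(t < 2.0, 1.0, np.sqrt(2.0))
        pm = compute_power(make_epochs(x[None, None, :], srate=SRATE),
                           TFRConfig(freqs=np.array([10.0])))
        rel = baseline_relative(pm, (0.5, 1.5))
        late = rel.values[0, 0, 0, (rel.times > 2.5) & (rel.times < 3.5)]
        assert np.allclose(late, 1.0, atol=0.02)

    def test_per_group_normalization(self):
        t = np.arange(0, 2.0, 1 / SRATE)
        x = np.stack([np.sin(2 * np.pi * 10 * t), 2 * np.sin(2 * np.pi * 10 * t)])
        pm = compute_power(make_epochs(x[:, None, :], srate=SRATE),
                           TFRConfig(freqs=np.array([10.0])))
        rel = baseline_relative(pm, (0.5, 1.5), groups=np.array([0, 1]))
        assert np.nanmax(np.abs(rel.values)) < 0.02  # each trial its own unit

    def test_baseline_on_masked_region_rejected(self):
        ep = make_epochs(np.ones((1, 1, 512)), srate=SRATE)
        pm = compute_power(ep, TFRConfig(freqs=np.array([8.0])))
        with pytest.raises(ValueError):
            baseline_relative(pm, (0.0, 0.05))

    def test_zero_baseline_power_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 512)), srate=SRATE)
        pm = compute_power(ep, TFRConfig(freqs=np.array([10.0])))
        with pytest.raises(ValueError, match="zero baseline"):
            baseline_relative(pm, (0.8, 1.2))


class TestBandAverage:
    def test_closed_band_mean(self):
        rng = np.random.default_rng(2)
        ep = make_epochs(rng.standard_normal((3, 2, 512)), srate=SRATE)
        pm = compute_power(ep, TFRConfig(freqs=np.arange(8.0, 13.0)))
        ba = band_average(pm, (8, 12))
        d = np.isfinite(pm.values).all(axis=2)
        assert np.allclose(ba.values[d], pm.values.mean(axis=2)[d])

    def test_theta_band_three_frequencies(self):
        rng = np.random.default_rng(3)
        ep = make_epochs(rng.standard_normal((2, 1, 1024)), srate=SRATE)
        pm = compute_power(ep, TFRConfig(freqs=np.arange(3.0, 8.0)))
        ba = band_average(pm, (4, 6))
        sel = (pm.freqs >= 4) & (pm.freqs <= 6)
        assert sel.sum() == 3
        d = np.isfinite(pm.values[:, :, sel]).all(axis=2)
        assert np.allclose(ba.values[d], pm.values[:, :, sel].mean(axis=2)[d])

    def test_single_frequency_identity_and_empty_band(self):
        rng = np.random.default_rng(4)
        ep = make_epochs(rng.standard_normal((2, 1, 512)), srate=SRATE)
        pm = compute_power(ep, TFRConfig(freqs=np.array([10.0])))
        ba = band_average(pm, (9.5, 10.5))
        assert np.allclose(ba.values, pm.values[:, :, 0], equal_nan=True)
        with pytest.raises(ValueError):
            band_average(pm, (20, 25))
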