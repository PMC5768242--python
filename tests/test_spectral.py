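"""Welch PSD, spectrogram, beta-peak detection and normalized beta."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dirlfp.lead import default_lead
from dirlfp.simulate import SimulationConfig, simulate_hemisphere_lfp
from dirlfp.spectral import (
    BetaPeak,
    ContactSpectrum,
    LfpRecording,
    band_power,
    compute_psd,
    compute_spectrogram,
    detect_beta_peak,
    fit_one_over_f,
    hemisphere_beta_profile,
    normalized_beta,
)


def recording(x, fs=250.0, cid=2):
    return LfpRecording((cid,), np.atleast_2d(x), fs)


def brute_force_peak(spec, band=(13.0, 35.0), prominence_db=3.0):
    """Independent oracle: scan every interior bin of the background-
    subtracted spectrum for the most elevated local maximum."""
    bg = fit_one_over_f(spec)
    best = None
    for i in range(1, len(spec.freqs) - 1):
        f, p = spec.freqs[i], spec.psd[i]
        if not band[0] <= f <= band[1]:
            continue
        if not (p > spec.psd[i - 1] and p >= spec.psd[i + 1]):
            continue
        if not np.isfinite(bg[i]) or bg[i] <= 0 or p <= 0:
            continue
        excess = 10 * np.log10(p / bg[i])
        if excess >= prominence_db and (best is None or excess > best[0]):
            best = (excess, f)
    return best  # None or (excess_db, freq)


# ---------------------------------------------------------------- PSD


def test_sine_psd_concentrates_power():
    """A 20 Hz sine of amplitude a carries integrated PSD ~ a^2/2 = its
    variance, concentrated in the 20 Hz bin."""
    fs, a = 250.0, 3.0
    t = np.arange(0, 120.0, 1 / fs)
    x = a * np.sin(2 * np.pi * 20.0 * t)
    spec = compute_psd(recording(x, fs), win_s=1.0, overlap=0.5)[2]
    total = band_power(spec.freqs, spec.psd, 0.5, fs / 2 - 1)
    assert total == pytest.approx(np.var(x), rel=0.05)  # oracle: direct variance
    assert spec.freqs[np.argmax(spec.psd)] == pytest.approx(20.0, abs=1.0)
    # mass outside the peak bin is negligible
    inside = band_power(spec.freqs, spec.psd, 18.0, 22.0)
    assert inside / total > 0.99


def test_zero_signal_zero_psd():
    spec = compute_psd(recording(np.zeros(2500)), win_s=1.0)[2]
    assert np.all(spec.psd == 0.0)


def test_white_noise_parseval(rng):
    sigma = 2.5
    x = rng.normal(0, sigma, 50_000)
    spec = compute_psd(recording(x), win_s=1.0, overlap=0.5)[2]
    total = np.trapezoid(spec.psd, spec.freqs)
    assert total == pytest.approx(x.var(), rel=0.05)


def test_psd_input_validation(rng):
    x = rng.normal(size=1000)
    with pytest.raises(ValueError, match="shorter than one"):
        compute_psd(recording(x[:100]), win_s=1.0)  # 250-sample window
    with pytest.raises(ValueError, match="overlap"):
        compute_psd(recording(x), win_s=1.0, overlap=1.0)
    bad = x.copy()
    bad[7] = np.nan
    with pytest.raises(ValueError, match="channel 2"):
        compute_psd(recording(bad), win_s=1.0)


# ---------------------------------------------------------- spectrogram


def test_spectrogram_stationary_sine_and_zero():
    fs = 250.0
    t = np.arange(0, 30.0, 1 / fs)
    x = np.sin(2 * np.pi * 20.0 * t)
    freqs, times, sxx = compute_spectrogram(recording(x, fs), 1.0, 0.5)[2]
    peak_bins = freqs[np.argmax(sxx, axis=0)]
    assert np.all(peak_bins == peak_bins[0])  # same peak bin in every slice
    assert abs(peak_bins[0] - 20.0) <= 1.0
    _, _, zz = compute_spectrogram(recording(np.zeros_like(x), fs), 1.0, 0.5)[2]
    assert np.all(zz == 0.0)


def test_spectrogram_amplitude_step():
    """Beta power in the on-half exceeds the off-half by the step ratio."""
    fs = 250.0
    t = np.arange(0, 60.0, 1 / fs)
    amp = np.where(t < 30.0, 1.0, 3.0)
    x = amp * np.sin(2 * np.pi * 20.0 * t)
    freqs, times, sxx = compute_spectrogram(recording(x, fs), 1.0, 1.0)[2]
    beta = (freqs >= 13) & (freqs <= 35)
    first = sxx[beta][:, times < 29].mean()
    second = sxx[beta][:, times > 31].mean()
    assert second / first == pytest.approx(9.0, rel=0.05)  # 3^2 in power


def test_spectrogram_time_average_matches_psd(rng):
    x = rng.normal(size=20_000)
    rec = recording(x)
    freqs, _, sxx = compute_spectrogram(rec, 1.0, 0.5)[2]
    spec = compute_psd(rec, win_s=1.0, overlap=0.5)[2]
    assert np.allclose(sxx.mean(axis=1), spec.psd, rtol=0.15, atol=1e-12)


# --------------------------------------------------------- peak detection


def one_over_f_spectrum(freqs, scale=10.0, exponent=1.5):
    psd = np.zeros_like(freqs)
    psd[freqs > 0] = scale / freqs[freqs > 0] ** exponent
    return psd


def gaussian_bump(freqs, center, height, width=2.0):
    return height * np.exp(-0.5 * ((freqs - center) / width) ** 2)


def test_monotone_spectrum_has_no_peak():
    freqs = np.arange(0.0, 126.0)
    spec = ContactSpectrum(2, freqs, one_over_f_spectrum(freqs))
    assert not detect_beta_peak(spec).present


def test_single_bump_detected_at_center():
    freqs = np.arange(0.0, 126.0)
    psd = one_over_f_spectrum(freqs)
    psd += gaussian_bump(freqs, 20.0, 5.0)
    spec = ContactSpectrum(2, freqs, psd)
    peak = detect_beta_peak(spec)
    assert peak.present
    assert abs(peak.peak_freq - 20.0) <= 1.0  # within one frequency bin
    assert peak.classification == "low"
    oracle = brute_force_peak(spec)
    assert oracle is not None and peak.peak_freq == oracle[1]


def test_two_bumps_most_prominent_wins():
    freqs = np.arange(0.0, 126.0)
    psd = one_over_f_spectrum(freqs)
    psd += gaussian_bump(freqs, 16.0, 1.0) + gaussian_bump(freqs, 28.0, 4.0)
    peak = detect_beta_peak(ContactSpectrum(2, freqs, psd))
    assert peak.present and abs(peak.peak_freq - 28.0) <= 1.0
    assert peak.classification == "high"
    assert peak.peak_band == (25.0, 31.0)


def test_peak_band_clipped_to_beta_band():
    freqs = np.arange(0.0, 126.0)
    psd = one_over_f_spectrum(freqs) + gaussian_bump(freqs, 34.0, 5.0)
    peak = detect_beta_peak(ContactSpectrum(2, freqs, psd))
    assert peak.present and peak.peak_band[1] == 35.0


def test_band_outside_support_rejected():
    freqs = np.arange(0.0, 20.0)
    with pytest.raises(ValueError, match="support"):
        detect_beta_peak(ContactSpectrum(2, freqs, one_over_f_spectrum(freqs)))


# ------------------------------------------------------- normalized beta


def flat_spectrum(value=1.0):
    freqs = np.arange(0.0, 126.0)
    return ContactSpectrum(2, freqs, np.full_like(freqs, value))


def test_flat_spectrum_bandwidth_ratios():
    present = BetaPeak(True, 20.0, (17.0, 23.0))
    nb = normalized_beta(flat_spectrum(), present)
    assert nb.value == pytest.approx(6.0 / 22.0)
    assert not nb.used_fallback
    absent = BetaPeak(False)
    nb2 = normalized_beta(flat_spectrum(), absent)
    assert nb2.value == pytest.approx(7.0 / 22.0)  # 13-20 Hz fallback
    assert nb2.used_fallback


def test_all_power_in_peak_band_gives_one():
    freqs = np.arange(0.0, 126.0)
    psd = np.where((freqs >= 18) & (freqs <= 22), 4.0, 0.0)
    nb = normalized_beta(ContactSpectrum(2, freqs, psd),
                         BetaPeak(True, 20.0, (17.0, 23.0)))
    assert nb.value == pytest.approx(1.0)


def test_zero_denominator_rejected():
    freqs = np.arange(0.0, 126.0)
    spec = ContactSpectrum(2, freqs, np.zeros_like(freqs))
    with pytest.raises(ValueError, match="zero power"):
        normalized_beta(spec, BetaPeak(False))


def test_amplitude_statistic_is_sqrt_of_power_ratio():
    peak = BetaPeak(True, 20.0, (17.0, 23.0))
    p = normalized_beta(flat_spectrum(), peak, statistic="power").value
    a = normalized_beta(flat_spectrum(), peak, statistic="amplitude").value
    assert a == pytest.approx(np.sqrt(p))


@given(st.floats(0.1, 50.0))
def test_normalized_beta_invariant_to_global_gain(gain):
    freqs = np.arange(0.0, 126.0)
    base = one_over_f_spectrum(freqs) + gaussian_bump(freqs, 22.0, 3.0)
    peak = BetaPeak(True, 22.0, (19.0, 25.0))
    v1 = normalized_beta(ContactSpectrum(2, freqs, base), peak).value
    v2 = normalized_beta(ContactSpectrum(2, freqs, gain * base), peak).value
    assert v2 == pytest.approx(v1, rel=1e-9)
    assert 0.0 <= v1 <= 1.0


# -------------------------------------------------- hemisphere profile


def test_identical_channels_equal_values(rng, lead):
    x = rng.normal(size=30_000)
    rec = LfpRecording(lead.segmented_ids, np.tile(x, (6, 1)), 250.0)
    profile, _ = hemisphere_beta_profile(rec, lead)
    values = {nb.value for nb in profile.values()}
    assert len(values) == 1


def test_source_at_contact5_dominates(lead):
    """Source aligned with contact 5: it wins, and its aligned partner
    (contact 2) leads the level-2 segments."""
    cfg = SimulationConfig(
        duration_s=60.0, fs=250.0, source_angle_deg=0.0, source_level=3.0,
        beta_freq=22.0, one_over_f_scale=0.5, noise_floor=0.005,
        peak_prob=1.0, seed=42,
    )
    rec, truth = simulate_hemisphere_lfp(cfg, np.random.default_rng(42), lead)
    profile, peak = hemisphere_beta_profile(rec, lead)
    assert peak.present
    order = sorted(profile, key=lambda c: -profile[c].value)
    assert order[0] == 5
    level2 = [c for c in order if lead.contact(c).level == 2]
    assert level2[0] == 2  # aligned partner leads its level
    assert truth.best_efficacy_contact == 5


def test_pure_noise_uses_fallback_everywhere(rng, lead):
    rows = rng.normal(size=(6, 30_000))
    rec = LfpRecording(lead.segmented_ids, rows, 250.0)
    profile, peak = hemisphere_beta_profile(rec, lead)
    assert not peak.present
    assert all(nb.used_fallback for nb in profile.values())


def test_missing_channel_reported(rng, lead):
    rec = LfpRecording((2, 3, 4, 5, 6), rng.normal(size=(5, 1000)), 250.0)
    with pytest.raises(ValueError, match=r"\[7\]"):
        hemisphere_beta_profile(rec, lead)
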