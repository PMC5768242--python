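"""Spectral estimation and the normalized-beta statistic.

Per segmented contact the pipeline estimates a Welch power spectrum,
detects (or fails to detect) a beta-band (13-35 Hz) peak standing above a
fitted 1/f background, and summarises each contact by *normalized beta*:
integrated power in the peak band divided by integrated power in the whole
beta band.  When no peak exists the numerator falls back to the low beta
band (13-20 Hz).  Because the statistic is a within-contact power ratio it
is invariant to global gain, which is what makes contacts comparable on a
single lead.

The peak decision is made once per hemisphere -- on the contact with the
largest raw beta power -- and its band reused for all six contacts, so that
the six values share a numerator band and differ only in how beta power is
distributed across directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .lead import DirectionalLead

logger = logging.getLogger(__name__)

BETA_BAND: tuple[float, float] = (13.0, 35.0)
LOW_BETA_BAND: tuple[float, float] = (13.0, 20.0)
LOW_HIGH_SPLIT_HZ: float = 20.0
#: band used to fit the aperiodic 1/f background, excluding the beta band
BACKGROUND_FIT_BAND: tuple[float, float] = (5.0, 45.0)

__all__ = [
    "BETA_BAND",
    "LOW_BETA_BAND",
    "LfpRecording",
    "ContactSpectrum",
    "BetaPeak",
    "NormalizedBeta",
    "compute_psd",
    "compute_spectrogram",
    "fit_one_over_f",
    "detect_beta_peak",
    "band_power",
    "normalized_beta",
    "hemisphere_beta_profile",
]


@dataclass
class LfpRecording:
    """Multichannel LFP time series, one channel per contact.

    samples are in microvolts, shape ``(n_channels, n_samples)``; ``fs`` in
    Hz.  The beta band must be resolvable, so ``fs > 70``.
    """

    channel_ids: tuple[int, ...]
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_ids = tuple(int(i) for i in self.channel_ids)
        if self.samples.shape[0] != len(self.channel_ids):
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[0]} sample rows"
            )
        if not self.fs > 70.0:
            raise ValueError(f"fs={self.fs} Hz too low to resolve the beta band")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel(self, contact_id: int) -> np.ndarray:
        return self.samples[self.channel_ids.index(contact_id)]

    def validate(self, min_duration_s: float = 60.0) -> None:
        """Raise if the recording is unusable for a hemisphere analysis."""
        if self.duration_s < min_duration_s:
            raise ValueError(
                f"recording of {self.duration_s:.1f} s shorter than the "
                f"required minimum {min_duration_s:.0f} s"
            )
        for cid in self.channel_ids:
            if np.isnan(self.channel(cid)).any():
                raise ValueError(f"NaN samples in channel {cid}")


@dataclass
class ContactSpectrum:
    """One-sided power spectral density for one contact (uV^2/Hz)."""

    contact_id: int
    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.shape != self.psd.shape:
            raise ValueError("freqs and psd must have equal shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValueError("psd must be nonnegative")


@dataclass(frozen=True)
class BetaPeak:
    """Outcome of the beta-peak search on one spectrum."""

    present: bool
    peak_freq: float | None = None
    peak_band: tuple[float, float] = LOW_BETA_BAND
    prominence_db: float | None = None

    @property
    def classification(self) -> str | None:
        """"low" for peaks at or below 20 Hz, "high" above; None if absent."""
        if not self.present:
            return None
        return "low" if self.peak_freq <= LOW_HIGH_SPLIT_HZ else "high"


@dataclass(frozen=True)
class NormalizedBeta:
    contact_id: int
    value: float
    used_fallback: bool
    peak_band: tuple[float, float]


def _nan_check(rec: LfpRecording) -> None:
    for cid in rec.channel_ids:
        if np.isnan(rec.channel(cid)).any():
            raise ValueError(f"NaN samples in channel {cid}")


def compute_psd(
    rec: LfpRecording, win_s: float = 1.0, overlap: float = 0.5
) -> dict[int, ContactSpectrum]:
    """Welch power spectral density per channel (Hann taper).

    ``win_s`` sets the frequency resolution (1/win_s Hz); ``overlap`` is the
    fractional window overlap in [0, 1).  Power is conserved: the PSD
    integrated over [0, fs/2] approximates the signal variance.
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    nperseg = int(round(win_s * rec.fs))
    if nperseg < 2:
        raise ValueError(f"window of {win_s} s at fs={rec.fs} is under 2 samples")
    if rec.samples.shape[1] < nperseg:
        raise ValueError(
            f"recording of {rec.samples.shape[1]} samples shorter than one "
            f"{nperseg}-sample window"
        )
    _nan_check(rec)
    freqs, psd = signal.welch(
        rec.samples,
        fs=rec.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return {
        cid: ContactSpectrum(cid, freqs, psd[i])
        for i, cid in enumerate(rec.channel_ids)
    }


def compute_spectrogram(
    rec: LfpRecording, win_s: float = 1.0, step_s: float = 0.5
) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Time-frequency power map per channel.

    Returns ``{contact_id: (freqs, times, power)}`` with ``power`` of shape
    ``(n_freqs, n_times)`` in uV^2/Hz.  Averaging the map over time agrees
    with :func:`compute_psd` run with the same windows.
    """
    if not 0 < step_s <= win_s:
        raise ValueError(f"step_s must be in (0, win_s], got {step_s}")
    nperseg = int(round(win_s * rec.fs))
    if nperseg < 2:
        raise ValueError(f"window of {win_s} s at fs={rec.fs} is under 2 samples")
    if rec.samples.shape[1] < nperseg:
        raise ValueError("recording shorter than one window")
    _nan_check(rec)
    noverlap = nperseg - int(round(step_s * rec.fs))
    freqs, times, sxx = signal.spectrogram(
        rec.samples,
        fs=rec.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        mode="psd",
        axis=-1,
    )
    return {cid: (freqs, times, sxx[i]) for i, cid in enumerate(rec.channel_ids)}


def fit_one_over_f(
    spec: ContactSpectrum,
    fit_band: tuple[float, float] = BACKGROUND_FIT_BAND,
    exclude: tuple[float, float] = BETA_BAND,
) -> np.ndarray:
    """Aperiodic background: a log-log linear (power-law) fit.

    Fits log10(psd) against log10(f) over ``fit_band`` with the oscillatory
    ``exclude`` band masked out, and returns the fitted background evaluated
    on the full frequency grid.  Bins with zero power are ignored in the
    fit; if fewer than two usable bins remain the background is NaN
    (callers treat that as "no detectable peak").
    """
    f, p = spec.freqs, spec.psd
    mask = (
        (f >= fit_band[0])
        & (f <= fit_band[1])
        & ~((f >= exclude[0]) & (f <= exclude[1]))
        & (f > 0)
        & (p > 0)
    )
    if mask.sum() < 2:
        return np.full_like(f, np.nan)
    slope, intercept = np.polyfit(np.log10(f[mask]), np.log10(p[mask]), 1)
    with np.errstate(divide="ignore"):
        return np.where(f > 0, 10.0 ** (intercept + slope * np.log10(f)), np.nan)


def detect_beta_peak(
    spec: ContactSpectrum,
    band: tuple[float, float] = BETA_BAND,
    prominence_db: float = 3.0,
    halfwidth_hz: float = 3.0,
) -> BetaPeak:
    """Search for a spectral peak above the 1/f background inside ``band``.

    A peak is a local maximum of the PSD within the band whose elevation
    over the fitted background is at least ``prominence_db`` decibels.  If
    several qualify the most elevated one wins.  The peak band is the peak
    frequency +/- ``halfwidth_hz``, clipped to ``band``.
    """
    f = spec.freqs
    if f[0] > band[0] or f[-1] < band[1]:
        raise ValueError(
            f"spectrum support [{f[0]}, {f[-1]}] Hz does not cover {band}"
        )
    background = fit_one_over_f(spec)
    in_band = (f >= band[0]) & (f <= band[1])
    idx = np.flatnonzero(in_band)
    best: tuple[float, float] | None = None  # (excess_db, freq)
    for i in idx:
        if i == 0 or i == len(f) - 1:
            continue
        p = spec.psd[i]
        if not (p > spec.psd[i - 1] and p >= spec.psd[i + 1]):
            continue  # not a local maximum
        bg = background[i]
        if not np.isfinite(bg) or bg <= 0 or p <= 0:
            continue
        excess = 10.0 * np.log10(p / bg)
        if excess >= prominence_db and (best is None or excess > best[0]):
            best = (excess, f[i])
    if best is None:
        return BetaPeak(present=False)
    excess, peak_freq = best
    lo = max(band[0], peak_freq - halfwidth_hz)
    hi = min(band[1], peak_freq + halfwidth_hz)
    return BetaPeak(
        present=True, peak_freq=float(peak_freq), peak_band=(lo, hi),
        prominence_db=float(excess),
    )


def band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid-rule integral of the PSD over [lo, hi].

    Band edges falling between grid points are handled by linear
    interpolation of the PSD at the edge, so the integral is exact for
    piecewise-linear spectra.
    """
    if lo >= hi:
        raise ValueError(f"empty band [{lo}, {hi}]")
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError(f"band [{lo}, {hi}] outside spectrum support")
    inner = (freqs > lo) & (freqs < hi)
    f = np.concatenate(([lo], freqs[inner], [hi]))
    p = np.concatenate(
        ([np.interp(lo, freqs, psd)], psd[inner], [np.interp(hi, freqs, psd)])
    )
    return float(np.trapezoid(p, f))


def normalized_beta(
    spec: ContactSpectrum,
    peak: BetaPeak,
    statistic: str = "power",
) -> NormalizedBeta:
    """Normalized beta: peak-band power over whole-beta-band (13-35 Hz) power.

    With no peak the numerator band is low beta (13-20 Hz) and
    ``used_fallback`` is set.  ``statistic="amplitude"`` reports the square
    root of the power ratio (band amplitude instead of band power); both
    lie in [0, 1] because the numerator band is a sub-band of the
    denominator.
    """
    if statistic not in ("power", "amplitude"):
        raise ValueError(f"statistic must be 'power' or 'amplitude', got {statistic!r}")
    if peak.present:
        num_band = peak.peak_band
        fallback = False
    else:
        num_band = LOW_BETA_BAND
        fallback = True
    denom = band_power(spec.freqs, spec.psd, *BETA_BAND)
    if denom <= 0:
        raise ValueError(
            f"contact {spec.contact_id}: zero power in the 13-35 Hz band; "
            "normalized beta undefined"
        )
    value = band_power(spec.freqs, spec.psd, *num_band) / denom
    if statistic == "amplitude":
        value = float(np.sqrt(value))
    return NormalizedBeta(spec.contact_id, float(value), fallback, num_band)


def hemisphere_beta_profile(
    rec: LfpRecording,
    lead: DirectionalLead,
    win_s: float = 1.0,
    overlap: float = 0.5,
    prominence_db: float = 3.0,
    halfwidth_hz: float = 3.0,
    statistic: str = "power",
    min_duration_s: float = 0.0,
) -> tuple[dict[int, NormalizedBeta], BetaPeak]:
    """Normalized beta for every segmented contact of one hemisphere.

    The peak decision is hemisphere-level: the beta peak is searched on the
    contact with maximal raw beta-band power, and its peak band (or the
    low-beta fallback) is applied to all six contacts so their values share
    a common numerator band.  Returns the per-contact values and the
    hemisphere peak.
    """
    missing = [cid for cid in lead.segmented_ids if cid not in rec.channel_ids]
    if missing:
        raise ValueError(f"recording lacks channels for contacts {missing}")
    if min_duration_s:
        rec.validate(min_duration_s)
    spectra = compute_psd(rec, win_s=win_s, overlap=overlap)
    raw_beta = {
        cid: band_power(spectra[cid].freqs, spectra[cid].psd, *BETA_BAND)
        for cid in lead.segmented_ids
    }
    anchor = max(lead.segmented_ids, key=lambda cid: (raw_beta[cid], -cid))
    peak = detect_beta_peak(
        spectra[anchor], prominence_db=prominence_db, halfwidth_hz=halfwidth_hz
    )
    if not peak.present:
        logger.info("no beta peak on anchor contact %d; low-beta fallback", anchor)
    profile = {
        cid: normalized_beta(spectra[cid], peak, statistic=statistic)
        for cid in lead.segmented_ids
    }
    return profile, peak
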