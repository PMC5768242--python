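"""Synthetic directional-LFP cohorts with known ground truth.

Each simulated hemisphere contains a beta source at a continuous angular
and level position between the two segmented levels of the lead.  The
source drives two observable layers that the analysis later tries to
reconnect:

* electrophysiology -- every segmented contact records a shared
  narrowband beta oscillation (amplitude-modulated band-limited noise, not
  a pure sine) attenuated exponentially with the contact's angular and
  level distance from the source, on top of an independent 1/f background;
* clinic -- expected clinical efficacy and therapeutic window are monotone
  in the same source proximity, with Gaussian noise, so that the contact
  closest to the source is (up to noise) both the beta-dominant and the
  clinically best one.

A configurable fraction of hemispheres carries no clear oscillatory peak:
their beta component is weak and broad, spreading over the band instead of
standing out of the background, which exercises the low-beta fallback of
the spectral pipeline while preserving a faint spatial gradient.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .clinical import ContactReview, HemisphereDataset, score_review
from .lead import DirectionalLead, circular_distance_deg, default_lead
from .spectral import LfpRecording, NormalizedBeta, hemisphere_beta_profile

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_hemisphere_lfp",
    "simulate_review",
    "generate_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic cohort.

    Defaults describe the cohort the analysis is designed for: 19
    hemispheres, ~2-minute intraoperative recordings at 1 kHz, roughly
    12/19 hemispheres with a clear beta peak, a dorsally biased source,
    and a moderate beta-clinic coupling.
    """

    n_hemispheres: int = 19
    fs: float = 1000.0
    duration_s: float = 120.0
    # source geometry; None -> drawn per hemisphere
    source_angle_deg: float | None = None
    source_level: float | None = None  # drawn uniform [2.4, 3.0] (dorsal bias)
    beta_freq: float | None = None  # drawn uniform [15, 30] Hz
    # electrophysiology
    beta_amp: float = 6.0  # uV RMS of the oscillation at zero source distance
    beta_band_halfwidth: float = 2.0  # Hz, narrowband oscillation
    angular_decay: float = 0.012  # amplitude e-folding per degree
    level_decay: float = 1.5  # amplitude e-folding per level unit
    one_over_f_exponent: float = 1.5
    one_over_f_scale: float = 10.0  # background PSD at 1 Hz, uV^2/Hz
    noise_floor: float = 0.05  # white background floor, uV^2/Hz
    peak_prob: float = 12.0 / 19.0
    no_peak_amp_frac: float = 0.25  # residual beta amplitude without a peak
    no_peak_band_halfwidth: float = 6.0  # Hz, broad residual activity
    # clinic
    coupling: float = 0.7  # 0..1 strength of the beta-efficacy link
    efficacy_base: float = 12.0  # %/mA at zero proximity
    efficacy_gain: float = 40.0  # %/mA per unit proximity at coupling=1
    efficacy_noise_sd: float = 5.0  # %/mA
    test_current: float = 2.0  # mA, fixed review current
    effect_base: float = 2.0  # mA effect threshold at zero proximity
    effect_gain: float = 1.2  # mA reduction per unit proximity
    effect_noise_sd: float = 0.2
    tw_base: float = 0.7  # mA
    tw_gain: float = 1.2  # mA per unit proximity
    tw_noise_sd: float = 0.25
    current_ceiling: float = 5.0  # mA, maximum tested current
    # score-level shortcut (generate_cohort(synthesize_lfp=False))
    beta_score_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if not 0 <= self.peak_prob <= 1:
            problems.append(f"peak_prob={self.peak_prob} not in [0, 1]")
        if not 0 <= self.coupling <= 1:
            problems.append(f"coupling={self.coupling} not in [0, 1]")
        if not self.fs > 70:
            problems.append(f"fs={self.fs} too low to resolve beta")
        for name in ("beta_amp", "angular_decay", "level_decay", "noise_floor",
                     "efficacy_noise_sd", "tw_noise_sd", "duration_s"):
            if getattr(self, name) < 0:
                problems.append(f"{name}={getattr(self, name)} is negative")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    hemisphere_id: str
    source_angle_deg: float
    source_level: float
    beta_freq: float
    has_peak: bool
    attenuation: dict[int, float]  # amplitude factor per contact, max = 1 scale-free
    true_beta_power: dict[int, float]  # uV^2 of the oscillation per contact
    expected_efficacy: dict[int, float]
    expected_tw: dict[int, float]
    best_efficacy_contact: int
    best_tw_contact: int


def _attenuation(cfg: SimulationConfig, lead: DirectionalLead,
                 source_angle: float, source_level: float) -> dict[int, float]:
    out = {}
    for cid in lead.segmented_ids:
        c = lead.contact(cid)
        ang = circular_distance_deg(c.angle_deg, source_angle)
        out[cid] = math.exp(-cfg.angular_decay * ang) * math.exp(
            -cfg.level_decay * abs(c.level - source_level)
        )
    return out


def _proximity(attenuation: dict[int, float]) -> dict[int, float]:
    """Attenuation rescaled to max 1: the clinic's proximity signal."""
    m = max(attenuation.values())
    return {cid: a / m for cid, a in attenuation.items()}


def _colored_noise(n: int, fs: float, exponent: float, scale: float,
                   floor: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with one-sided PSD scale/f^exponent + floor (uV^2/Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    target = np.full_like(f, floor)
    target[1:] += scale / f[1:] ** exponent
    target[0] = 0.0  # no DC
    # unit-variance white noise has one-sided PSD 2/fs
    spec *= np.sqrt(target * fs / 2.0)
    return np.fft.irfft(spec, n)


def _narrowband(n: int, fs: float, center: float, halfwidth: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited noise around ``center`` Hz."""
    lo = max(center - halfwidth, 1.0)
    hi = min(center + halfwidth, fs / 2 - 1.0)
    sos = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _draw_source(cfg: SimulationConfig, rng: np.random.Generator
                 ) -> tuple[float, float, float, bool]:
    angle = (cfg.source_angle_deg if cfg.source_angle_deg is not None
             else float(rng.uniform(0.0, 360.0)))
    level = (cfg.source_level if cfg.source_level is not None
             else float(rng.uniform(2.4, 3.0)))
    freq = (cfg.beta_freq if cfg.beta_freq is not None
            else float(rng.uniform(15.0, 30.0)))
    has_peak = bool(rng.random() < cfg.peak_prob)
    return angle, level, freq, has_peak


def _truth_skeleton(cfg: SimulationConfig, lead: DirectionalLead,
                    hemisphere_id: str, angle: float, level: float,
                    freq: float, has_peak: bool) -> GroundTruth:
    atten = _attenuation(cfg, lead, angle, level)
    prox = _proximity(atten)
    amp = cfg.beta_amp * (1.0 if has_peak else cfg.no_peak_amp_frac)
    power = {cid: (amp * a) ** 2 for cid, a in atten.items()}
    eff = {cid: cfg.efficacy_base + cfg.coupling * cfg.efficacy_gain * s
           for cid, s in prox.items()}
    tw = {cid: cfg.tw_base + cfg.tw_gain * s for cid, s in prox.items()}
    # generative argmax, ties broken by lower contact id like the pipeline
    best_eff = min(eff, key=lambda c: (-eff[c], c))
    best_tw = min(tw, key=lambda c: (-tw[c], c))
    return GroundTruth(hemisphere_id, angle, level, freq, has_peak, atten,
                       power, eff, tw, best_eff, best_tw)


def simulate_hemisphere_lfp(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    lead: DirectionalLead | None = None,
    hemisphere_id: str = "H1",
) -> tuple[LfpRecording, GroundTruth]:
    """One hemisphere's 6-channel recording plus its ground truth.

    Every segmented contact receives the *same* beta oscillation scaled by
    its attenuation factor -- aligned contacts on adjacent levels therefore
    carry correlated beta -- plus an independent 1/f background.
    """
    lead = lead or default_lead()
    angle, level, freq, has_peak = _draw_source(cfg, rng)
    truth = _truth_skeleton(cfg, lead, hemisphere_id, angle, level, freq, has_peak)
    n = int(round(cfg.duration_s * cfg.fs))
    halfwidth = (cfg.beta_band_halfwidth if has_peak
                 else cfg.no_peak_band_halfwidth)
    osc = _narrowband(n, cfg.fs, freq, halfwidth, rng)
    amp = cfg.beta_amp * (1.0 if has_peak else cfg.no_peak_amp_frac)
    rows = []
    for cid in lead.segmented_ids:
        bg = _colored_noise(n, cfg.fs, cfg.one_over_f_exponent,
                            cfg.one_over_f_scale, cfg.noise_floor, rng)
        rows.append(bg + amp * truth.attenuation[cid] * osc)
    rec = LfpRecording(lead.segmented_ids, np.vstack(rows), cfg.fs)
    return rec, truth


def simulate_review(
    cfg: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> dict[int, ContactReview]:
    """Monopolar-review table consistent with the hemisphere's ground truth.

    Rigidity improvement is back-computed so that the efficacy score
    recovered by the clinical module equals the generative expected
    efficacy plus noise (improvement truncated to [-50, 100]%); effect and
    side-effect thresholds move with source proximity so TW does too.
    """
    prox = _proximity(truth.attenuation)
    baseline = float(rng.integers(2, 5))  # >= 2 points so filters pass
    reviews: dict[int, ContactReview] = {}
    for cid in sorted(prox):
        eff = truth.expected_efficacy[cid] + rng.normal(0.0, cfg.efficacy_noise_sd)
        improvement = float(np.clip(eff * cfg.test_current, -50.0, 100.0))
        on_stim = baseline * (1.0 - improvement / 100.0)
        effect_thr = float(np.clip(
            cfg.effect_base - cfg.effect_gain * prox[cid]
            + rng.normal(0.0, cfg.effect_noise_sd),
            0.2, cfg.current_ceiling,
        ))
        tw = max(0.0, truth.expected_tw[cid] + rng.normal(0.0, cfg.tw_noise_sd))
        side_thr: float | None = effect_thr + tw
        if side_thr > cfg.current_ceiling:  # never provoked within test range
            side_thr = None
        reviews[cid] = ContactReview(
            contact_id=cid,
            rigidity_baseline=baseline,
            rigidity_on_stim=on_stim,
            test_current=cfg.test_current,
            effect_threshold=effect_thr,
            side_effect_threshold=side_thr,
        )
    return reviews


def _score_level_beta(cfg: SimulationConfig, truth: GroundTruth,
                      rng: np.random.Generator) -> dict[int, NormalizedBeta]:
    """Beta scores without waveform synthesis: true power + relative noise.

    Used for large replicate studies of the ranking layer where the
    spectral estimator itself is not under test.
    """
    noisy = {
        cid: max(p * (1.0 + rng.normal(0.0, cfg.beta_score_noise_sd)), 0.0)
        for cid, p in truth.true_beta_power.items()
    }
    total = sum(noisy.values()) or 1.0  # share of beta power, keeps value in [0,1]
    return {
        cid: NormalizedBeta(cid, noisy[cid] / total,
                            used_fallback=not truth.has_peak,
                            peak_band=(13.0, 20.0))
        for cid in noisy
    }


@dataclass
class SimulatedCohort:
    """A generated cohort plus everything needed to serialize or audit it."""

    datasets: list[HemisphereDataset]
    truths: list[GroundTruth]
    reviews: dict[str, dict[int, ContactReview]]
    recordings: dict[str, LfpRecording] = field(default_factory=dict)


def generate_cohort(
    cfg: SimulationConfig,
    lead: DirectionalLead | None = None,
    synthesize_lfp: bool = True,
    keep_recordings: bool = False,
    profile_kwargs: dict | None = None,
) -> SimulatedCohort:
    """A cohort of independent hemispheres, deterministic given the seed.

    With ``synthesize_lfp`` the full waveform pipeline runs per hemisphere
    (simulate recording -> Welch -> peak detection -> normalized beta);
    without it the beta scores are taken from the generative power directly
    (plus measurement noise), which preserves the ranking structure at a
    fraction of the cost.  Per-hemisphere RNG substreams keep cohorts
    reproducible regardless of generation order.
    """
    lead = lead or default_lead()
    out = SimulatedCohort([], [], {})
    streams = np.random.SeedSequence(cfg.seed).spawn(max(cfg.n_hemispheres, 1))
    for i in range(cfg.n_hemispheres):
        rng = np.random.default_rng(streams[i])
        hid = f"H{i + 1}"
        if synthesize_lfp:
            rec, truth = simulate_hemisphere_lfp(cfg, rng, lead, hid)
            beta, peak = hemisphere_beta_profile(rec, lead,
                                                **(profile_kwargs or {}))
            has_peak = peak.present
            if keep_recordings:
                out.recordings[hid] = rec
        else:
            angle, level, freq, hp = _draw_source(cfg, rng)
            truth = _truth_skeleton(cfg, lead, hid, angle, level, freq, hp)
            beta = _score_level_beta(cfg, truth, rng)
            has_peak = truth.has_peak
        reviews = simulate_review(cfg, truth, rng)
        scores = score_review(reviews, ceiling_ma=cfg.current_ceiling)
        max_beta_contact = min(beta, key=lambda c: (-beta[c].value, c))
        stn_level = ("dorsal" if lead.contact(max_beta_contact).level == 3
                     else "middle")
        out.datasets.append(HemisphereDataset(
            hemisphere_id=hid,
            beta=beta,
            clinical=scores,
            has_beta_peak=has_peak,
            rigidity_baseline=reviews[min(reviews)].rigidity_baseline,
            stn_level=stn_level,
        ))
        out.truths.append(truth)
        out.reviews[hid] = reviews
    return out
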