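"""Readers and writers: LFP tables, EDF, review tables, spectra, cohorts.

All tabular formats are UTF-8 tab-delimited text with a header line.  LFP
recordings serialize as one column of seconds plus one column per contact
(header = contact id, samples in microvolts); EDF files are read through
MNE when it is installed.  A "not_reached" side-effect threshold is the
literal string in review tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import ContactReview
from .lead import DirectionalLead, default_lead
from .simulate import GroundTruth, SimulationConfig
from .spectral import ContactSpectrum, LfpRecording

NOT_REACHED = "not_reached"

REVIEW_COLUMNS = [
    "hemisphere",
    "contact",
    "rigidity_baseline",
    "rigidity_on_stim",
    "test_current",
    "effect_threshold",
    "side_effect_threshold",
]

__all__ = [
    "read_lfp",
    "read_lfp_tsv",
    "read_lfp_edf",
    "write_lfp_tsv",
    "read_review_table",
    "write_review_table",
    "write_spectra_tsv",
    "save_cohort",
    "load_cohort_lfp",
]


def write_lfp_tsv(rec: LfpRecording, path: str | Path) -> None:
    t = np.arange(rec.samples.shape[1]) / rec.fs
    df = pd.DataFrame({"time": t})
    for cid in rec.channel_ids:
        df[str(cid)] = rec.channel(cid)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_lfp_tsv(path: str | Path, fs: float | None = None) -> LfpRecording:
    """Read a delimited LFP table.

    With a ``time`` first column the sampling rate is inferred from it;
    otherwise ``fs`` must be given and every column is a contact channel.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if cols and cols[0].lower() == "time":
        tt = df[cols[0]].to_numpy()
        if len(tt) < 2:
            raise ValueError(f"{path}: need at least 2 samples to infer fs")
        fs = 1.0 / float(np.median(np.diff(tt)))
        cols = cols[1:]
    elif fs is None:
        raise ValueError(f"{path}: no time column and no fs given")
    try:
        channel_ids = [int(c) for c in cols]
    except ValueError:
        raise ValueError(
            f"{path}: channel headers must be contact ids, got {cols}"
        ) from None
    return LfpRecording(channel_ids, df[cols].to_numpy().T, fs)


def read_lfp_edf(
    path: str | Path, channel_map: dict[str, int] | None = None
) -> LfpRecording:
    """Read an EDF recording via MNE (optional dependency).

    ``channel_map`` maps EDF channel labels to contact ids; without it the
    labels themselves must parse as integers.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF requires mne (install the 'edf' extra)"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = raw.ch_names
    if channel_map is not None:
        missing = [l for l in channel_map if l not in labels]
        if missing:
            raise ValueError(f"{path}: EDF lacks mapped channels {missing}")
        labels = list(channel_map)
        ids = [channel_map[l] for l in labels]
    else:
        ids = [int(l) for l in labels]
    data = raw.get_data(picks=labels) * 1e6  # MNE loads volts; we use uV
    return LfpRecording(ids, data, float(raw.info["sfreq"]))


def read_lfp(path: str | Path, fs: float | None = None,
             channel_map: dict[str, int] | None = None) -> LfpRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_lfp_edf(path, channel_map)
    return read_lfp_tsv(path, fs)


def write_review_table(
    reviews_by_hemisphere: dict[str, dict[int, ContactReview]],
    path: str | Path,
) -> None:
    rows = []
    for hid, reviews in reviews_by_hemisphere.items():
        for cid in sorted(reviews):
            r = reviews[cid]
            rows.append({
                "hemisphere": hid,
                "contact": cid,
                "rigidity_baseline": r.rigidity_baseline,
                "rigidity_on_stim": round(r.rigidity_on_stim, 4),
                "test_current": r.test_current,
                "effect_threshold": round(r.effect_threshold, 4),
                "side_effect_threshold": (
                    NOT_REACHED if r.side_effect_threshold is None
                    else round(r.side_effect_threshold, 4)
                ),
            })
    pd.DataFrame(rows, columns=REVIEW_COLUMNS).to_csv(path, sep="\t", index=False)


def read_review_table(path: str | Path) -> dict[str, dict[int, ContactReview]]:
    """Parse a review table; the header must match the schema exactly."""
    df = pd.read_csv(path, sep="\t", dtype={"side_effect_threshold": str})
    if list(df.columns) != REVIEW_COLUMNS:
        raise ValueError(
            f"{path}: bad review header {list(df.columns)}, "
            f"expected {REVIEW_COLUMNS}"
        )
    out: dict[str, dict[int, ContactReview]] = {}
    for i, row in df.iterrows():
        se_raw = str(row["side_effect_threshold"]).strip()
        side = None if se_raw == NOT_REACHED else float(se_raw)
        try:
            review = ContactReview(
                contact_id=int(row["contact"]),
                rigidity_baseline=float(row["rigidity_baseline"]),
                rigidity_on_stim=float(row["rigidity_on_stim"]),
                test_current=float(row["test_current"]),
                effect_threshold=float(row["effect_threshold"]),
                side_effect_threshold=side,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
        out.setdefault(str(row["hemisphere"]), {})[review.contact_id] = review
    return out


def write_spectra_tsv(spectra: dict[int, ContactSpectrum], path: str | Path) -> None:
    ids = sorted(spectra)
    df = pd.DataFrame({"freq_hz": spectra[ids[0]].freqs})
    for cid in ids:
        df[f"psd_{cid}"] = spectra[cid].psd
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _truth_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        for cid in sorted(t.attenuation):
            rows.append({
                "hemisphere": t.hemisphere_id,
                "contact": cid,
                "source_angle_deg": round(t.source_angle_deg, 3),
                "source_level": round(t.source_level, 4),
                "beta_freq": round(t.beta_freq, 3),
                "has_peak": t.has_peak,
                "attenuation": round(t.attenuation[cid], 6),
                "true_beta_power": round(t.true_beta_power[cid], 6),
                "expected_efficacy": round(t.expected_efficacy[cid], 4),
                "expected_tw": round(t.expected_tw[cid], 4),
                "best_efficacy_contact": t.best_efficacy_contact,
                "best_tw_contact": t.best_tw_contact,
            })
    return pd.DataFrame(rows)


def save_cohort(
    out_dir: str | Path,
    cfg: SimulationConfig,
    reviews_by_hemisphere: dict[str, dict[int, ContactReview]],
    truths: list[GroundTruth],
    recordings: dict[str, LfpRecording] | None = None,
    lead: DirectionalLead | None = None,
) -> Path:
    """Serialize a simulated cohort: LFP tables, review table, truth, config."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(cfg), indent=2) + "\n"
        )
        (out / "lead.json").write_text((lead or default_lead()).to_json() + "\n")
        write_review_table(reviews_by_hemisphere, out / "review.tsv")
        _truth_frame(truths).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        if recordings:
            lfp_dir = out / "lfp"
            lfp_dir.mkdir(exist_ok=True)
            for hid, rec in recordings.items():
                write_lfp_tsv(rec, lfp_dir / f"{hid}.tsv")
    except OSError as exc:
        raise OSError(f"failed writing cohort under {out}: {exc}") from exc
    return out


def load_cohort_lfp(cohort_dir: str | Path) -> tuple[
    dict[str, LfpRecording], dict[str, dict[int, ContactReview]], DirectionalLead
]:
    """Load the raw inputs of a serialized cohort (recordings + reviews)."""
    d = Path(cohort_dir)
    reviews = read_review_table(d / "review.tsv")
    lead_file = d / "lead.json"
    lead = (DirectionalLead.from_json(lead_file.read_text())
            if lead_file.exists() else default_lead())
    recordings: dict[str, LfpRecording] = {}
    lfp_dir = d / "lfp"
    if lfp_dir.is_dir():
        for f in sorted(lfp_dir.glob("*.tsv")):
            recordings[f.stem] = read_lfp_tsv(f)
    return recordings, reviews, lead
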