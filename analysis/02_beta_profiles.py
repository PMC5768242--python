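#!/usr/bin/env python
"""Spectral stage: normalized beta per contact for every hemisphere.

Reads the cohort written by 01_simulate_cohort.py, runs Welch spectra,
hemisphere-level peak detection and the normalized-beta statistic, and
writes results/beta_profiles.tsv plus a time-frequency figure for the
first hemisphere (figures/spectrogram_H1.png).
"""

import pandas as pd

from _common import COHORT_DIR, FIGURES, RESULTS, load_datasets
from dirlfp import io as dio
from dirlfp.plots import plot_spectrogram_grid


def main() -> None:
    datasets = load_datasets()
    rows = []
    for h in datasets:
        for cid in h.contact_ids:
            nb = h.beta[cid]
            rows.append({
                "hemisphere": h.hemisphere_id,
                "contact": cid,
                "normalized_beta": round(nb.value, 5),
                "peak_band_lo": nb.peak_band[0],
                "peak_band_hi": nb.peak_band[1],
                "used_fallback": nb.used_fallback,
            })
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "beta_profiles.tsv", sep="\t",
                              index=False)

    n_fallback = sum(1 for h in datasets if not h.has_beta_peak)
    print(f"beta profiles for {len(datasets)} hemispheres -> "
          f"{RESULTS / 'beta_profiles.tsv'}")
    print(f"  {n_fallback} hemispheres used the low-beta (13-20 Hz) fallback")

    recordings, _, _ = dio.load_cohort_lfp(COHORT_DIR)
    FIGURES.mkdir(parents=True, exist_ok=True)
    plot_spectrogram_grid(recordings["H1"], FIGURES / "spectrogram_H1.png")
    print(f"time-frequency figure: {FIGURES / 'spectrogram_H1.png'}")


if __name__ == "__main__":
    main()
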