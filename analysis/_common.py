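"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from dirlfp import io as dio
from dirlfp.pipeline import AnalysisConfig, build_hemisphere_dataset

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
FIGURES = RESULTS / "figures"


def load_datasets(cohort_dir=COHORT_DIR, config=AnalysisConfig()):
    """Rebuild hemisphere datasets from a serialized cohort directory."""
    recordings, reviews, lead = dio.load_cohort_lfp(cohort_dir)
    if not recordings:
        raise SystemExit(
            f"no cohort under {cohort_dir}; run analysis/01_simulate_cohort.py first"
        )
    datasets = []
    for hid in sorted(recordings, key=lambda h: (len(h), h)):
        datasets.append(
            build_hemisphere_dataset(hid, recordings[hid], reviews[hid], lead, config)
        )
    return datasets
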