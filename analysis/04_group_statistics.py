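#!/usr/bin/env python
"""Group statistics: correlations, paired comparisons, level tally.

Per hemisphere, Spearman rho between normalized beta and clinical
efficacy across the six contacts; across hemispheres, a one-sample t on
the rhos, paired t tests of the top-2-beta contacts vs the remaining four
(efficacy and TW), and the tally of the ring level carrying maximal beta.
Writes results/correlations.tsv, results/group_summary.txt and
figures/beta_vs_efficacy.png (per-hemisphere ranked scatter panels).
"""

import pandas as pd

from _common import FIGURES, RESULTS, load_datasets
from dirlfp.pipeline import analyze_cohort, summary_lines
from dirlfp.plots import plot_beta_vs_efficacy_panels


def main() -> None:
    analysis = analyze_cohort(load_datasets())
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame([
        {"hemisphere": c.hemisphere_id, "rho": round(c.rho, 4), "n": c.n}
        for c in analysis.correlations
    ]).to_csv(RESULTS / "correlations.tsv", sep="\t", index=False)

    lines = summary_lines(analysis)
    (RESULTS / "group_summary.txt").write_text("\n".join(lines) + "\n")
    FIGURES.mkdir(parents=True, exist_ok=True)
    plot_beta_vs_efficacy_panels(analysis, FIGURES / "beta_vs_efficacy.png")

    for line in lines:
        print(line)
    print(f"tables: {RESULTS / 'correlations.tsv'}; "
          f"figure: {FIGURES / 'beta_vs_efficacy.png'}")


if __name__ == "__main__":
    main()
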