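#!/usr/bin/env python
"""Prediction stage: LFP-guided vs uninformed top-k screening curves.

For each hemisphere the contacts are ranked by normalized beta; the curves
give the probability that the best clinical contact (highest efficacy, or
widest therapeutic window) lies among the first k contacts screened.
Writes results/strategy_curves.tsv and figures/strategy_curves.png.
"""

from _common import FIGURES, RESULTS, load_datasets
from dirlfp.pipeline import analyze_cohort, curves_frame
from dirlfp.plots import plot_strategy_curves


def main() -> None:
    analysis = analyze_cohort(load_datasets())
    RESULTS.mkdir(exist_ok=True)
    frame = curves_frame(analysis)
    frame.to_csv(RESULTS / "strategy_curves.tsv", sep="\t", index=False)
    FIGURES.mkdir(parents=True, exist_ok=True)
    plot_strategy_curves(analysis, FIGURES / "strategy_curves.png")

    eff = analysis.curves["efficacy/lfp/all"].probability
    tw = analysis.curves["tw/lfp/all"].probability
    print(f"n = {analysis.n_hemispheres} hemispheres "
          f"({analysis.n_beta_peak} with a beta peak)")
    print(f"best-efficacy contact found: top-1 {eff[0]:.2f}, top-2 {eff[1]:.2f} "
          f"(random 0.17 / 0.33)")
    print(f"widest-TW contact found:     top-1 {tw[0]:.2f}, top-2 {tw[1]:.2f}")
    key = "efficacy/lfp/beta_peak_only"
    if key in analysis.curves:
        c = analysis.curves[key]
        print(f"beta-peak subset (n={c.n_hemispheres}): "
              f"top-2 {c.probability[1]:.2f}")
    print(f"tables: {RESULTS / 'strategy_curves.tsv'}; "
          f"figure: {FIGURES / 'strategy_curves.png'}")


if __name__ == "__main__":
    main()
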