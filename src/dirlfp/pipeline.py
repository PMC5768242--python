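"""End-to-end cohort analysis: recordings + reviews -> ranked predictions.

This is the layer the drivers, the CLI and the reproduction script all call
into.  Given per-hemisphere recordings and monopolar-review tables it

1. computes the normalized-beta profile per hemisphere (hemisphere-level
   peak decision, low-beta fallback),
2. scores each contact's clinical efficacy and therapeutic window,
3. applies the cohort inclusion filters,
4. runs the group battery: per-hemisphere Spearman rho between beta and
   efficacy with a one-sample t across hemispheres, top-k strategy curves
   (LFP-guided vs the analytic k/6 baseline, all hemispheres and the
   beta-peak subset), top-2-vs-rest paired comparisons for efficacy and TW,
   and the dorsal-level tally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import (
    ContactReview,
    HemisphereDataset,
    apply_inclusion_filters,
    score_review,
)
from .lead import DirectionalLead, default_lead
from .ranking import (
    StrategyCurve,
    Top2Comparison,
    dorsal_level_tally,
    lfp_strategy_curve,
    random_strategy_curve,
    top2_vs_rest,
)
from .spectral import LfpRecording, hemisphere_beta_profile
from .stats import CorrelationResult, GroupTestResult, one_sample_t, spearman_rho

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "CohortAnalysis",
    "build_hemisphere_dataset",
    "analyze_cohort",
    "curves_frame",
    "summary_lines",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the analysis, with the defaults used throughout."""

    win_s: float = 1.0  # Welch window -> 1 Hz resolution
    overlap: float = 0.5
    prominence_db: float = 3.0  # peak elevation over the 1/f fit
    halfwidth_hz: float = 3.0  # peak band = peak freq +/- this
    statistic: str = "power"  # or "amplitude"
    current_basis: str = "fixed"  # efficacy denominator: test current
    ceiling_ma: float = 5.0  # cap for "not reached" side-effect thresholds
    min_rigidity: float = 2.0  # inclusion: baseline rigidity points
    min_range: float = 5.0  # inclusion: efficacy spread across contacts, %/mA
    min_duration_s: float = 60.0


@dataclass
class CohortAnalysis:
    """Everything the group analysis produces for one cohort."""

    datasets: list[HemisphereDataset]
    excluded: list[tuple[str, str]]
    correlations: list[CorrelationResult]
    rho_t_test: GroupTestResult | None
    n_positive_rho: int
    curves: dict[str, StrategyCurve]  # keyed e.g. "efficacy/lfp/all"
    top2: dict[str, Top2Comparison]  # keyed by metric
    level_tally: dict[str, int]
    n_beta_peak: int

    @property
    def n_hemispheres(self) -> int:
        return len(self.datasets)

    def match_rate(self, criterion: str, k: int, subset: str = "all") -> float:
        """Fraction of hemispheres whose best contact is in the beta top-k."""
        curve = self.curves[f"{criterion}/lfp/{subset}"]
        return curve.probability[curve.k_values.index(k)]


def build_hemisphere_dataset(
    hemisphere_id: str,
    rec: LfpRecording,
    reviews: dict[int, ContactReview],
    lead: DirectionalLead | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> HemisphereDataset:
    """Pair one hemisphere's electrophysiology with its clinical review."""
    lead = lead or default_lead()
    beta, peak = hemisphere_beta_profile(
        rec, lead,
        win_s=config.win_s, overlap=config.overlap,
        prominence_db=config.prominence_db, halfwidth_hz=config.halfwidth_hz,
        statistic=config.statistic, min_duration_s=config.min_duration_s,
    )
    missing = [cid for cid in lead.segmented_ids if cid not in reviews]
    if missing:
        raise ValueError(
            f"hemisphere {hemisphere_id}: review lacks contacts {missing}"
        )
    scores = score_review(
        {cid: reviews[cid] for cid in lead.segmented_ids},
        current_basis=config.current_basis, ceiling_ma=config.ceiling_ma,
    )
    max_beta = min(beta, key=lambda c: (-beta[c].value, c))
    stn_level = "dorsal" if lead.contact(max_beta).level == 3 else "middle"
    baseline = reviews[min(reviews)].rigidity_baseline
    return HemisphereDataset(
        hemisphere_id=hemisphere_id, beta=beta, clinical=scores,
        has_beta_peak=peak.present, rigidity_baseline=baseline,
        stn_level=stn_level,
    )


def analyze_cohort(
    cohort: list[HemisphereDataset],
    config: AnalysisConfig = AnalysisConfig(),
) -> CohortAnalysis:
    """The full group analysis on an assembled cohort."""
    kept, excluded = apply_inclusion_filters(
        cohort, min_rigidity=config.min_rigidity, min_range=config.min_range
    )
    if not kept:
        logger.warning("no hemispheres pass the inclusion filters")
        return CohortAnalysis(
            datasets=[], excluded=excluded, correlations=[], rho_t_test=None,
            n_positive_rho=0, curves={}, top2={},
            level_tally={"ventral": 0, "middle": 0, "dorsal": 0}, n_beta_peak=0,
        )
    correlations = []
    for h in kept:
        ids = h.contact_ids
        rho = spearman_rho(
            [h.beta[c].value for c in ids],
            [h.clinical[c].efficacy for c in ids],
        )
        correlations.append(CorrelationResult(
            h.hemisphere_id, rho, len(ids), degenerate=not np.isfinite(rho)
        ))
    rhos = [c.rho for c in correlations if not c.degenerate]
    rho_t = one_sample_t(rhos) if len(rhos) >= 2 else None
    curves: dict[str, StrategyCurve] = {}
    for criterion in ("efficacy", "tw"):
        curves[f"{criterion}/lfp/all"] = lfp_strategy_curve(kept, criterion)
        peak_subset = [h for h in kept if h.has_beta_peak]
        if peak_subset:
            curves[f"{criterion}/lfp/beta_peak_only"] = lfp_strategy_curve(
                kept, criterion, subset="beta_peak_only"
            )
        curves[f"{criterion}/random"] = random_strategy_curve(criterion=criterion)
    top2 = {m: top2_vs_rest(kept, m) for m in ("efficacy", "tw")}
    return CohortAnalysis(
        datasets=kept, excluded=excluded, correlations=correlations,
        rho_t_test=rho_t, n_positive_rho=sum(1 for r in rhos if r > 0),
        curves=curves, top2=top2, level_tally=dorsal_level_tally(kept),
        n_beta_peak=sum(1 for h in kept if h.has_beta_peak),
    )


def curves_frame(analysis: CohortAnalysis) -> pd.DataFrame:
    """Strategy curves as a tidy table (k, one column per curve)."""
    data: dict[str, list] = {"k": list(range(1, 7))}
    for key in sorted(analysis.curves):
        data[key.replace("/", "_")] = list(analysis.curves[key].probability)
    return pd.DataFrame(data)


def summary_lines(analysis: CohortAnalysis) -> list[str]:
    """Human-readable summary mirroring the headline group results."""
    a = analysis
    lines = [
        f"hemispheres analyzed: {a.n_hemispheres} "
        f"({a.n_beta_peak} with a clear beta peak); excluded: {len(a.excluded)}",
    ]
    if a.rho_t_test is not None:
        t = a.rho_t_test
        lines.append(
            f"beta-efficacy Spearman rho > 0 in {a.n_positive_rho}/"
            f"{a.n_hemispheres} hemispheres; one-sample t{t.df} = "
            f"{t.statistic:.2f}, p = {t.p:.2g} (mean rho {t.mean:.2f})"
        )
    for criterion, label in (("efficacy", "highest-efficacy"),
                             ("tw", "widest-TW")):
        if f"{criterion}/lfp/all" not in a.curves:
            continue
        c = a.curves[f"{criterion}/lfp/all"]
        line = (f"{label} contact in beta top-1: {c.probability[0]:.2f}, "
                f"top-2: {c.probability[1]:.2f} (random: 0.17 / 0.33)")
        peak_key = f"{criterion}/lfp/beta_peak_only"
        if peak_key in a.curves:
            line += (f"; beta-peak subset top-2: "
                     f"{a.curves[peak_key].probability[1]:.2f} "
                     f"(n={a.curves[peak_key].n_hemispheres})")
        lines.append(line)
    for metric, unit in (("efficacy", "%/mA"), ("tw", "mA")):
        if metric not in a.top2:
            continue
        c = a.top2[metric]
        lines.append(
            f"{metric}: top-2-beta contacts {c.top2_mean:.1f} +/- "
            f"{c.top2_sem:.1f} {unit} vs rest {c.rest_mean:.1f} +/- "
            f"{c.rest_sem:.1f} {unit} (paired t{c.test.df} = "
            f"{c.test.statistic:.2f}, p = {c.test.p:.2g})"
        )
    lines.append(
        "max-beta ring level: ventral {ventral}, middle {middle}, "
        "dorsal {dorsal}".format(**a.level_tally)
    )
    return lines
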