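"""Contact ranking by beta and top-k screening-strategy curves.

The programming question the curves answer: if a clinician can only screen
k of the six segmented contacts, what is the probability that the screened
set contains the contact that monopolar review will later identify as best
(highest clinical efficacy, or widest therapeutic window)?  The LFP-guided
strategy screens contacts in descending order of normalized beta; the
conventional baseline screens contacts in an uninformed order, for which
the hit probability is exactly k/6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .clinical import HemisphereDataset
from .stats import GroupTestResult, paired_t

logger = logging.getLogger(__name__)

N_SEGMENTS = 6

__all__ = [
    "StrategyCurve",
    "Top2Comparison",
    "rank_by_beta",
    "best_clinical_contact",
    "lfp_strategy_curve",
    "random_strategy_curve",
    "top2_vs_rest",
    "dorsal_level_tally",
]


@dataclass(frozen=True)
class StrategyCurve:
    """Hit probability as a function of the number of contacts screened."""

    criterion: str  # "efficacy" or "tw"
    strategy: str  # "lfp" or "random"
    k_values: tuple[int, ...]
    probability: tuple[float, ...]
    n_hemispheres: int
    subset: str = "all"  # "all" or "beta_peak_only"


@dataclass(frozen=True)
class Top2Comparison:
    """Per-hemisphere means of a clinical metric: top-2-beta vs other 4."""

    metric: str
    top2_means: tuple[float, ...]
    rest_means: tuple[float, ...]
    top2_mean: float
    top2_sem: float
    rest_mean: float
    rest_sem: float
    test: GroupTestResult


def _metric_value(h: HemisphereDataset, criterion: str, cid: int) -> float:
    if criterion == "efficacy":
        return h.clinical[cid].efficacy
    if criterion == "tw":
        return h.clinical[cid].tw
    raise ValueError(f"criterion must be 'efficacy' or 'tw', got {criterion!r}")


def rank_by_beta(h: HemisphereDataset) -> list[int]:
    """Contact ids ordered by normalized beta, highest first.

    Exact ties are broken toward the lower contact id so the order is a
    deterministic total order; ties are logged.
    """
    values = {cid: h.beta[cid].value for cid in h.contact_ids}
    if any(v is None or not np.isfinite(v) for v in values.values()):
        raise ValueError(f"hemisphere {h.hemisphere_id}: missing beta values")
    order = sorted(values, key=lambda cid: (-values[cid], cid))
    if len(set(values.values())) < len(values):
        logger.info(
            "hemisphere %s: tied beta values, ties broken by lower contact id",
            h.hemisphere_id,
        )
    return order


def best_clinical_contact(h: HemisphereDataset, criterion: str) -> int:
    """The contact monopolar review would select under ``criterion``.

    Max efficacy for "efficacy", max TW for "tw"; ties broken toward the
    lower contact id and logged.
    """
    vals = {cid: _metric_value(h, criterion, cid) for cid in h.contact_ids}
    best = min(vals, key=lambda cid: (-vals[cid], cid))
    if sum(1 for v in vals.values() if v == vals[best]) > 1:
        logger.info(
            "hemisphere %s: clinical tie on %s, broken by lower contact id",
            h.hemisphere_id, criterion,
        )
    return best


def _select_subset(
    cohort: list[HemisphereDataset], subset: str
) -> list[HemisphereDataset]:
    if subset == "all":
        return list(cohort)
    if subset == "beta_peak_only":
        return [h for h in cohort if h.has_beta_peak]
    raise ValueError(f"subset must be 'all' or 'beta_peak_only', got {subset!r}")


def lfp_strategy_curve(
    cohort: list[HemisphereDataset], criterion: str, subset: str = "all"
) -> StrategyCurve:
    """Hit probability of beta-ordered screening, for k = 1..6.

    probability(k) is the fraction of hemispheres whose best clinical
    contact lies among the top-k beta-ranked contacts.  Nondecreasing in k
    and exactly 1 at k = 6.
    """
    hemis = _select_subset(cohort, subset)
    if not hemis:
        raise ValueError("empty cohort (after subsetting)")
    ranks: list[int] = []
    for h in hemis:
        order = rank_by_beta(h)
        best = best_clinical_contact(h, criterion)
        ranks.append(order.index(best) + 1)  # beta rank of the best contact
    ks = tuple(range(1, N_SEGMENTS + 1))
    prob = tuple(sum(r <= k for r in ranks) / len(ranks) for k in ks)
    return StrategyCurve(criterion, "lfp", ks, prob, len(hemis), subset)


def random_strategy_curve(
    n_contacts: int = N_SEGMENTS, criterion: str = "efficacy"
) -> StrategyCurve:
    """The uninformed baseline: probability(k) = k / n_contacts, exactly.

    Screening k of n contacts uniformly without replacement contains the
    single best contact with probability k/n; the curve is analytic, no
    sampling involved.
    """
    if n_contacts < 1:
        raise ValueError("n_contacts must be >= 1")
    ks = tuple(range(1, n_contacts + 1))
    prob = tuple(float(Fraction(k, n_contacts)) for k in ks)
    return StrategyCurve(criterion, "random", ks, prob, 0, "all")


def top2_vs_rest(cohort: list[HemisphereDataset], metric: str) -> Top2Comparison:
    """Mean metric over the two highest-beta contacts vs the other four.

    Returns the paired per-hemisphere means, their group mean +/- SEM, and
    a paired t test of the within-hemisphere difference.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 hemispheres for the paired test")
    top2, rest = [], []
    for h in cohort:
        order = rank_by_beta(h)
        top2.append(np.mean([_metric_value(h, metric, c) for c in order[:2]]))
        rest.append(np.mean([_metric_value(h, metric, c) for c in order[2:]]))
    top2_a, rest_a = np.asarray(top2), np.asarray(rest)
    n = len(cohort)
    return Top2Comparison(
        metric=metric,
        top2_means=tuple(top2_a),
        rest_means=tuple(rest_a),
        top2_mean=float(top2_a.mean()),
        top2_sem=float(top2_a.std(ddof=1) / np.sqrt(n)),
        rest_mean=float(rest_a.mean()),
        rest_sem=float(rest_a.std(ddof=1) / np.sqrt(n)),
        test=paired_t(top2_a, rest_a),
    )


def dorsal_level_tally(cohort: list[HemisphereDataset]) -> dict[str, int]:
    """Count hemispheres by the STN zone of their max-beta ring level.

    Each hemisphere must carry an ``stn_level`` annotation in
    {"ventral", "middle", "dorsal"}; counts sum to the cohort size.
    """
    counts = {"ventral": 0, "middle": 0, "dorsal": 0}
    for h in cohort:
        if h.stn_level not in counts:
            raise ValueError(
                f"hemisphere {h.hemisphere_id}: unknown STN level "
                f"{h.stn_level!r}"
            )
        counts[h.stn_level] += 1
    return counts
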