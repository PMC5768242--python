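"""Monopolar-review scoring: clinical efficacy, therapeutic window, filters.

During a monopolar contact review each segmented contact is tested in turn:
upper-limb rigidity is scored at baseline and on stimulation at a test
current, and the currents at which a clinical effect and the first
side effect appear are noted.  Two scores summarise each contact:

* clinical efficacy -- percent rigidity improvement per milliampere,
* therapeutic window (TW) -- side-effect threshold minus effect threshold,
  in mA, the current range within which stimulation helps without harming.

Hemispheres enter the group analysis only if baseline rigidity is at least
2 points (otherwise improvement cannot be graded) and the efficacy spread
across the six contacts exceeds a minimum range (otherwise there is no
best contact to predict).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .spectral import NormalizedBeta

logger = logging.getLogger(__name__)

#: default ceiling used when the side-effect threshold was never reached (mA)
DEFAULT_CURRENT_CEILING_MA = 5.0

__all__ = [
    "ContactReview",
    "ContactClinicalScore",
    "HemisphereDataset",
    "clinical_efficacy",
    "therapeutic_window",
    "score_review",
    "apply_inclusion_filters",
]


@dataclass(frozen=True)
class ContactReview:
    """Raw monopolar-review entries for one contact.

    ``side_effect_threshold`` is None when no side effect appeared up to
    the maximum tested current ("not reached").  Rigidity is in clinical
    rating points (0-4 scale per item).
    """

    contact_id: int
    rigidity_baseline: float
    rigidity_on_stim: float
    test_current: float
    effect_threshold: float
    side_effect_threshold: float | None

    def __post_init__(self) -> None:
        for name in ("test_current", "effect_threshold"):
            v = getattr(self, name)
            if v is None or v < 0 or not math.isfinite(v):
                raise ValueError(f"contact {self.contact_id}: invalid {name}={v}")
        if self.side_effect_threshold is not None and self.side_effect_threshold < 0:
            raise ValueError(
                f"contact {self.contact_id}: negative side-effect threshold"
            )
        if self.rigidity_on_stim > self.rigidity_baseline:
            # worsening is allowed but flagged in the log
            logger.info(
                "contact %d: rigidity worsened on stimulation (%.2f > %.2f)",
                self.contact_id, self.rigidity_on_stim, self.rigidity_baseline,
            )


@dataclass(frozen=True)
class ContactClinicalScore:
    contact_id: int
    efficacy: float  # % rigidity improvement per mA
    tw: float  # therapeutic window, mA


@dataclass
class HemisphereDataset:
    """Paired electrophysiology and clinic for one hemisphere.

    ``beta`` and ``clinical`` map the same six segmented contact ids.
    ``stn_level`` optionally labels the anatomical level (ventral/middle/
    dorsal STN) of the ring level holding the max-beta contact.
    """

    hemisphere_id: str
    beta: dict[int, NormalizedBeta]
    clinical: dict[int, ContactClinicalScore]
    has_beta_peak: bool
    rigidity_baseline: float | None = None
    stn_level: str | None = None

    def __post_init__(self) -> None:
        if set(self.beta) != set(self.clinical):
            raise ValueError(
                f"hemisphere {self.hemisphere_id}: beta and clinical maps "
                f"cover different contacts"
            )
        if len(self.beta) != 6:
            raise ValueError(
                f"hemisphere {self.hemisphere_id}: expected 6 contacts, "
                f"got {len(self.beta)}"
            )

    @property
    def contact_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.beta))


def clinical_efficacy(
    review: ContactReview, current_basis: str = "fixed"
) -> float:
    """Percent rigidity improvement per mA.

    ``current_basis="fixed"`` divides by the test current at which rigidity
    was scored; ``"threshold"`` divides by the effect threshold instead.
    """
    if current_basis == "fixed":
        current = review.test_current
    elif current_basis == "threshold":
        current = review.effect_threshold
    else:
        raise ValueError(f"current_basis must be 'fixed' or 'threshold'")
    if current <= 0:
        raise ValueError(
            f"contact {review.contact_id}: nonpositive current {current} mA"
        )
    if review.rigidity_baseline <= 0:
        raise ValueError(
            f"contact {review.contact_id}: nonpositive baseline rigidity"
        )
    improvement = (
        100.0
        * (review.rigidity_baseline - review.rigidity_on_stim)
        / review.rigidity_baseline
    )
    return improvement / current


def therapeutic_window(
    review: ContactReview, ceiling_ma: float = DEFAULT_CURRENT_CEILING_MA
) -> float:
    """Side-effect threshold minus effect threshold, in mA.

    A side-effect threshold that was never reached is capped at
    ``ceiling_ma`` (the maximum current tested).  Negative windows -- side
    effects at or below the effect threshold -- are clipped to 0 and
    logged.
    """
    if not math.isfinite(review.effect_threshold):
        raise ValueError(f"contact {review.contact_id}: missing effect threshold")
    se = review.side_effect_threshold
    if se is None:
        se = ceiling_ma
        logger.info(
            "contact %d: side-effect threshold not reached, capped at %.1f mA",
            review.contact_id, ceiling_ma,
        )
    tw = se - review.effect_threshold
    if tw < 0:
        logger.warning(
            "contact %d: negative therapeutic window %.2f mA clipped to 0",
            review.contact_id, tw,
        )
        tw = 0.0
    return float(tw)


def score_review(
    reviews: dict[int, ContactReview],
    current_basis: str = "fixed",
    ceiling_ma: float = DEFAULT_CURRENT_CEILING_MA,
) -> dict[int, ContactClinicalScore]:
    """Efficacy and TW for every reviewed contact."""
    return {
        cid: ContactClinicalScore(
            cid,
            clinical_efficacy(r, current_basis=current_basis),
            therapeutic_window(r, ceiling_ma=ceiling_ma),
        )
        for cid, r in reviews.items()
    }


def apply_inclusion_filters(
    cohort: list[HemisphereDataset],
    min_rigidity: float = 2.0,
    min_range: float = 5.0,
) -> tuple[list[HemisphereDataset], list[tuple[str, str]]]:
    """Keep hemispheres suitable for the contact-level comparison.

    A hemisphere is retained when baseline upper-limb rigidity is at least
    ``min_rigidity`` points and the efficacy spread across its six contacts
    (max minus min) exceeds ``min_range`` %/mA.  Returns the filtered
    cohort and an exclusion log of ``(hemisphere_id, reason)`` pairs.
    Filtering is idempotent.
    """
    kept: list[HemisphereDataset] = []
    log: list[tuple[str, str]] = []
    for h in cohort:
        if h.rigidity_baseline is not None and h.rigidity_baseline < min_rigidity:
            log.append((h.hemisphere_id, "rigidity"))
            logger.info(
                "excluding %s: baseline rigidity %.1f < %.1f",
                h.hemisphere_id, h.rigidity_baseline, min_rigidity,
            )
            continue
        effs = [s.efficacy for s in h.clinical.values()]
        if max(effs) - min(effs) <= min_range:
            log.append((h.hemisphere_id, "range"))
            logger.info(
                "excluding %s: efficacy range %.2f <= %.2f %%/mA",
                h.hemisphere_id, max(effs) - min(effs), min_range,
            )
            continue
        kept.append(h)
    return kept, log
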