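"""Beta ranking, strategy curves, top-2 comparison, level tally."""

import numpy as np
import pytest

from dirlfp.ranking import (
    best_clinical_contact,
    dorsal_level_tally,
    lfp_strategy_curve,
    random_strategy_curve,
    rank_by_beta,
    top2_vs_rest,
)
from dirlfp.simulate import SimulationConfig, generate_cohort
from tests.conftest import make_hemisphere


def test_rank_by_beta_orders_and_breaks_ties():
    h = make_hemisphere(beta=(0.1, 0.5, 0.3, 0.9, 0.2, 0.4))
    assert rank_by_beta(h) == [5, 3, 7, 4, 6, 2]
    flat = make_hemisphere(beta=(0.3,) * 6)
    assert rank_by_beta(flat) == [2, 3, 4, 5, 6, 7]  # tie rule: lower id first


def test_rank_equivariant_under_relabeling():
    beta = (0.1, 0.5, 0.3, 0.9, 0.2, 0.4)
    h = make_hemisphere(beta=beta)
    # rotate values across contacts: the ranking rotates identically
    h2 = make_hemisphere(beta=beta[1:] + beta[:1])
    ids = (2, 3, 4, 5, 6, 7)
    relabel = dict(zip(ids, ids[-1:] + ids[:-1]))  # value of c moved to relabel[c]
    assert [relabel[c] for c in rank_by_beta(h)] == rank_by_beta(h2)


def test_lfp_curve_hand_enumeration():
    # best clinical contact sits at beta rank 1, 2 and 4 in three hemispheres
    hs = [
        make_hemisphere("a", beta=(6, 5, 4, 3, 2, 1), efficacy=(60, 1, 2, 3, 4, 5)),
        make_hemisphere("b", beta=(6, 5, 4, 3, 2, 1), efficacy=(1, 60, 2, 3, 4, 5)),
        make_hemisphere("c", beta=(6, 5, 4, 3, 2, 1), efficacy=(1, 2, 3, 60, 4, 5)),
    ]
    curve = lfp_strategy_curve(hs, "efficacy")
    assert curve.probability == pytest.approx((1/3, 2/3, 2/3, 1.0, 1.0, 1.0))
    assert curve.n_hemispheres == 3


def test_lfp_curve_perfect_when_rankings_coincide():
    hs = [make_hemisphere(h) for h in "xyz"]  # beta and efficacy both descending
    curve = lfp_strategy_curve(hs, "efficacy")
    assert curve.probability == (1.0,) * 6
    with pytest.raises(ValueError):
        lfp_strategy_curve([], "efficacy")


def test_curves_monotone_and_exhaustive_on_random_cohorts():
    cfg = SimulationConfig(n_hemispheres=25, coupling=0.4, seed=3)
    cohort = generate_cohort(cfg, synthesize_lfp=False)
    for criterion in ("efficacy", "tw"):
        for subset in ("all", "beta_peak_only"):
            c = lfp_strategy_curve(cohort.datasets, criterion, subset=subset)
            assert all(b >= a for a, b in zip(c.probability, c.probability[1:]))
            assert c.probability[-1] == 1.0  # k=6 screens everything


def test_random_curve_is_exactly_k_over_six():
    c = random_strategy_curve()
    assert c.probability == tuple(k / 6 for k in range(1, 7))
    assert c.probability[0] == pytest.approx(1 / 6)
    assert c.probability[2] == 0.5
    assert c.probability[5] == 1.0


def test_best_clinical_contact_tw_independent_of_efficacy():
    h = make_hemisphere(efficacy=(60, 1, 2, 3, 4, 5), tw=(0.1, 0.2, 0.3, 2.0, 0.4, 0.5))
    assert best_clinical_contact(h, "efficacy") == 2
    assert best_clinical_contact(h, "tw") == 5


def test_top2_vs_rest_constant_metric_gives_zero_t():
    hs = [make_hemisphere(h, efficacy=(20,) * 6) for h in "abcd"]
    cmp = top2_vs_rest(hs, "efficacy")
    assert cmp.test.statistic == 0.0
    assert cmp.top2_means == cmp.rest_means


def test_top2_vs_rest_positive_under_coupling():
    """With beta and clinic driven by one source, top-2 beats the rest."""
    cfg = SimulationConfig(n_hemispheres=40, coupling=0.8, seed=5)
    cohort = generate_cohort(cfg, synthesize_lfp=False)
    for metric in ("efficacy", "tw"):
        cmp = top2_vs_rest(cohort.datasets, metric)
        assert cmp.top2_mean > cmp.rest_mean
        assert cmp.test.statistic > 0


def test_dorsal_level_tally():
    hs = [make_hemisphere(str(i), stn_level=lvl)
          for i, lvl in enumerate(["dorsal", "dorsal", "middle"])]
    assert dorsal_level_tally(hs) == {"ventral": 0, "middle": 1, "dorsal": 2}
    assert dorsal_level_tally([]) == {"ventral": 0, "middle": 0, "dorsal": 0}
    with pytest.raises(ValueError, match="unknown STN level"):
        dorsal_level_tally([make_hemisphere(stn_level="apex")])
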