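"""Ground-truth structure and determinism of the cohort generator."""

import numpy as np
import pytest

from dirlfp.ranking import rank_by_beta
from dirlfp.simulate import (
    SimulationConfig,
    generate_cohort,
    simulate_hemisphere_lfp,
    simulate_review,
)
from dirlfp.stats import one_sample_t, spearman_rho


def test_invalid_config_lists_fields():
    with pytest.raises(ValueError) as err:
        SimulationConfig(peak_prob=1.5, beta_amp=-1.0)
    assert "peak_prob" in str(err.value) and "beta_amp" in str(err.value)


def test_zero_decay_zero_noise_identical_channels(lead):
    cfg = SimulationConfig(
        duration_s=20.0, fs=250.0, angular_decay=0.0, level_decay=0.0,
        one_over_f_scale=0.0, noise_floor=0.0, peak_prob=1.0, seed=9,
    )
    rec, _ = simulate_hemisphere_lfp(cfg, np.random.default_rng(9), lead)
    for cid in lead.segmented_ids[1:]:
        assert np.array_equal(rec.channel(cid), rec.channel(2))


def test_source_geometry_sets_band_power(lead):
    """Source at angle 0, level 3: contact 5 carries maximal beta power and
    contact 2 leads level 2 (the aligned-pair motif)."""
    cfg = SimulationConfig(
        duration_s=20.0, fs=250.0, source_angle_deg=0.0, source_level=3.0,
        beta_freq=20.0, one_over_f_scale=0.0, noise_floor=0.0,
        peak_prob=1.0, seed=9,
    )
    rec, truth = simulate_hemisphere_lfp(cfg, np.random.default_rng(9), lead)
    power = {cid: rec.channel(cid).var() for cid in lead.segmented_ids}
    assert max(power, key=power.get) == 5
    level2 = {c: power[c] for c in (2, 3, 4)}
    assert max(level2, key=level2.get) == 2
    assert truth.attenuation[5] == max(truth.attenuation.values())


def test_fixed_seed_bit_identical(lead):
    cfg = SimulationConfig(duration_s=10.0, fs=250.0, n_hemispheres=2, seed=21)
    a = generate_cohort(cfg, keep_recordings=True)
    b = generate_cohort(cfg, keep_recordings=True)
    for hid in a.recordings:
        assert np.array_equal(a.recordings[hid].samples, b.recordings[hid].samples)
    for ha, hb in zip(a.datasets, b.datasets):
        assert {c: v.value for c, v in ha.beta.items()} == \
               {c: v.value for c, v in hb.beta.items()}


def test_review_noise_free_links_clinic_to_beta(lead):
    cfg = SimulationConfig(
        coupling=0.8, efficacy_noise_sd=0.0, tw_noise_sd=0.0,
        effect_noise_sd=0.0, n_hemispheres=30, seed=4, beta_score_noise_sd=0.0,
    )
    cohort = generate_cohort(cfg, synthesize_lfp=False)
    for h, t in zip(cohort.datasets, cohort.truths):
        best_eff = max(h.clinical, key=lambda c: h.clinical[c].efficacy)
        best_beta = max(t.true_beta_power, key=t.true_beta_power.get)
        assert best_eff == best_beta  # monotone link, no noise
        tw_order = sorted(h.clinical, key=lambda c: -h.clinical[c].tw)
        prox_order = sorted(t.attenuation, key=lambda c: -t.attenuation[c])
        assert tw_order == prox_order


def test_zero_coupling_decouples_efficacy_from_beta():
    """At coupling=0 the per-hemisphere beta-efficacy correlation is null:
    a one-sample t over 200 hemispheres fails to reject independence."""
    cfg = SimulationConfig(n_hemispheres=200, coupling=0.0, seed=8)
    cohort = generate_cohort(cfg, synthesize_lfp=False)
    rhos = []
    for h in cohort.datasets:
        ids = h.contact_ids
        rho = spearman_rho([h.beta[c].value for c in ids],
                           [h.clinical[c].efficacy for c in ids])
        if np.isfinite(rho):
            rhos.append(rho)
    assert one_sample_t(rhos).p > 0.01


def test_no_peak_fraction_matches_binomial():
    """Across many seeds the generated no-peak fraction centers on 7/19."""
    fractions = []
    for seed in range(500):
        cfg = SimulationConfig(n_hemispheres=19, seed=seed)
        cohort = generate_cohort(cfg, synthesize_lfp=False)
        fractions.append(np.mean([not t.has_peak for t in cohort.truths]))
    p = 7 / 19
    se = np.sqrt(p * (1 - p) / (500 * 19))
    assert abs(np.mean(fractions) - p) < 4 * se


def test_top2_hit_rate_monotone_in_coupling():
    """The k=2 hit probability of the beta-guided strategy grows with the
    beta-clinic coupling strength (trend over a 5-value grid, 200 replicate
    cohorts each)."""
    from dirlfp.ranking import lfp_strategy_curve

    couplings = [0.0, 0.25, 0.5, 0.75, 1.0]
    means = []
    for ci, coupling in enumerate(couplings):
        vals = []
        for rep in range(200):
            cfg = SimulationConfig(n_hemispheres=19, coupling=coupling,
                                   seed=10_000 * ci + rep)
            cohort = generate_cohort(cfg, synthesize_lfp=False)
            vals.append(lfp_strategy_curve(cohort.datasets,
                                           "efficacy").probability[1])
        means.append(np.mean(vals))
    assert spearman_rho(couplings, means) == pytest.approx(1.0)


def test_empty_cohort_is_valid():
    cohort = generate_cohort(SimulationConfig(n_hemispheres=0, seed=1),
                             synthesize_lfp=False)
    assert cohort.datasets == [] and cohort.truths == []


def test_simulated_review_is_internally_consistent(lead, rng):
    cfg = SimulationConfig(seed=2)
    _, truth = simulate_hemisphere_lfp(
        SimulationConfig(duration_s=10.0, fs=250.0, seed=2), rng, lead)
    reviews = simulate_review(cfg, truth, rng)
    assert set(reviews) == set(lead.segmented_ids)
    for r in reviews.values():
        assert r.rigidity_baseline >= 2
        assert r.effect_threshold >= 0
        if r.side_effect_threshold is not None:
            assert r.side_effect_threshold >= r.effect_threshold
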