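"""Synthetic cohort generator: behavior, forward hemodynamics, optics."""

import numpy as np
import pytest

from nirspt.behavior import code_response
from nirspt.glm import build_regressor
from nirspt.preprocess import optical_to_hemo
from nirspt.simulate import (
    DEFAULT_DPF,
    DEFAULT_EXTINCTION,
    BehaviorPolicy,
    NoiseModel,
    SUBGROUPS,
    default_planted_activation,
    hemo_to_optical,
    inject_spikes,
    simulate_behavior,
    simulate_cohort,
    simulate_hemodynamics,
)


@pytest.mark.parametrize("base", ["egocentric", "altercentric"])
def test_zero_switch_policy_codes_base_perspective(trials, base):
    """With switch probability 0 every coded response is the base
    perspective."""
    policy = BehaviorPolicy(base, switch_probability=0.0)
    responses = simulate_behavior(policy, trials, seed=0)
    coded = [
        code_response(t.target_side_participant, key)
        for t, (key, _) in zip(trials, responses)
    ]
    assert all(c == base for c in coded)


def test_switch_probability_is_binomial(trials):
    """At switch probability 0.5 the coded-altercentric fraction over 10^4
    trials lies within 3 Monte-Carlo SE of 0.5 (binomial oracle)."""
    policy = BehaviorPolicy("altercentric", switch_probability=0.5)
    long_trials = trials * 417  # 10,008 trials
    responses = simulate_behavior(policy, long_trials, seed=1)
    coded = [
        code_response(t.target_side_participant, key)
        for t, (key, _) in zip(long_trials, responses)
    ]
    frac = np.mean([c == "altercentric" for c in coded])
    se = 0.5 / np.sqrt(len(long_trials))
    assert abs(frac - 0.5) < 3 * se


def test_rt_lognormal_mean_matches_closed_form(trials):
    """Sample mean RT matches exp(mu + sigma^2/2) within 3 SE."""
    policy = BehaviorPolicy(
        "egocentric",
        switch_probability=0.0,
        rt_log_mean=7.0,
        rt_log_sd=0.3,
        rt_altercentric_shift=0.0,
        rt_switch_shift=0.0,
    )
    rts = np.array([rt for _, rt in simulate_behavior(policy, trials * 417, seed=2)])
    expected = np.exp(7.0 + 0.3**2 / 2)
    sd = expected * np.sqrt(np.exp(0.3**2) - 1)
    assert abs(rts.mean() - expected) < 3 * sd / np.sqrt(len(rts))


def test_noise_free_forward_model_is_linear(timeline, roi_map, montage, hrf):
    """Zero betas give zero traces; beta B gives exactly B x regressor."""
    zeros = {r: 0.0 for r in roi_map}
    hemo = simulate_hemodynamics(
        timeline, zeros, roi_map, NoiseModel.none(), 0, montage=montage, hrf=hrf
    )
    assert not np.any(hemo.o2hb)
    assert not np.any(hemo.hhb)

    betas = {r: 1.7 for r in roi_map}
    hemo = simulate_hemodynamics(
        timeline, betas, roi_map, NoiseModel.none(), 0, montage=montage, hrf=hrf
    )
    reg = build_regressor(timeline.stimulus_onset_s, hrf, hemo.n_samples)
    np.testing.assert_allclose(hemo.o2hb, np.tile(1.7 * reg, (44, 1)), atol=1e-12)
    np.testing.assert_allclose(hemo.hhb, -0.5 * hemo.o2hb, atol=1e-12)


def test_hemodynamics_deterministic(timeline, roi_map, montage, hrf):
    betas = {r: 0.5 for r in roi_map}
    a = simulate_hemodynamics(timeline, betas, roi_map, NoiseModel(), 42, montage=montage, hrf=hrf)
    b = simulate_hemodynamics(timeline, betas, roi_map, NoiseModel(), 42, montage=montage, hrf=hrf)
    np.testing.assert_array_equal(a.o2hb, b.o2hb)
    np.testing.assert_array_equal(a.hhb, b.hhb)


def test_missing_channel_in_roi_map_raises(timeline, montage, hrf):
    partial = {"left_IFG": [1, 2]}
    with pytest.raises(ValueError, match="missing from the ROI map"):
        simulate_hemodynamics(
            timeline, {"left_IFG": 1.0}, partial, NoiseModel.none(), 0,
            montage=montage, hrf=hrf,
        )


def test_mbll_forward_matches_hand_formula(montage):
    """Unit O2Hb, zero HHb: ΔOD per wavelength equals ε_O2Hb·d·DPF."""
    from nirspt.containers import HemoTimeSeries

    hemo = HemoTimeSeries(o2hb=np.ones((44, 5)), hhb=np.zeros((44, 5)))
    opt = hemo_to_optical(hemo, montage=montage)
    od = opt.optical_density()
    for w in range(2):
        expected = DEFAULT_EXTINCTION[w, 0] * 1e-3 * 3.0 * DEFAULT_DPF[w]
        np.testing.assert_allclose(od[:, :, w], expected, rtol=1e-12)

    zero = HemoTimeSeries(o2hb=np.zeros((44, 5)), hhb=np.zeros((44, 5)))
    opt0 = hemo_to_optical(zero, montage=montage)
    np.testing.assert_array_equal(opt0.intensity, 1.0)


def test_mbll_round_trip(timeline, roi_map, montage, hrf):
    """Forward then inverse Beer-Lambert recovers concentrations to 1e-9
    relative accuracy, for the default and a random invertible ε matrix."""
    betas = {r: 0.8 for r in roi_map}
    hemo = simulate_hemodynamics(
        timeline, betas, roi_map, NoiseModel(), 3, montage=montage, hrf=hrf
    )
    scale = np.abs(hemo.o2hb).max()
    for eps in (None, np.array([[0.5, 1.2], [1.1, 0.4]])):
        opt = hemo_to_optical(hemo, montage=montage, coefficients=eps)
        back = optical_to_hemo(opt, coefficients=eps)
        assert np.abs(back.o2hb - hemo.o2hb).max() / scale < 1e-9
        assert np.abs(back.hhb - hemo.hhb).max() / scale < 1e-9


def test_singular_extinction_matrix_rejected(montage):
    from nirspt.containers import HemoTimeSeries

    hemo = HemoTimeSeries(o2hb=np.ones((44, 5)), hhb=np.zeros((44, 5)))
    with pytest.raises(ValueError, match="singular"):
        hemo_to_optical(hemo, montage=montage, coefficients=np.ones((2, 2)))


def test_spike_injection_disabled_is_identity(timeline, roi_map, montage, hrf):
    betas = {r: 0.5 for r in roi_map}
    hemo = simulate_hemodynamics(
        timeline, betas, roi_map, NoiseModel.none(), 0, montage=montage, hrf=hrf
    )
    opt = hemo_to_optical(hemo, montage=montage)
    out = inject_spikes(opt, NoiseModel.none(), seed=0)
    np.testing.assert_array_equal(out.intensity, opt.intensity)


def test_cohort_structure_and_determinism():
    cohort = simulate_cohort((2, 1, 1, 1), seed=11, include_optical=False)
    assert len(cohort) == 5
    assert [p.intended_subgroup for p in cohort] == [
        SUBGROUPS[0], SUBGROUPS[0], SUBGROUPS[1], SUBGROUPS[2], SUBGROUPS[3]
    ]
    again = simulate_cohort((2, 1, 1, 1), seed=11, include_optical=False)
    for a, b in zip(cohort, again):
        assert a.responses == b.responses
        assert a.covariates == b.covariates
        assert a.true_roi_betas == b.true_roi_betas

    single = simulate_cohort((1, 0, 0, 0), seed=0, include_optical=False)
    assert len(single) == 1
    assert single[0].intended_subgroup == "egocentric-consistent"


def test_cohort_substreams_stable_under_growth():
    """Enlarging a later subgroup leaves earlier participants untouched."""
    small = simulate_cohort((2, 1, 0, 0), seed=5, include_optical=False)
    large = simulate_cohort((2, 1, 2, 2), seed=5, include_optical=False)
    for a, b in zip(small, large):
        assert a.responses == b.responses


def test_planted_activation_covers_all_rois(roi_map):
    planted = default_planted_activation()
    for sg in SUBGROUPS:
        assert set(roi_map) <= set(planted[sg])
    # the altercentric-inconsistent subgroup carries the largest left-IFG beta
    lifg = {sg: planted[sg]["left_IFG"] for sg in SUBGROUPS}
    assert max(lifg, key=lifg.get) == "altercentric-inconsistent"
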