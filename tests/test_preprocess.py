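"""Signal-chain stages: filtering, CBSI, artifact correction, channel
repair, global-signal reduction, standardization, and stage composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from nirspt.containers import HemoTimeSeries
from nirspt.preprocess import (
    PreprocessConfig,
    bandpass,
    cbsi_merge,
    cbsi_session,
    component_correct,
    default_component_selector,
    detect_spike_train,
    flag_deviant_channels,
    global_signal_reduce,
    interpolate_channels,
    optical_to_hemo,
    preprocess_session,
    zscore_signal,
)
from nirspt.simulate import NoiseModel, hemo_to_optical, simulate_cohort

FS = 10.0


def _steady_amplitude(freq, low, high, duration=600.0):
    t = np.arange(0, duration, 1 / FS)
    y = bandpass(np.sin(2 * np.pi * freq * t), low, high)
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    return np.abs(y[mid]).max()


def test_bandpass_removes_dc():
    x = np.full(6000, 3.7)
    y = bandpass(x, 0.01, 0.2)
    assert np.abs(y.mean()) < 1e-6 * 3.7


@pytest.mark.parametrize(
    "freq,band,lo,hi",
    [
        (0.05, (0.01, 0.2), 0.95, 1.05),  # band interior: retained
        (1.0, (0.01, 0.2), 0.0, 0.10),  # cardiac: attenuated
    ],
)
def test_bandpass_contracts(freq, band, lo, hi):
    amp = _steady_amplitude(freq, *band)
    assert lo <= amp <= hi


@pytest.mark.parametrize("freq", [0.001, 0.005, 0.02, 0.05, 0.1, 0.19, 0.5, 1.0, 2.0])
def test_bandpass_matches_frequency_response_oracle(freq):
    """Measured steady-state gain tracks |H(f)|^2 from sosfreqz (the
    forward-backward pass squares the magnitude response) within 2% of
    unity gain."""
    low, high = 0.01, 0.2
    sos = sps.butter(3, [low, high], btype="band", fs=FS, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=FS)
    expected = np.abs(h[0]) ** 2
    measured = _steady_amplitude(freq, low, high, duration=4000.0)
    assert measured == pytest.approx(expected, abs=0.02)


def test_bandpass_zero_phase():
    """A band-interior sinusoid is not shifted in time."""
    t = np.arange(0, 600, 1 / FS)
    x = np.sin(2 * np.pi * 0.05 * t)
    y = bandpass(x, 0.01, 0.2)
    mid = slice(1000, 5000)
    lag = np.argmax(np.correlate(y[mid], x[mid], mode="full")) - (len(x[mid]) - 1)
    assert lag == 0


def test_bandpass_rejects_bad_bands():
    x = np.zeros(100)
    for low, high in ((0.2, 0.1), (0.1, 6.0), (-0.1, 0.2)):
        with pytest.raises(ValueError):
            bandpass(x, low, high)


def test_cbsi_algebraic_identities():
    rng = np.random.default_rng(0)
    s = rng.standard_normal(500)
    s -= s.mean()
    merged, alpha = cbsi_merge(s, -s)
    assert alpha == pytest.approx(1.0)
    np.testing.assert_allclose(merged, s, atol=1e-12)

    merged, alpha = cbsi_merge(2 * s, -s)
    assert alpha == pytest.approx(2.0)
    np.testing.assert_allclose(merged, 2 * s, atol=1e-12)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    c=st.floats(min_value=1e-3, max_value=1e3),
    seed=st.integers(min_value=0, max_value=1000),
)
def test_cbsi_invariant_to_hhb_rescaling(c, seed):
    """α absorbs any positive rescaling of HHb."""
    rng = np.random.default_rng(seed)
    o2 = rng.standard_normal(400)
    hb = -0.5 * o2 + 0.1 * rng.standard_normal(400)
    base, _ = cbsi_merge(o2, hb)
    scaled, _ = cbsi_merge(o2, c * hb)
    np.testing.assert_allclose(scaled, base, atol=1e-9)


def test_cbsi_degenerate_channel():
    with pytest.raises(ValueError, match="zero variance"):
        cbsi_merge(np.arange(10.0), np.ones(10))


def _spiky_signal(rng, n_ch=44, T=2000, amp=20.0):
    X = 0.5 * rng.standard_normal((n_ch, T))
    t = np.arange(60)
    k = np.exp(-t / 10.0) - np.exp(-t / 2.0)
    spike = np.zeros(T)
    for onset in (300, 900, 1500):
        spike[onset : onset + 60] += k * amp
    return X + np.outer(rng.uniform(0.5, 1.5, n_ch), spike)


@pytest.mark.parametrize("method", ["ica", "pca"])
def test_component_correct_removes_planted_spike(method):
    """A shared high-amplitude spike component is attenuated >= 80%."""
    rng = np.random.default_rng(0)
    X = _spiky_signal(rng)
    train = detect_spike_train(X)
    corrected, n_removed, excluded = component_correct(
        X,
        method,
        removal_selector=lambda s: default_component_selector(s, spike_train=train),
    )
    assert n_removed >= 1
    assert not excluded
    assert np.abs(corrected).max() <= 0.2 * np.abs(X).max()


@pytest.mark.parametrize("method", ["ica", "pca"])
def test_component_correct_identity_when_nothing_selected(method):
    rng = np.random.default_rng(1)
    X = rng.standard_normal((10, 500))
    corrected, n_removed, excluded = component_correct(
        X, method, removal_selector=lambda s: []
    )
    assert n_removed == 0 and not excluded
    np.testing.assert_allclose(corrected, X, atol=1e-8)


def test_component_correct_exclusion_rule():
    """Removing 6 of 44 components (> 10%) marks the subject excluded."""
    rng = np.random.default_rng(2)
    X = rng.standard_normal((44, 500))
    _, n_removed, excluded = component_correct(
        X, "pca", removal_selector=lambda s: list(range(6))
    )
    assert n_removed == 6 and excluded
    _, n_removed, excluded = component_correct(
        X, "pca", removal_selector=lambda s: list(range(4))
    )
    assert n_removed == 4 and not excluded  # 4/44 < 10%


def test_flag_deviant_channels():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((10, 300))
    assert flag_deviant_channels(np.tile(X[0], (10, 1))) == set()
    X2 = X.copy()
    X2[4] *= 100
    assert flag_deviant_channels(X2, k=3) == {5}
    assert flag_deviant_channels(X2, k=np.inf) == set()


def test_interpolate_channels(montage):
    adjacency = montage.adjacency()
    rng = np.random.default_rng(4)
    X = rng.standard_normal((44, 200))
    out = interpolate_channels(X, [], adjacency)
    np.testing.assert_array_equal(out, X)

    out = interpolate_channels(X, [1], adjacency)
    good = sorted(adjacency[1])
    np.testing.assert_allclose(out[0], X[[g - 1 for g in good]].mean(axis=0))
    np.testing.assert_array_equal(out[1:], X[1:])

    all_nb = adjacency[1] | {1}
    with pytest.raises(ValueError, match="no good neighbours"):
        interpolate_channels(X, all_nb, adjacency)


def test_global_reduction_separates_global_from_local(montage):
    rng = np.random.default_rng(5)
    g = rng.standard_normal(500)
    X = np.tile(g, (44, 1))
    resid = global_signal_reduce(X, montage, sigma=40.0)
    assert np.sqrt((resid**2).mean()) <= 0.05 * np.sqrt((X**2).mean())

    local = np.zeros((44, 500))
    local[10] = np.sin(np.linspace(0, 20, 500))
    resid = global_signal_reduce(local, montage, sigma=40.0)
    assert np.abs(resid[10]).max() >= 0.8 * np.abs(local[10]).max()

    np.testing.assert_array_equal(
        global_signal_reduce(np.zeros((44, 100)), montage), np.zeros((44, 100))
    )


def test_global_reduction_preserves_shape(montage):
    rng = np.random.default_rng(6)
    X = rng.standard_normal((44, 321))
    assert global_signal_reduce(X, montage).shape == X.shape


def test_zscore_properties():
    rng = np.random.default_rng(7)
    x = rng.standard_normal((3, 400)) * 5 + 2
    z = zscore_signal(x)
    np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-10)
    np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-10)
    np.testing.assert_allclose(zscore_signal(3.2 * x - 7.0), z, atol=1e-10)
    with pytest.raises(ValueError, match="constant"):
        zscore_signal(np.vstack([x[0], np.ones(400)]))


def test_mbll_inverse_hand_case(montage):
    """A ΔOD built from unit concentrations and a printed ε matrix inverts
    back to (1, 1)."""
    eps = np.array([[0.5, 1.2], [1.1, 0.4]])
    hemo = HemoTimeSeries(o2hb=np.ones((44, 3)), hhb=np.ones((44, 3)))
    opt = hemo_to_optical(hemo, montage=montage, coefficients=eps)
    back = optical_to_hemo(opt, coefficients=eps)
    np.testing.assert_allclose(back.o2hb, 1.0, rtol=1e-9)
    np.testing.assert_allclose(back.hhb, 1.0, rtol=1e-9)


def test_session_stage_composition(montage):
    """With the optional stages off, the pipeline equals the hand
    composition zscore(band2(cbsi(band1(mbll)))) exactly."""
    cohort = simulate_cohort(
        (1, 0, 0, 0), seed=9, noise=NoiseModel(spike_rate_per_min=0.0)
    )
    optical = cohort[0].optical
    cfg = PreprocessConfig(
        component_correction="off", interpolate=False, global_reduce=False
    )
    merged, report = preprocess_session(optical, cfg)

    hemo = optical_to_hemo(optical)
    o2 = bandpass(hemo.o2hb, 0.001, 0.2)
    hb = bandpass(hemo.hhb, 0.001, 0.2)
    manual = cbsi_session(HemoTimeSeries(o2hb=o2, hhb=hb)).signal
    manual = zscore_signal(bandpass(manual, 0.01, 0.2))
    np.testing.assert_allclose(merged.signal, manual, atol=1e-10)
    assert not report.excluded


def test_session_exclusion_report(montage):
    """A session forced through wholesale component removal is excluded."""
    cohort = simulate_cohort(
        (1, 0, 0, 0),
        seed=10,
        noise=NoiseModel(spike_rate_per_min=6.0, spike_amplitude=0.05),
    )
    cfg = PreprocessConfig(component_correction="pca", kurtosis_threshold=-10.0)
    _, report = preprocess_session(cohort[0].optical, cfg)
    assert report.excluded
    assert report.n_components_removed > 0.10 * report.n_components
    assert "pca_correction" in report.stages
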