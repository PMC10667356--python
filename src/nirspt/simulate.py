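"""Synthetic cohort generator: behavior, hemodynamics, and raw optics.

The generator emulates the structure of the implicit spatial
perspective-taking study this package analyzes: 117 participants split
64/9/31/13 into egocentric-consistent / egocentric-inconsistent /
altercentric-consistent / altercentric-inconsistent subgroups, lognormal
reaction times with response-perspective and perspective-switch costs, and
44-channel two-wavelength optical recordings carrying planted ROI-level
activations under realistic fNIRS noise (1/f drift, cardiac/respiratory/
Mayer oscillations, a spatially smooth global component, and spike
artifacts injected into the raw intensities).

Every knob is explicit so each downstream stage can be tested against a
known ground truth; noise magnitudes are free parameters of the simulator,
not estimates of any real recording.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .containers import HemoTimeSeries, OpticalTimeSeries, WAVELENGTHS_NM
from .design import SessionTimeline, TrialSpec, build_timeline, generate_trial_set
from .glm import HrfKernel, build_regressor, canonical_hrf
from .montage import Montage, ROI_LABELS, build_montage, default_roi_map

SUBGROUPS = (
    "egocentric-consistent",
    "egocentric-inconsistent",
    "altercentric-consistent",
    "altercentric-inconsistent",
)

#: study cohort structure: subgroup sizes summing to 117
STUDY_SUBGROUP_SIZES = (64, 9, 31, 13)

#: extinction coefficients, mM^-1 cm^-1, rows = wavelengths (695, 830 nm),
#: columns = (O2Hb, HHb).  Approximate literature values; editable config.
DEFAULT_EXTINCTION = np.array(
    [
        [0.30, 1.85],  # 695 nm
        [0.974, 0.693],  # 830 nm
    ]
)

#: differential pathlength factor per wavelength
DEFAULT_DPF = np.array([6.0, 6.0])


@dataclass
class BehaviorPolicy:
    """Response policy of one simulated participant.

    ``base_perspective`` is the perspective adopted on non-switch trials;
    with probability ``switch_probability`` a trial is answered from the
    other perspective.  RTs are lognormal in ms with additive log-scale
    costs for altercentric responses and for switch trials.
    """

    base_perspective: str  # {"egocentric", "altercentric"}
    switch_probability: float = 0.0
    rt_log_mean: float = 7.85
    rt_log_sd: float = 0.45
    rt_altercentric_shift: float = 0.18
    rt_switch_shift: float = 0.15

    def __post_init__(self) -> None:
        if self.base_perspective not in ("egocentric", "altercentric"):
            raise ValueError(f"unknown perspective {self.base_perspective!r}")
        if not 0.0 <= self.switch_probability <= 1.0:
            raise ValueError("switch_probability must be in [0, 1]")
        if self.rt_log_sd <= 0:
            raise ValueError("rt_log_sd must be positive")


def default_policies() -> dict[str, BehaviorPolicy]:
    """Per-subgroup response policies emulating the four observed groups.

    Inconsistent participants switch on a fifth of trials: enough that
    the 23-of-24 consistency rule almost never classifies them as
    consistent, while the intended majority perspective is essentially
    never overturned (P(Bin(24, 0.2) >= 13) ~ 2e-4), so the cohort's
    group structure is preserved.
    """
    return {
        "egocentric-consistent": BehaviorPolicy("egocentric", 0.02),
        "egocentric-inconsistent": BehaviorPolicy("egocentric", 0.2),
        "altercentric-consistent": BehaviorPolicy("altercentric", 0.02),
        "altercentric-inconsistent": BehaviorPolicy("altercentric", 0.2),
    }


@dataclass
class NoiseModel:
    """Additive noise components of the simulated hemodynamic signal.

    All amplitudes are in the simulator's concentration units (nominally
    µM); each component can be disabled independently by setting it to
    zero, and disabling all of them reproduces the noise-free forward
    model exactly.
    """

    pink_noise_sd: float = 0.3
    cardiac_hz: float = 1.1
    cardiac_amplitude: float = 0.2
    respiratory_hz: float = 0.3
    respiratory_amplitude: float = 0.1
    mayer_hz: float = 0.1
    mayer_amplitude: float = 0.15
    global_component_sd: float = 0.5
    global_length_scale_mm: float = 80.0
    spike_rate_per_min: float = 0.5
    spike_amplitude: float = 0.02  # optical-density units, pre-inversion
    gain_jitter_sd: float = 0.05
    hhb_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        nyquist = 5.0
        for f in (self.cardiac_hz, self.respiratory_hz, self.mayer_hz):
            if not 0 < f < nyquist:
                raise ValueError(f"oscillation frequency {f} Hz outside (0, {nyquist})")
        for a in (
            self.pink_noise_sd,
            self.cardiac_amplitude,
            self.respiratory_amplitude,
            self.mayer_amplitude,
            self.global_component_sd,
            self.spike_rate_per_min,
            self.spike_amplitude,
            self.gain_jitter_sd,
            self.hhb_noise_sd,
        ):
            if a < 0:
                raise ValueError("noise amplitudes must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        """Noise-free model: pure forward hemodynamics."""
        return cls(
            pink_noise_sd=0.0,
            cardiac_amplitude=0.0,
            respiratory_amplitude=0.0,
            mayer_amplitude=0.0,
            global_component_sd=0.0,
            spike_rate_per_min=0.0,
            spike_amplitude=0.0,
            gain_jitter_sd=0.0,
            hhb_noise_sd=0.0,
        )


#: Planted per-subgroup ROI activations (z-units of the standardized
#: signal).  The qualitative ordering mirrors the reported group pattern:
#: the altercentric-inconsistent subgroup carries the largest left-IFG,
#: left-DLPFC and left-MC activations.
def default_planted_activation() -> dict[str, dict[str, float]]:
    table = {
        "left_IFG": (0.368, 0.013, 0.193, 1.061),
        "left_DLPFC": (0.174, -0.736, -0.171, 0.664),
        "right_DLPFC": (0.215, -0.238, -0.228, 0.288),
        "right_IFG": (0.370, -0.168, 0.200, 0.574),
        "left_IPL": (-0.838, -0.720, -0.877, 0.237),
        "right_IPL": (-0.418, -0.300, -0.638, 0.662),
        "left_MC": (1.108, 0.503, 0.697, 1.809),
        "right_MC": (-0.053, -0.343, 0.160, 0.727),
    }
    return {
        sg: {roi: table[roi][k] for roi in ROI_LABELS} for k, sg in enumerate(SUBGROUPS)
    }


def validate_planted(
    planted: Mapping[str, Mapping[str, float]], roi_map: Mapping[str, Sequence[int]]
) -> None:
    for sg in SUBGROUPS:
        if sg not in planted:
            raise ValueError(f"planted activation missing subgroup {sg}")
        missing = set(roi_map) - set(planted[sg])
        if missing:
            raise ValueError(f"planted activation for {sg} missing ROIs {missing}")


def simulate_behavior(
    policy: BehaviorPolicy,
    trials: Sequence[TrialSpec],
    seed: int | np.random.Generator,
) -> list[tuple[str, float]]:
    """Simulate one participant's keypresses and RTs.

    The key is chosen so that response coding recovers the intended
    perspective: an egocentric response presses the key on the target's
    side in the participant's frame; an altercentric response presses the
    opposite key.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for trial in trials:
        switch = rng.random() < policy.switch_probability
        if switch:
            perspective = (
                "altercentric"
                if policy.base_perspective == "egocentric"
                else "egocentric"
            )
        else:
            perspective = policy.base_perspective
        if perspective == "egocentric":
            key = trial.target_side_participant
        else:
            key = "right" if trial.target_side_participant == "left" else "left"
        mu = policy.rt_log_mean
        if perspective == "altercentric":
            mu += policy.rt_altercentric_shift
        if switch:
            mu += policy.rt_switch_shift
        rt_ms = float(np.exp(rng.normal(mu, policy.rt_log_sd)))
        out.append((key, rt_ms))
    return out


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f (power) noise via spectral shaping."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spectrum * scale, n)
    return x / x.std()


def _channel_betas(
    planted_rois: Mapping[str, float],
    roi_map: Mapping[str, Sequence[int]],
    montage: Montage,
) -> np.ndarray:
    betas = np.full(montage.n_channels, np.nan)
    for roi, chans in roi_map.items():
        for c in chans:
            betas[int(c) - 1] = planted_rois[roi]
    if np.any(np.isnan(betas)):
        missing = list(np.flatnonzero(np.isnan(betas)) + 1)
        raise ValueError(f"channels {missing} missing from the ROI map")
    return betas


def simulate_hemodynamics(
    timeline: SessionTimeline,
    planted_rois: Mapping[str, float],
    roi_map: Mapping[str, Sequence[int]],
    noise: NoiseModel,
    seed: int | np.random.Generator,
    montage: Montage | None = None,
    hrf: HrfKernel | None = None,
    hbr_ratio: float = 0.5,
) -> HemoTimeSeries:
    """Forward model: planted ROI betas -> per-channel concentration traces.

    ΔO2Hb(c, t) = β_ROI(c) · regressor(t) + noise; ΔHHb is an
    anticorrelated scaled copy (-``hbr_ratio`` × ΔO2Hb) plus independent
    1/f noise, matching the anticorrelation assumption that the CBSI merge
    exploits.  Spike artifacts are *not* added here; they contaminate the
    raw optics and are injected by :func:`inject_spikes`.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    montage = montage or build_montage()
    hrf = hrf or canonical_hrf(dt=1.0 / timeline.sampling_rate)
    fs = timeline.sampling_rate
    n_samples = int(np.ceil((timeline.duration_s + hrf.duration_s) * fs))
    regressor = build_regressor(timeline.stimulus_onset_s, hrf, n_samples)
    betas = _channel_betas(planted_rois, roi_map, montage)

    t = np.arange(n_samples) / fs
    n_ch = montage.n_channels
    o2hb = betas[:, None] * regressor[None, :]

    if noise.global_component_sd > 0:
        g = _pink_noise(rng, n_samples) * noise.global_component_sd
        lo = montage.coords_mm.min(axis=0)
        hi = montage.coords_mm.max(axis=0)
        center = lo + rng.random(2) * (hi - lo)
        d2 = np.sum((montage.coords_mm - center) ** 2, axis=1)
        weights = 0.5 + 0.5 * np.exp(-d2 / (2 * noise.global_length_scale_mm**2))
        o2hb = o2hb + weights[:, None] * g[None, :]

    for i in range(n_ch):
        if noise.pink_noise_sd > 0:
            o2hb[i] += noise.pink_noise_sd * _pink_noise(rng, n_samples)
        for f, a in (
            (noise.cardiac_hz, noise.cardiac_amplitude),
            (noise.respiratory_hz, noise.respiratory_amplitude),
            (noise.mayer_hz, noise.mayer_amplitude),
        ):
            if a > 0:
                o2hb[i] += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))

    if noise.gain_jitter_sd > 0:
        gains = 1.0 + noise.gain_jitter_sd * rng.standard_normal(n_ch)
        o2hb = o2hb * gains[:, None]

    hhb = -hbr_ratio * o2hb
    if noise.hhb_noise_sd > 0:
        for i in range(n_ch):
            hhb[i] += noise.hhb_noise_sd * _pink_noise(rng, n_samples)

    return HemoTimeSeries(o2hb=o2hb, hhb=hhb, sampling_rate=fs)


def hemo_to_optical(
    hemo: HemoTimeSeries,
    montage: Montage | None = None,
    coefficients: np.ndarray | None = None,
    dpf: np.ndarray | None = None,
    distance_mm: float = 30.0,
    i0: float = 1.0,
) -> OpticalTimeSeries:
    """Forward modified Beer-Lambert law: concentrations -> intensities.

    ΔOD(λ, t) = [ε_O2Hb(λ)·ΔO2Hb(t) + ε_HHb(λ)·ΔHHb(t)] · d · DPF(λ)
    with concentrations in µM, ε in mM⁻¹cm⁻¹ and d in cm, then
    I = I₀·10^(−ΔOD).
    """
    eps = np.asarray(coefficients if coefficients is not None else DEFAULT_EXTINCTION)
    dpf = np.asarray(dpf if dpf is not None else DEFAULT_DPF, dtype=float)
    if abs(np.linalg.det(eps)) < 1e-12:
        raise ValueError("extinction-coefficient matrix is singular")
    montage = montage or build_montage()
    d_cm = distance_mm / 10.0
    conc = np.stack([hemo.o2hb, hemo.hhb], axis=-1)  # (ch, T, 2) in µM
    od = (conc * 1e-3) @ eps.T  # (ch, T, 2) over wavelengths
    od = od * (d_cm * dpf)[None, None, :]
    intensity = i0 * 10.0 ** (-od)
    return OpticalTimeSeries(
        intensity=intensity,
        montage=montage,
        sampling_rate=hemo.sampling_rate,
        wavelengths_nm=WAVELENGTHS_NM,
        i0=i0,
        source_detector_mm=distance_mm,
    )


def inject_spikes(
    optical: OpticalTimeSeries,
    noise: NoiseModel,
    seed: int | np.random.Generator,
    tau_rise_s: float = 0.1,
    tau_decay_s: float = 1.0,
) -> OpticalTimeSeries:
    """Add biexponential spike transients (teeth-clench emulation) to the
    raw optical densities.

    Events arrive as a Poisson process at ``noise.spike_rate_per_min``;
    each event hits a random subset of channels with amplitudes scaled by
    ``noise.spike_amplitude`` (optical-density units) on both wavelengths.
    """
    if noise.spike_rate_per_min == 0 or noise.spike_amplitude == 0:
        return optical
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fs = optical.sampling_rate
    n = optical.n_samples
    duration_min = n / fs / 60.0
    n_events = rng.poisson(noise.spike_rate_per_min * duration_min)
    od = optical.optical_density()
    t_kernel = np.arange(0, 6 * tau_decay_s, 1.0 / fs)
    kernel = np.exp(-t_kernel / tau_decay_s) - np.exp(-t_kernel / tau_rise_s)
    kernel /= kernel.max()
    for _ in range(n_events):
        onset = rng.integers(0, n)
        hit = rng.random(optical.n_channels) < rng.uniform(0.3, 1.0)
        amps = noise.spike_amplitude * rng.uniform(0.5, 1.5, optical.n_channels)
        seg = slice(onset, min(n, onset + len(kernel)))
        piece = kernel[: seg.stop - seg.start]
        for ch in np.flatnonzero(hit):
            od[ch, seg, :] += amps[ch] * piece[:, None]
    intensity = optical.i0 * 10.0 ** (-od)
    return replace(optical, intensity=intensity)


@dataclass
class SimulatedParticipant:
    """Ground-truth bundle for one simulated participant."""

    participant_id: str
    intended_subgroup: str
    trials: list[TrialSpec]
    responses: list[tuple[str, float]]  # (key, rt_ms)
    timeline: SessionTimeline
    covariates: dict
    true_roi_betas: dict[str, float]
    optical: OpticalTimeSeries | None = None


#: per-subgroup PFT score distributions (mean, sd) emulating the cohort's
#: consistent > inconsistent spatial-ability pattern
DEFAULT_PFT_PARAMS = {
    "egocentric-consistent": (7.69, 1.81),
    "egocentric-inconsistent": (6.44, 2.13),
    "altercentric-consistent": (7.23, 2.05),
    "altercentric-inconsistent": (6.46, 1.71),
}


def simulate_cohort(
    subgroup_sizes: Sequence[int] = STUDY_SUBGROUP_SIZES,
    policies: Mapping[str, BehaviorPolicy] | None = None,
    planted: Mapping[str, Mapping[str, float]] | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    between_subject_sd: float = 0.75,
    include_optical: bool = True,
    montage: Montage | None = None,
    roi_map: Mapping[str, Sequence[int]] | None = None,
    pft_params: Mapping[str, tuple[float, float]] | None = None,
    hbr_ratio: float = 0.5,
) -> list[SimulatedParticipant]:
    """Simulate a full cohort with per-participant independent substreams.

    Each participant draws from a child stream spawned off the master
    seed, so enlarging a later subgroup never perturbs earlier
    participants' data.  ``between_subject_sd`` is the SD (z-units) of the
    participant-level scatter around the planted subgroup ROI means.
    ``include_optical=False`` skips the (comparatively expensive) optical
    forward model for behavior-only analyses.
    """
    if len(subgroup_sizes) != 4:
        raise ValueError("subgroup_sizes must have 4 entries")
    if any(s < 0 for s in subgroup_sizes):
        raise ValueError("subgroup sizes must be non-negative")
    policies = dict(policies or default_policies())
    planted = planted or default_planted_activation()
    noise = noise or NoiseModel()
    montage = montage or build_montage()
    roi_map = roi_map or default_roi_map()
    pft_params = pft_params or DEFAULT_PFT_PARAMS
    validate_planted(planted, roi_map)

    total = int(sum(subgroup_sizes))
    children = np.random.SeedSequence(seed).spawn(total)
    hrf = canonical_hrf()
    cohort: list[SimulatedParticipant] = []
    slot = 0
    for sg, size in zip(SUBGROUPS, subgroup_sizes):
        for _ in range(int(size)):
            rng = np.random.default_rng(children[slot])
            pid = f"P{slot + 1:03d}"
            trials = generate_trial_set(int(rng.integers(2**31)))
            responses = simulate_behavior(policies[sg], trials, rng)
            rts = [rt for _, rt in responses]
            timeline = build_timeline(trials, rts, int(rng.integers(2**31)))
            mu, sd_ = pft_params[sg]
            pft = int(np.clip(np.round(rng.normal(mu, sd_)), 0, 10))
            covariates = {
                "pft_score": pft,
                "sex": "female" if rng.random() < 0.72 else "male",
                "age": float(np.clip(np.round(rng.normal(24.4, 4.0), 1), 18, 37)),
                "handedness": "right" if rng.random() < 0.93 else "left",
            }
            true_betas = {
                roi: planted[sg][roi] + between_subject_sd * rng.standard_normal()
                for roi in roi_map
            }
            optical = None
            if include_optical:
                hemo = simulate_hemodynamics(
                    timeline,
                    true_betas,
                    roi_map,
                    noise,
                    rng,
                    montage=montage,
                    hrf=hrf,
                    hbr_ratio=hbr_ratio,
                )
                optical = hemo_to_optical(hemo, montage=montage)
                optical = inject_spikes(optical, noise, rng)
            cohort.append(
                SimulatedParticipant(
                    participant_id=pid,
                    intended_subgroup=sg,
                    trials=trials,
                    responses=responses,
                    timeline=timeline,
                    covariates=covariates,
                    true_roi_betas=true_betas,
                    optical=optical,
                )
            )
            slot += 1
    return cohort


def simulate_roi_betas(
    subgroup_sizes: Sequence[int],
    planted: Mapping[str, Mapping[str, float]] | None = None,
    between_subject_sd: float = 0.75,
    seed: int | np.random.Generator = 0,
    rois: Sequence[str] = ROI_LABELS,
):
    """Fast path: draw participant-level ROI activations directly.

    Samples each participant's ROI beta from the planted subgroup mean
    plus Gaussian between-subject scatter — the distribution the full
    pipeline's GLM stage estimates — without simulating optics.  Used for
    replicated power / type-I studies of the group statistics.

    Returns (betas array of shape (N, len(rois)), subgroup labels list).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    planted = planted or default_planted_activation()
    labels: list[str] = []
    rows = []
    for sg, size in zip(SUBGROUPS, subgroup_sizes):
        for _ in range(int(size)):
            rows.append(
                [
                    planted[sg][roi] + between_subject_sd * rng.standard_normal()
                    for roi in rois
                ]
            )
            labels.append(sg)
    return np.asarray(rows), labels
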