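"""fNIRS signal chain: raw optics to the z-standardized merged signal.

Stage order (each stage individually toggleable):

1. modified Beer-Lambert inversion (optical density -> ΔO2Hb/ΔHHb)
2. band-pass 0.001-0.2 Hz (zero-phase Butterworth, order 3)
3. CBSI merge of O2Hb and HHb into one signal
4. ICA- or PCA-based component removal for spike/systemic artifacts
   (conditional on artifact severity; removing more than 10% of
   components excludes the participant)
5. interpolation of amplitude-deviant channels from montage neighbours
6. band-pass 0.01-0.2 Hz
7. spatial-Gaussian PCA global-signal reduction (σ = 40 mm)
8. per-channel z-standardization

The correlation-based signal improvement (CBSI) merge scales HHb by
α = sd(O2Hb)/sd(HHb) and averages it, negated, with O2Hb, exploiting the
expected anticorrelation of the two chromophores to suppress motion and
systemic components they share with equal sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import PCA, FastICA

from .containers import HemoTimeSeries, MergedSignal, OpticalTimeSeries
from .montage import Montage
from .simulate import DEFAULT_DPF, DEFAULT_EXTINCTION


def optical_to_hemo(
    optical: OpticalTimeSeries,
    coefficients: np.ndarray | None = None,
    dpf: np.ndarray | None = None,
) -> HemoTimeSeries:
    """Invert the modified Beer-Lambert law per channel and sample.

    Solves ΔOD(λ) = Σ_c ε_c(λ)·Δc·d·DPF(λ) for (ΔO2Hb, ΔHHb) with the
    2x2 extinction matrix; concentrations come out in µM.
    """
    eps = np.asarray(coefficients if coefficients is not None else DEFAULT_EXTINCTION)
    dpf = np.asarray(dpf if dpf is not None else DEFAULT_DPF, dtype=float)
    if np.any(dpf <= 0):
        raise ValueError("DPF values must be positive")
    if abs(np.linalg.det(eps)) < 1e-12:
        raise ValueError("extinction-coefficient matrix is singular")
    od = optical.optical_density()  # (ch, T, 2)
    d_cm = optical.source_detector_mm / 10.0
    eff = eps * 1e-3 * (d_cm * dpf)[:, None]  # maps µM -> OD
    conc = od @ np.linalg.inv(eff).T  # (ch, T, 2) = (O2Hb, HHb)
    return HemoTimeSeries(
        o2hb=conc[..., 0], hhb=conc[..., 1], sampling_rate=optical.sampling_rate
    )


def bandpass(
    signal: np.ndarray,
    low_hz: float,
    high_hz: float,
    fs: float = 10.0,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along time.

    Accepts 1-D traces or (channels x time) matrices.
    """
    nyquist = fs / 2.0
    if not 0 <= low_hz < high_hz < nyquist:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy "
            f"0 <= low < high < {nyquist} (Nyquist)"
        )
    if low_hz == 0:
        sos = sps.butter(order, high_hz, btype="low", fs=fs, output="sos")
    else:
        sos = sps.butter(order, [low_hz, high_hz], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)


def cbsi_merge(o2hb_channel: np.ndarray, hhb_channel: np.ndarray):
    """CBSI merge of one channel: ((O2Hb - α·HHb)/2, α) with
    α = sd(O2Hb)/sd(HHb)."""
    o2 = np.asarray(o2hb_channel, dtype=float)
    hb = np.asarray(hhb_channel, dtype=float)
    sd_hb = hb.std()
    if sd_hb == 0:
        raise ValueError("degenerate channel: HHb has zero variance")
    alpha = o2.std() / sd_hb
    return (o2 - alpha * hb) / 2.0, float(alpha)


def cbsi_session(hemo: HemoTimeSeries) -> MergedSignal:
    merged = np.empty_like(hemo.o2hb)
    alphas = np.empty(hemo.n_channels)
    for i in range(hemo.n_channels):
        merged[i], alphas[i] = cbsi_merge(hemo.o2hb[i], hemo.hhb[i])
    return MergedSignal(signal=merged, alpha=alphas, sampling_rate=hemo.sampling_rate)


def detect_spike_train(signal: np.ndarray, z: float = 5.0) -> np.ndarray:
    """Fraction of channels per sample exceeding a robust |z| threshold.

    Channels are centred by their median and scaled by 1.4826·MAD; a
    sample counts as spiking on a channel when |z| > ``z``.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True) * 1.4826
    mad = np.where(mad == 0, np.inf, mad)
    return np.mean(np.abs(x - med) / mad > z, axis=0)


def default_component_selector(
    sources: np.ndarray,
    kurtosis_threshold: float = 10.0,
    spike_train: np.ndarray | None = None,
    corr_threshold: float = 0.8,
) -> list[int]:
    """Select artifact components by time-course shape.

    A component is selected if its excess-kurtosis exceeds the threshold
    (heavy-tailed transients) or its time course correlates |r| >
    ``corr_threshold`` with the detected spike train.  This automates the
    visual amplitude-plot comparison such selections are normally based
    on and is necessarily a stand-in for expert judgment.
    """
    from scipy.stats import kurtosis

    selected = []
    for k in range(sources.shape[1]):
        s = sources[:, k]
        if kurtosis(s, fisher=True) > kurtosis_threshold:
            selected.append(k)
            continue
        if spike_train is not None and spike_train.std() > 0 and s.std() > 0:
            r = np.corrcoef(s, spike_train)[0, 1]
            if abs(r) > corr_threshold:
                selected.append(k)
    return selected


def component_correct(
    signal: np.ndarray,
    method: str,
    removal_selector: Callable[[np.ndarray], Sequence[int]] | None = None,
    max_fraction: float = 0.10,
    random_state: int = 0,
):
    """Decompose across channels, zero selected components, reconstruct.

    ``method`` is "ica" (FastICA) or "pca".  ``removal_selector`` maps the
    (time x components) source matrix to indices to remove; the default
    selector uses kurtosis.  If more than ``max_fraction`` of components
    must be removed the participant is marked excluded (the correction is
    still returned for inspection).

    Returns ``(corrected, n_removed, excluded)``.
    """
    X = np.asarray(signal, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (channels x time) matrix with >= 2 channels")
    n_comp = X.shape[0]
    if method == "ica":
        dec = FastICA(
            n_components=n_comp,
            random_state=random_state,
            max_iter=1000,
            whiten="unit-variance",
        )
    elif method == "pca":
        dec = PCA(n_components=n_comp, random_state=random_state)
    else:
        raise ValueError(f"unknown method {method!r}")
    try:
        sources = dec.fit_transform(X.T)  # (T, k)
    except Exception as exc:  # pragma: no cover - decomposition failure
        raise RuntimeError(
            f"{method} decomposition failed on shape {X.shape}: {exc}"
        ) from exc
    selector = removal_selector or default_component_selector
    removed = list(selector(sources))
    kept = sources.copy()
    if removed:
        kept[:, removed] = 0.0
    corrected = dec.inverse_transform(kept).T
    excluded = len(removed) / n_comp > max_fraction
    return corrected, len(removed), excluded


def flag_deviant_channels(signal: np.ndarray, k: float = 3.0) -> set[int]:
    """Channels whose peak-to-peak amplitude exceeds ``k`` times the
    median peak-to-peak amplitude of the *other* channels.

    Returns 1-based channel indices.
    """
    X = np.asarray(signal, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 channels")
    ptp = np.ptp(X, axis=1)
    flagged = set()
    for i in range(len(ptp)):
        others = np.delete(ptp, i)
        ref = np.median(others)
        if ptp[i] > k * ref:
            flagged.add(i + 1)
    return flagged


def interpolate_channels(
    signal: np.ndarray,
    bad_channels: Iterable[int],
    adjacency: dict[int, set[int]],
) -> np.ndarray:
    """Replace each bad channel by the sample-wise unweighted mean of its
    good montage neighbours (1-based channel ids)."""
    X = np.array(signal, dtype=float)
    bad = set(int(b) for b in bad_channels)
    out = X.copy()
    for b in sorted(bad):
        good = [n for n in adjacency.get(b, set()) if n not in bad]
        if not good:
            raise ValueError(
                f"channel {b} has no good neighbours to interpolate from "
                f"(bad set: {sorted(bad)})"
            )
        out[b - 1] = X[[g - 1 for g in good]].mean(axis=0)
    return out


def global_signal_reduce(
    signal: np.ndarray, montage: Montage, sigma: float = 40.0
) -> np.ndarray:
    """Remove the spatially smooth (global/systemic) part of the signal.

    The channels x time matrix is decomposed by SVD; each spatial loading
    vector is smoothed over the 2-D scalp coordinates with a Gaussian
    kernel of standard deviation ``sigma`` (mm).  The reconstruction from
    the smoothed loadings estimates the spatially global component, which
    is subtracted.  A spatially uniform signal is removed entirely while
    single-channel (spatially sharp) activity passes nearly unchanged.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = np.asarray(signal, dtype=float)
    if X.shape[0] != montage.n_channels:
        raise ValueError(
            f"signal has {X.shape[0]} channels but montage coordinates "
            f"cover {montage.n_channels}"
        )
    coords = montage.coords_mm
    if not np.all(np.isfinite(coords)):
        raise ValueError("montage coordinates contain non-finite values")
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    G = np.exp(-d2 / (2.0 * sigma**2))
    G /= G.sum(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    smooth = (G @ U) * s
    return X - smooth @ Vt


def zscore_signal(signal: np.ndarray) -> np.ndarray:
    """Standardize each channel to mean 0, SD 1 (sample SD)."""
    X = np.atleast_2d(np.asarray(signal, dtype=float))
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0]) + 1
        raise ValueError(f"channel {bad} is constant; cannot z-standardize")
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return out if np.asarray(signal).ndim == 2 else out[0]


@dataclass
class PreprocessConfig:
    """Every stage toggle and threshold of the preprocessing chain."""

    band1_hz: tuple[float, float] = (0.001, 0.2)
    band2_hz: tuple[float, float] = (0.01, 0.2)
    filter_order: int = 3
    band1: bool = True
    band2: bool = True
    component_correction: str = "auto"  # auto | ica | pca | off
    spike_z: float = 5.0
    correction_trigger_fraction: float = 0.001  # spike samples to trigger any
    pca_trigger_fraction: float = 0.01  # spike samples to prefer PCA over ICA
    kurtosis_threshold: float = 10.0
    spike_corr_threshold: float = 0.8
    max_component_fraction: float = 0.10
    interpolate: bool = True
    deviant_k: float = 3.0
    global_reduce: bool = True
    global_sigma_mm: float = 40.0
    zscore: bool = True
    extinction: np.ndarray | None = None
    dpf: np.ndarray | None = None
    random_state: int = 0


@dataclass
class ExclusionReport:
    """Per-stage provenance and the subject-level exclusion verdict."""

    excluded: bool = False
    reason: str | None = None
    correction_method: str | None = None
    n_components_removed: int = 0
    n_components: int = 0
    spike_sample_fraction: float = 0.0
    deviant_channels: list[int] = field(default_factory=list)
    interpolated_channels: list[int] = field(default_factory=list)
    stages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "excluded": self.excluded,
            "reason": self.reason,
            "correction_method": self.correction_method,
            "n_components_removed": self.n_components_removed,
            "n_components": self.n_components,
            "spike_sample_fraction": self.spike_sample_fraction,
            "deviant_channels": self.deviant_channels,
            "interpolated_channels": self.interpolated_channels,
            "stages": self.stages,
        }


def preprocess_session(
    optical: OpticalTimeSeries,
    config: PreprocessConfig | None = None,
) -> tuple[MergedSignal, ExclusionReport]:
    """Run the full signal chain on one session.

    Returns the CBSI-merged, corrected, filtered, globally-reduced and
    z-standardized signal together with a provenance/exclusion report.
    """
    cfg = config or PreprocessConfig()
    report = ExclusionReport()
    fs = optical.sampling_rate

    hemo = optical_to_hemo(optical, cfg.extinction, cfg.dpf)
    report.stages.append("mbll")

    o2, hb = hemo.o2hb, hemo.hhb
    if cfg.band1:
        o2 = bandpass(o2, *cfg.band1_hz, fs=fs, order=cfg.filter_order)
        hb = bandpass(hb, *cfg.band1_hz, fs=fs, order=cfg.filter_order)
        report.stages.append(f"bandpass{cfg.band1_hz}")

    merged_obj = cbsi_session(HemoTimeSeries(o2hb=o2, hhb=hb, sampling_rate=fs))
    merged = merged_obj.signal
    report.stages.append("cbsi")

    if cfg.component_correction != "off":
        train = detect_spike_train(merged, z=cfg.spike_z)
        frac = float(np.mean(train > 0))
        report.spike_sample_fraction = frac
        method = None
        if cfg.component_correction in ("ica", "pca"):
            method = cfg.component_correction
        elif frac > cfg.correction_trigger_fraction:
            # too many high-amplitude artifact samples for stable ICA -> PCA
            method = "pca" if frac > cfg.pca_trigger_fraction else "ica"
        if method is not None:
            selector = lambda src: default_component_selector(  # noqa: E731
                src,
                kurtosis_threshold=cfg.kurtosis_threshold,
                spike_train=train,
                corr_threshold=cfg.spike_corr_threshold,
            )
            merged, n_removed, excluded = component_correct(
                merged,
                method,
                removal_selector=selector,
                max_fraction=cfg.max_component_fraction,
                random_state=cfg.random_state,
            )
            report.correction_method = method
            report.n_components_removed = n_removed
            report.n_components = merged.shape[0]
            report.stages.append(f"{method}_correction")
            if excluded:
                report.excluded = True
                report.reason = (
                    f"removed {n_removed}/{merged.shape[0]} components "
                    f"(> {cfg.max_component_fraction:.0%})"
                )
                # subject leaves the analysis set; no point running the
                # remaining stages on the gutted signal
                return (
                    MergedSignal(
                        signal=merged, alpha=merged_obj.alpha, sampling_rate=fs
                    ),
                    report,
                )

    if cfg.interpolate:
        deviant = flag_deviant_channels(merged, k=cfg.deviant_k)
        if deviant:
            merged = interpolate_channels(
                merged, deviant, optical.montage.adjacency()
            )
            report.deviant_channels = sorted(deviant)
            report.interpolated_channels = sorted(deviant)
            report.stages.append("interpolation")

    if cfg.band2:
        merged = bandpass(merged, *cfg.band2_hz, fs=fs, order=cfg.filter_order)
        report.stages.append(f"bandpass{cfg.band2_hz}")

    if cfg.global_reduce:
        merged = global_signal_reduce(
            merged, optical.montage, sigma=cfg.global_sigma_mm
        )
        report.stages.append(f"global_reduce(sigma={cfg.global_sigma_mm})")

    if cfg.zscore:
        merged = zscore_signal(merged)
        report.stages.append("zscore")

    return (
        MergedSignal(signal=merged, alpha=merged_obj.alpha, sampling_rate=fs),
        report,
    )
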