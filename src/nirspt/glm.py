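"""Task regressor construction and per-channel GLM activation estimates.

The activation measure is the ordinary-least-squares slope ("beta") of a
channel's preprocessed signal on a single task regressor: an impulse train
at the 24 stimulus onsets convolved with a canonical double-gamma
hemodynamic response function whose time-to-peak is 6.5 s, appropriate for
sensorimotor paradigms.  Channel betas are averaged within regions of
interest to give the participant-by-ROI activation table that all group
statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .montage import Montage, validate_roi_map


@dataclass
class HrfKernel:
    """Sampled, peak-normalized canonical HRF."""

    kernel: np.ndarray
    dt: float
    peak_time_s: float

    @property
    def duration_s(self) -> float:
        return len(self.kernel) * self.dt


@dataclass
class GlmResult:
    """Per-channel OLS fits of one participant's session."""

    beta: np.ndarray  # (n_channels,)
    intercept: np.ndarray
    residual_variance: np.ndarray
    channel_ids: np.ndarray


def canonical_hrf(
    peak_time_s: float = 6.5,
    dt: float = 0.1,
    duration_s: float = 30.0,
    undershoot_peak_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    shape_main: float = 6.0,
    shape_undershoot: float = 16.0,
) -> HrfKernel:
    """Double-gamma canonical HRF, peak-normalized.

    The positive lobe is a gamma density with mode at ``peak_time_s``; the
    undershoot is a second gamma with mode at ``undershoot_peak_s`` scaled
    by ``undershoot_ratio`` and subtracted.  Both lobes keep conventional
    shape parameters; only the time-to-peak is study-specific.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0 < peak_time_s < duration_s:
        raise ValueError("peak_time_s must lie inside the kernel duration")
    t = np.arange(0, duration_s, dt)

    def gamma_lobe(shape: float, mode: float) -> np.ndarray:
        rate = (shape - 1.0) / mode  # gamma density mode = (shape-1)/rate
        with np.errstate(divide="ignore"):
            logp = (shape - 1.0) * np.log(np.maximum(t, 1e-12)) - rate * t
        lobe = np.exp(logp - logp.max())
        lobe[t == 0] = 0.0
        return lobe

    h = gamma_lobe(shape_main, peak_time_s) - undershoot_ratio * gamma_lobe(
        shape_undershoot, undershoot_peak_s
    )
    h = h / h.max()
    return HrfKernel(kernel=h, dt=dt, peak_time_s=peak_time_s)


def build_regressor(
    onsets_s: Sequence[float], hrf: HrfKernel, n_samples: int
) -> np.ndarray:
    """Convolve an impulse train at stimulus onsets with the HRF kernel."""
    fs = 1.0 / hrf.dt
    onsets_s = np.asarray(onsets_s, dtype=float)
    train = np.zeros(n_samples)
    if onsets_s.size:
        idx = np.round(onsets_s * fs).astype(int)
        if np.any(idx < 0) or np.any(idx >= n_samples):
            bad = onsets_s[(idx < 0) | (idx >= n_samples)][0]
            raise ValueError(f"onset at {bad} s falls outside the session")
        np.add.at(train, idx, 1.0)
    return np.convolve(train, hrf.kernel)[:n_samples]


def fit_glm(signal_channel: np.ndarray, regressor: np.ndarray):
    """OLS of one channel on [intercept, task regressor].

    Returns ``(beta, intercept, residual_variance)`` with the residual
    variance computed with ``n - 2`` degrees of freedom.
    """
    y = np.asarray(signal_channel, dtype=float)
    r = np.asarray(regressor, dtype=float)
    if y.shape != r.shape:
        raise ValueError("signal and regressor lengths differ")
    if np.ptp(r) == 0:
        raise ValueError("regressor is constant; beta is unidentifiable")
    X = np.column_stack([np.ones_like(r), r])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(y) - 2, 1)
    return float(coef[1]), float(coef[0]), float(resid @ resid / dof)


def fit_glm_session(
    signal: np.ndarray, regressor: np.ndarray, channel_ids: np.ndarray | None = None
) -> GlmResult:
    """Fit every channel of a (channels x time) signal matrix."""
    signal = np.asarray(signal, dtype=float)
    n_ch = signal.shape[0]
    if channel_ids is None:
        channel_ids = np.arange(1, n_ch + 1)
    beta = np.empty(n_ch)
    intercept = np.empty(n_ch)
    rvar = np.empty(n_ch)
    for i in range(n_ch):
        beta[i], intercept[i], rvar[i] = fit_glm(signal[i], regressor)
    return GlmResult(
        beta=beta,
        intercept=intercept,
        residual_variance=rvar,
        channel_ids=np.asarray(channel_ids),
    )


def aggregate_roi(
    glm: GlmResult,
    roi_map: Mapping[str, Sequence[int]],
    montage: Montage | None = None,
) -> dict[str, float]:
    """Unweighted mean of member-channel betas per ROI."""
    if montage is not None:
        validate_roi_map(dict(roi_map), montage)
    id_to_idx = {int(c): i for i, c in enumerate(glm.channel_ids)}
    out = {}
    for roi, chans in roi_map.items():
        for c in chans:
            if int(c) not in id_to_idx:
                raise ValueError(f"ROI {roi} references unknown channel {c}")
        out[roi] = float(np.mean([glm.beta[id_to_idx[int(c)]] for c in chans]))
    return out


def roi_table(
    per_participant: Mapping[str, Mapping[str, float]]
) -> pd.DataFrame:
    """Stack per-participant ROI means into a participant x ROI table."""
    return pd.DataFrame.from_dict(per_participant, orient="index").rename_axis(
        "participant_id"
    )
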