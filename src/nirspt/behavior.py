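"""Response coding, RT-based trial exclusion, and participant grouping.

A keypress congruent with the target object's side in the participant's
reference frame is an egocentric response; an incongruent keypress is
altercentric (the front-facing agent's frame is rotated 180 degrees).
Participants are grouped by their majority perspective over all 24 trials
and sub-grouped by consistency: at least 23 of 24 trials with the same
perspective (one-trial buffer) counts as consistent.

Grouping uses all 24 trials; the 3-SD reaction-time exclusion applies only
to RT analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .design import TrialSpec

PERSPECTIVES = ("egocentric", "altercentric")
SUBGROUP_ORDER = (
    "egocentric-consistent",
    "egocentric-inconsistent",
    "altercentric-consistent",
    "altercentric-inconsistent",
)


@dataclass(frozen=True)
class CodedTrial:
    trial_index: int
    perspective: str
    rt_ms: float
    retained: bool = True


@dataclass
class ParticipantRecord:
    """Coded behavioral record plus covariates and group labels."""

    participant_id: str
    trials: list[CodedTrial]
    group: str
    subgroup: str
    n_switches: int
    tie_flagged: bool = False
    pft_score: int | None = None
    sex: str | None = None
    age: float | None = None
    handedness: str | None = None

    def __post_init__(self) -> None:
        if not self.subgroup.startswith(self.group):
            raise ValueError("subgroup perspective must match group")


def code_response(target_side_participant: str, key_response: str) -> str:
    """Code one keypress: same side as the target -> egocentric."""
    for arg in (target_side_participant, key_response):
        if arg not in ("left", "right"):
            raise ValueError(f"expected 'left' or 'right', got {arg!r}")
    return (
        "egocentric" if key_response == target_side_participant else "altercentric"
    )


def code_trials(
    trials: Sequence[TrialSpec], responses: Sequence[tuple[str, float]]
) -> list[CodedTrial]:
    """Code a whole session of (key, rt_ms) responses."""
    if len(trials) != len(responses):
        raise ValueError("trials and responses differ in length")
    return [
        CodedTrial(
            trial_index=t.trial_index,
            perspective=code_response(t.target_side_participant, key),
            rt_ms=float(rt),
        )
        for t, (key, rt) in zip(trials, responses)
    ]


def exclude_rt_outliers(trials: Sequence[CodedTrial]) -> list[CodedTrial]:
    """Flag trials whose RT deviates more than 3 SD from the participant
    mean (single pass, sample SD).  If the SD is zero nothing is excluded."""
    rts = np.array([t.rt_ms for t in trials], dtype=float)
    if len(rts) < 2 or np.any(rts <= 0):
        raise ValueError("need at least 2 trials with positive RTs")
    mean = rts.mean()
    sd = rts.std(ddof=1)
    if sd == 0:
        return [replace(t, retained=True) for t in trials]
    keep = np.abs(rts - mean) <= 3 * sd
    return [replace(t, retained=bool(k)) for t, k in zip(trials, keep)]


def count_switches(trials: Sequence[CodedTrial]) -> int:
    """Number of trial-to-trial perspective changes, in presentation order."""
    ordered = sorted(trials, key=lambda t: t.trial_index)
    return int(
        sum(
            a.perspective != b.perspective
            for a, b in zip(ordered[:-1], ordered[1:])
        )
    )


def assign_group(
    trials: Sequence[CodedTrial], tie_rule: str = "egocentric"
) -> tuple[str, bool]:
    """Majority perspective over all trials.

    Returns ``(group, tie_flagged)``.  An exact 12-12 split is not covered
    by the majority rule; it falls back to ``tie_rule`` (default
    egocentric, the no-transformation default) and is flagged.
    """
    n_ego = sum(t.perspective == "egocentric" for t in trials)
    n_alt = len(trials) - n_ego
    if n_ego > n_alt:
        return "egocentric", False
    if n_alt > n_ego:
        return "altercentric", False
    warnings.warn(
        f"exact {n_ego}-{n_alt} perspective tie; falling back to tie rule "
        f"{tie_rule!r}",
        stacklevel=2,
    )
    return tie_rule, True


def assign_subgroup(
    trials: Sequence[CodedTrial], group: str, buffer_trials: int = 1
) -> str:
    """Consistency split: >= (n - buffer) trials with the majority
    perspective -> consistent, else inconsistent (default 23-of-24)."""
    n_majority = sum(t.perspective == group for t in trials)
    consistent = n_majority >= len(trials) - buffer_trials
    return f"{group}-{'consistent' if consistent else 'inconsistent'}"


def build_participant_record(
    participant_id: str,
    trials: Sequence[TrialSpec],
    responses: Sequence[tuple[str, float]],
    covariates: dict | None = None,
    tie_rule: str = "egocentric",
) -> ParticipantRecord:
    """Full coding chain for one participant: code, group, subgroup,
    RT-exclude."""
    coded = code_trials(trials, responses)
    group, tie_flagged = assign_group(coded, tie_rule=tie_rule)
    subgroup = assign_subgroup(coded, group)
    coded = exclude_rt_outliers(coded)
    covariates = covariates or {}
    return ParticipantRecord(
        participant_id=participant_id,
        trials=coded,
        group=group,
        subgroup=subgroup,
        n_switches=count_switches(coded),
        tie_flagged=tie_flagged,
        pft_score=covariates.get("pft_score"),
        sex=covariates.get("sex"),
        age=covariates.get("age"),
        handedness=covariates.get("handedness"),
    )


def elimination_table(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """2x2 trial counts: group (rows) x retained/excluded (columns)."""
    counts = {g: [0, 0] for g in PERSPECTIVES}
    for rec in records:
        for t in rec.trials:
            counts[rec.group][0 if t.retained else 1] += 1
    return pd.DataFrame(
        counts, index=["retained", "excluded"]
    ).T.rename_axis("group")


def trials_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Long trial-level table (one row per coded trial)."""
    rows = []
    for rec in records:
        for t in rec.trials:
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "trial_index": t.trial_index,
                    "perspective": t.perspective,
                    "rt_ms": t.rt_ms,
                    "retained": t.retained,
                    "group": rec.group,
                    "subgroup": rec.subgroup,
                }
            )
    return pd.DataFrame(rows)


def participants_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Participant-level table (group, subgroup, covariates, mean RT)."""
    rows = []
    for rec in records:
        retained_rts = [t.rt_ms for t in rec.trials if t.retained]
        rows.append(
            {
                "participant_id": rec.participant_id,
                "group": rec.group,
                "subgroup": rec.subgroup,
                "n_switches": rec.n_switches,
                "tie_flagged": rec.tie_flagged,
                "mean_rt_ms": float(np.mean(retained_rts)),
                "pft_score": rec.pft_score,
                "sex": rec.sex,
                "age": rec.age,
                "handedness": rec.handedness,
            }
        )
    return pd.DataFrame(rows)
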