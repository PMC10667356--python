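"""Trial design and session timeline for the left-right spatial judgment task.

The task shows a front-facing agent seated behind a table, reaching for one
of two side-by-side objects.  Because the agent faces the participant at
180 degrees, the agent's right hand reaches the object on the participant's
*left* and vice versa.  A session is 24 trials: all six unordered pairings
of four objects, each pairing shown four times so that each object of the
pair sits twice on the participant's left and twice on their right; four
agents (two male, two female) each appear six times; reaching hand (and
hence target side) is balanced 12/12.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

OBJECTS: tuple[str, ...] = ("book", "bottle", "glass", "plate")
AGENTS: tuple[str, ...] = ("male_1", "male_2", "female_1", "female_2")

#: seconds of fixation cross before the blank screen
FIXATION_S = 0.5
#: seconds of blank screen before stimulus onset
BLANK_S = 0.5
#: inter-trial interval jitter bounds, seconds
ITI_RANGE_S = (5.0, 7.0)

SAMPLING_RATE_HZ = 10.0


@dataclass(frozen=True)
class TrialSpec:
    """Design cell of a single stimulus trial.

    ``target_side_participant`` is the side of the reached-for object in the
    participant's reference frame; ``reaching_hand`` is the agent's hand.
    The 180-degree face-to-face geometry ties them together: right hand
    reaches the participant-left object.
    """

    trial_index: int
    agent_id: str
    left_object: str
    right_object: str
    target_object: str
    target_side_participant: str  # {"left", "right"}
    reaching_hand: str  # {"left", "right"}, agent's frame

    def __post_init__(self) -> None:
        if self.left_object == self.right_object:
            raise ValueError("left_object and right_object must differ")
        if self.target_object not in (self.left_object, self.right_object):
            raise ValueError("target_object must be one of the displayed pair")
        expected_hand = "right" if self.target_side_participant == "left" else "left"
        if self.reaching_hand != expected_hand:
            raise ValueError(
                "front-facing geometry violated: target on participant's "
                f"{self.target_side_participant} requires the agent's "
                f"{expected_hand} hand"
            )


@dataclass
class SessionTimeline:
    """Per-trial event times (seconds from session start) for one session."""

    fixation_onset_s: np.ndarray
    blank_onset_s: np.ndarray
    stimulus_onset_s: np.ndarray
    response_time_s: np.ndarray
    iti_duration_s: np.ndarray
    sampling_rate: float = SAMPLING_RATE_HZ

    @property
    def n_trials(self) -> int:
        return len(self.stimulus_onset_s)

    @property
    def duration_s(self) -> float:
        """Session end: last response plus its inter-trial interval."""
        return float(self.response_time_s[-1] + self.iti_duration_s[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": np.arange(1, self.n_trials + 1),
                "fixation_onset_s": self.fixation_onset_s,
                "blank_onset_s": self.blank_onset_s,
                "stimulus_onset_s": self.stimulus_onset_s,
                "response_time_s": self.response_time_s,
                "iti_duration_s": self.iti_duration_s,
            }
        )


def _base_trial_multiset(target_is_reached: bool = True) -> list[dict]:
    """The fixed 24-cell design before agent assignment and shuffling.

    For every unordered pairing (a, b): a-left/b-right and b-left/a-right,
    each with both members as target once, giving 4 cells per pairing with
    each object twice per side and target side balanced 2/2.
    """
    cells = []
    for a, b in combinations(OBJECTS, 2):
        for left, right in ((a, b), (b, a)):
            for target in (left, right):
                side = "left" if target == left else "right"
                cells.append(
                    {
                        "left_object": left,
                        "right_object": right,
                        "target_object": target,
                        "target_side_participant": side,
                        "reaching_hand": "right" if side == "left" else "left",
                    }
                )
    assert len(cells) == 24
    return cells


def generate_trial_set(seed: int, target_is_reached: bool = True) -> list[TrialSpec]:
    """Generate the randomized 24-trial stimulus schedule.

    The trial multiset is fixed by the design; the seed only permutes
    presentation order and the pairing of agents with design cells.  Agents
    are drawn from a fixed 6-copies-each multiset, so agent marginals hold
    for every seed.

    Parameters
    ----------
    seed : int
        Seed for the order / agent-assignment permutations.
    target_is_reached : bool
        If True (default) the queried target object is the object the agent
        reaches for.  The alternative (target is the non-reached object of
        the pair) flips the depicted hand/side relative to the target.
    """
    rng = np.random.default_rng(seed)
    cells = _base_trial_multiset()
    if not target_is_reached:
        for c in cells:
            c["target_object"] = (
                c["right_object"]
                if c["target_object"] == c["left_object"]
                else c["left_object"]
            )
            c["target_side_participant"] = (
                "right" if c["target_side_participant"] == "left" else "left"
            )
            c["reaching_hand"] = (
                "right" if c["target_side_participant"] == "left" else "left"
            )
    agents = np.repeat(AGENTS, 6)
    rng.shuffle(agents)
    order = rng.permutation(len(cells))
    trials = [
        TrialSpec(trial_index=i + 1, agent_id=str(agents[i]), **cells[j])
        for i, j in enumerate(order)
    ]
    return trials


def build_timeline(
    trials: Sequence[TrialSpec],
    rts_ms: Sequence[float],
    seed: int,
    itis_s: Sequence[float] | None = None,
) -> SessionTimeline:
    """Lay the trials out in time, with response-locked stimulus offsets.

    Each trial is a 0.5 s fixation cross, a 0.5 s blank, then the stimulus,
    which stays up until the response; the inter-trial interval is jittered
    uniformly on [5, 7] s.  The first fixation starts at t = 0, so the first
    stimulus onset is at 1.0 s.  ``itis_s`` overrides the jitter with fixed
    intervals (validated against the design range).
    """
    rts_ms = np.asarray(rts_ms, dtype=float)
    if len(rts_ms) != len(trials):
        raise ValueError(f"got {len(trials)} trials but {len(rts_ms)} RTs")
    if np.any(rts_ms <= 0):
        bad = int(np.flatnonzero(rts_ms <= 0)[0])
        raise ValueError(
            f"non-positive RT at trial {bad + 1}: {rts_ms[bad]} ms; "
            "response-locked stimulus durations require RT > 0"
        )
    if itis_s is not None:
        itis = np.asarray(itis_s, dtype=float)
        if len(itis) != len(trials):
            raise ValueError("itis_s length must match trials")
        if np.any((itis < ITI_RANGE_S[0]) | (itis > ITI_RANGE_S[1])):
            raise ValueError(f"ITIs must lie within {ITI_RANGE_S} s")
    else:
        rng = np.random.default_rng(seed)
        itis = rng.uniform(*ITI_RANGE_S, size=len(trials))

    n = len(trials)
    fixation = np.empty(n)
    t = 0.0
    for k in range(n):
        fixation[k] = t
        t = fixation[k] + FIXATION_S + BLANK_S + rts_ms[k] / 1000.0 + itis[k]
    blank = fixation + FIXATION_S
    stimulus = blank + BLANK_S
    response = stimulus + rts_ms / 1000.0
    return SessionTimeline(
        fixation_onset_s=fixation,
        blank_onset_s=blank,
        stimulus_onset_s=stimulus,
        response_time_s=response,
        iti_duration_s=itis,
    )


def trials_to_frame(trials: Sequence[TrialSpec]) -> pd.DataFrame:
    """Serialize a trial set as a table (one row per trial)."""
    return pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in trials],
            "agent_id": [t.agent_id for t in trials],
            "left_object": [t.left_object for t in trials],
            "right_object": [t.right_object for t in trials],
            "target_object": [t.target_object for t in trials],
            "target_side_participant": [t.target_side_participant for t in trials],
            "reaching_hand": [t.reaching_hand for t in trials],
        }
    )


def frame_to_trials(frame: pd.DataFrame) -> list[TrialSpec]:
    return [
        TrialSpec(
            trial_index=int(row.trial_index),
            agent_id=row.agent_id,
            left_object=row.left_object,
            right_object=row.right_object,
            target_object=row.target_object,
            target_side_participant=row.target_side_participant,
            reaching_hand=row.reaching_hand,
        )
        for row in frame.itertuples(index=False)
    ]
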