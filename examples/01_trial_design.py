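"""Build one session's balanced trial schedule and its event timeline.

The 24-trial design is a fixed multiset — six object pairings shown four
times each with side and reaching-hand balance, four agents six times
each — and the seed only permutes presentation order.
"""

from collections import Counter

from nirspt import build_timeline, generate_trial_set
from nirspt.design import trials_to_frame

trials = generate_trial_set(seed=1)
frame = trials_to_frame(trials)
print(frame.head(6).to_string(index=False))

pairings = Counter(frozenset((t.left_object, t.right_object)) for t in trials)
print(f"\n{len(trials)} trials, {len(pairings)} object pairings x "
      f"{set(pairings.values())} each")
print("right-hand reaches:", sum(t.reaching_hand == 'right' for t in trials),
      "of 24  (hand and target side are balanced 12/12)")

timeline = build_timeline(trials, rts_ms=[2500.0] * 24, seed=2)
print(f"\nfirst stimulus onset: {timeline.stimulus_onset_s[0]:.1f} s "
      "(0.5 s fixation + 0.5 s blank)")
print(f"session length: {timeline.duration_s:.1f} s with ITIs jittered on "
      f"[{timeline.iti_duration_s.min():.2f}, {timeline.iti_duration_s.max():.2f}] s")
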