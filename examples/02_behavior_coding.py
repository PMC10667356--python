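"""Simulate and code one participant's keypresses.

A response on the target's side (participant frame) codes egocentric;
the opposite key codes altercentric, because the front-facing agent's
frame is rotated 180 degrees.  Majority perspective assigns the group;
at least 23 of 24 same-perspective trials counts as consistent.
"""

from nirspt import BehaviorPolicy, build_participant_record, generate_trial_set
from nirspt.simulate import simulate_behavior

trials = generate_trial_set(seed=1)

# an altercentric responder who occasionally falls back to egocentric
policy = BehaviorPolicy("altercentric", switch_probability=0.25)
responses = simulate_behavior(policy, trials, seed=7)
record = build_participant_record("P001", trials, responses)

n_alt = sum(t.perspective == "altercentric" for t in record.trials)
print(f"coded altercentric on {n_alt}/24 trials "
      f"-> group={record.group}, subgroup={record.subgroup}")
print(f"perspective switches between consecutive trials: {record.n_switches}")
excluded = [t.trial_index for t in record.trials if not t.retained]
print(f"trials excluded by the 3-SD reaction-time rule: {excluded or 'none'}")
rts = [t.rt_ms for t in record.trials if t.retained]
print(f"mean RT over retained trials: {sum(rts)/len(rts):.0f} ms")
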