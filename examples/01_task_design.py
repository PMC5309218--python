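"""Generate one 60-trial encoding session and inspect its structure.

Six characters, two per reward-anticipation level, ten trials each;
positive feedback is predetermined at 8/10 (high), 5/10 (medium) and
2/10 (low) regardless of the participant's choices.
"""

import rewardmem as rm

design = rm.generate_session_design(seed=1)
print(f"session {design.session_id} ({design.delay}): {design.n_trials} trials\n")
for char in design.characters:
    fb = design.feedback_for(char.character_id)
    print(f"  {char.character_id}  level={char.level:6s}  "
          f"feedback={''.join(map(str, fb))}  ({fb.sum()}/10 positive)")

print("\nTotal positive feedbacks:", sum(t.feedback for t in design.trials),
      "(2*8 + 2*5 + 2*2 = 30 under the default ratios)")
print("First five trials:")
print(design.to_frame().head().to_string(index=False))
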