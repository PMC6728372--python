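"""Build the virtual-environment task design and audit its balance.

Constructs the arena (four landmarks at the compass points, four textured
boundaries), enumerates the 24 passive approach paths and the 12
judgement-of-relative-direction questions, builds the three 96-trial run
tables, and verifies that the two allocentric factors (boundary direction,
goal direction) are counterbalanced.
"""

import allodecode as ad

env = ad.build_environment()
paths = ad.enumerate_paths(env)
table = ad.build_trial_table(paths, env, seed=0)
df = table.to_dataframe()

print(f"paths: {len(paths)} (8 boundary sides x 3 egocentric positions)")
print(f"trials per run: {df.groupby('run').size().tolist()}")
print("per-run boundary-direction counts:",
      df[df.run == 1].allo_boundary.value_counts().to_dict())
print("per-run goal-direction counts:",
      df[df.run == 1].allo_goal.value_counts().to_dict())

for factor in ("allo_boundary", "allo_goal"):
    rep = ad.verify_balance(table, factor, env)
    print(f"balance audit [{factor}]: all flags pass = {rep.all_pass}")

jrd = ad.enumerate_jrd(env)
print(f"JRD questions: {len(jrd)}; e.g. facing {jrd[0].facing_landmark}, "
      f"probe {jrd[0].probe_landmark} -> {jrd[0].correct_response} "
      f"({jrd[0].angular_disparity} deg clockwise)")
print("landmark right of Mountain:", ad.relative_landmark("Mountain", 90, env))

# A trial table row: each 8 s trial carries both allocentric codes.
ev = table.events(1)[0]
print(f"first trial: onset {ev.onset_s:.2f} s, boundary {ev.allo_boundary}, "
      f"goal {ev.allo_goal}, ego {ev.ego_boundary}, cue {ev.cue_side}, "
      f"respond '{ev.correct_response_landmark}'")
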