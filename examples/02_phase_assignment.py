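"""Identify each subject's change and post-change phases.

The change score at week w is baseline minus week-w severity (positive =
improvement).  The visit with the largest absolute change is the
post-change phase; the scheduled visit just before it is the change phase.
"""

from sympnet import assign_phases, classify_responder, compute_deltas, find_max_change

scores = {0: 20, 4: 17, 6: 8, 9: 12, 12: 13}  # QIDS totals by week
deltas = compute_deltas(scores)
max_delta, max_week = find_max_change(deltas)
change_week, post_week = assign_phases(max_week)

print(f"change scores by week: {deltas}")
print(f"maximum change {max_delta:+g} at week {max_week}")
print(f"change phase = week {change_week}, post-change phase = week {post_week}")
print(f"responder (>=50% reduction at any visit): {classify_responder(scores)}")
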