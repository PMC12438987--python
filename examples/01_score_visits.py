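"""Score raw QIDS items and the quality-of-life context questionnaire.

Builds two subjects' baseline visits by hand, consolidates the 16 items
into the nine symptom domains (max rule for the multi-item domains), and
classifies the perceived context from the Q-LES-Q-SF total.
"""

import pandas as pd

from sympnet import score_visits

rows = []
for sid, fill, qol in [("mild", 1, 55), ("severe", 3, 30)]:
    row = {"subject_id": sid, "week": 0}
    row.update({f"item{i:02d}": fill for i in range(1, 17)})
    per_item = qol // 14
    row.update({f"qlesq{i:02d}": min(5, per_item + (i <= qol - 14 * per_item)) for i in range(1, 17)})
    rows.append(row)

scored = score_visits(pd.DataFrame(rows), context_threshold=45)
print(scored.visits[["subject_id", "week", "qids_total"]].to_string(index=False))
print(scored.context.to_string(index=False))
print(
    "\nqids_total is the 0-27 depression severity (sum of nine 0-3 domains);"
    "\ncontext_class is poor/good by the Q-LES-Q-SF cut at 45."
)
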