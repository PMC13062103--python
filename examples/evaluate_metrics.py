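"""The clinical evaluation metric suite on small constructed fixtures.

Builds an explanation, a panel annotation and paired dosing decisions, then
computes alignment, correctness tiers, dose accuracy, agreement, a benefit
score, and a faulty (deranged) explanation.
"""

import numpy as np

from stiidil.metrics import (
    DosageRecord,
    ExpertAnnotation,
    ExplanationItem,
    benefit_score,
    clinical_agreement,
    correctness_rates,
    mae_dosage,
    make_faulty_explanation,
    top_n_alignment_rate,
)

items = [
    ExplanationItem(target=t, direction=1, magnitude=float(10 - t), rank=t + 1)
    for t in range(10)
]
# panel of one expert picks targets {0, 1, 12}; algorithm's top-3 is {0, 1, 2}
ann = ExpertAnnotation(top3=[{0, 1, 12}], verdicts=np.ones((10, 1, 3), bool))
print(f"top-3 alignment: {top_n_alignment_rate(items, ann, N=3):.1f} %")

verdicts = np.zeros((10, 1, 3), dtype=bool)
verdicts[:9, 0, 0] = True   # 9 items have the right feature
verdicts[:8, 0, 1] = True   # 8 of those the right direction
verdicts[:7, 0, 2] = True   # 7 of those the right size
tiers = correctness_rates(ExpertAnnotation(top3=[set()], verdicts=verdicts))
print(f"correctness partial/moderate/absolute: "
      f"{tiers['partial']:.0f}/{tiers['moderate']:.0f}/{tiers['absolute']:.0f} %")

decisions = [DosageRecord(10, 12, 8, 5), DosageRecord(8, 8, 8, 6)]
print(f"dose MAE vs expert: {mae_dosage(decisions):.2f} U")
print(f"agreement (10 vs expert 12, prior 8): {clinical_agreement(decisions[0])}")

pre = DosageRecord(10, 12, 8, confidence=4, scenario=1)
post = DosageRecord(12, 12, 8, confidence=7, scenario=3)
print(f"benefit of assistance (accuracy up, confidence up): {benefit_score(pre, post):+d}")

faulty = make_faulty_explanation(items, seed=0)
orig = {it.target: it.magnitude for it in items}
moved = sum(it.magnitude != orig[it.target] for it in faulty)
print(f"faulty explanation: {moved}/10 targets carry a different payload "
      f"(derangement, same payload multiset)")
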