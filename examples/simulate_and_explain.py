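"""Simulate a synthetic inpatient cohort and explain one predicted dose.

Generates patients with the clinical grid shape (3 days x 7 BG slots,
insulin history, medication flags, demographics), attaches a surrogate
titration model, compiles the full set of clinical constraints for one
patient and prints the top-10 explanation items.
"""

import numpy as np

from stiidil import build_constraints, explain_kernel, rank_items
from stiidil.synthetic import (
    CohortConfig,
    cohort_baseline,
    make_clinical_surrogate,
    simulate_cohort,
)

cfg = CohortConfig(n_patients=20, missing_rate=0.1, seed=11)
patients = simulate_cohort(cfg)
x = patients[0]
print(f"cohort: {len(patients)} patients, d={x.d} features each")

fs = x.space
model = make_clinical_surrogate(fs, seed=11, reference=cohort_baseline(cfg, fs))
f = model.to_value_function()

constraints = build_constraints(x, base_strength=1.0)
print(f"compiled {len(constraints.specs)} constraint terms for {x.patient_id}")

coeffs = explain_kernel(f, x, M=2048, seed=0, constraints=constraints)
print(f"predicted dose adjustment: {f(x.values):+.2f} U "
      f"(explained total {coeffs.total():+.2f} U)\n")
print("top-10 explanation items (feature or pair, signed effect in U):")
for it in rank_items(coeffs, k=10):
    names = (
        " x ".join(fs[k].name for k in it.target)
        if isinstance(it.target, tuple)
        else fs[it.target].name
    )
    print(f"  #{it.rank:<2d} {names:<28s} {it.direction * it.magnitude:+.3f}")
# Positive effects push the predicted insulin adjustment up (e.g. high
# action-window BG); negative effects pull it down (recent insulin already
# given, an added oral agent).
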