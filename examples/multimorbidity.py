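"""Multi-morbidity analysis: diabetes and depression in 11 patient groups.

Inputs are gender (g), income (i), family history (f) and marital
status (m); outputs are diabetes (a) and depression (e).  Every
diabetic group is also depressive, so every complex cause of diabetes
must recur in the explanation of depression — visible only under
system-level minimization.
"""

import cora
from cora import datasets

cases = datasets.patient_groups()
sol = cora.solve(cases, inc_threshold=1.0)

print(f"{len(sol)} irredundant system(s):")
(system,) = sol.systems
for out, cubes in system.models:
    label = {"a": "diabetes", "e": "depression"}[out]
    print(f"  {cora.format_model(list(cubes), out, cases.input_names):28s} ({label})")

for out in cases.output_names:
    cons, cov = cora.model_fit(list(system.model(out)), out, cases)
    print(f"  fit of {out}: consistency={cons:.2f}, coverage={cov:.2f}")

print(
    "\nBoth disjuncts of the diabetes model (low income combined with being"
    "\nsingle, and a family history) reappear for depression, which adds the"
    "\nbare marital-status and family-history literals: a co-morbid structure."
)
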