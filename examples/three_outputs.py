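"""Three outputs, four inputs: systems ambiguity and cross-output sharing.

A denser artificial system where the exact solution consists of five
irredundant systems, each a different causal reading of the same data.
"""

import cora
from cora import datasets

spec = datasets.three_function_demo()
names = ("a", "b", "c", "d")
sol = cora.solve(spec)

print(f"{len(sol)} irredundant systems\n")
for i, s in enumerate(sol.systems, 1):
    shared12 = set(s.model("f1")) & set(s.model("f2"))
    print(f"S*{i} (f1 and f2 share {len(shared12)} terms):")
    for out, cubes in s.models:
        print("  " + cora.format_model(list(cubes), out, names))
    print()

print(
    "Five equally data-consistent systems exist: the data alone cannot"
    "\ndiscriminate among them (systems ambiguity).  At best f1 and f2 share"
    "\nthree complex causes, and one system routes a common cause into all"
    "\nthree outputs at once."
)
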