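# cora

Exact multi-output Boolean minimization for configurational causal
inference.

## The problem

Configurational comparative methods (QCA, CNA and relatives) infer
Boolean cause–effect models from case-level binary data: each case is a
configuration of binary conditions (inputs) and binary outcomes
(outputs), and a model is a minimally necessary disjunction of minimally
sufficient conjunctions — the INUS template.  Classical implementations
minimize **one outcome at a time**, which makes them blind to *complex
effects*: conjunctions of outcomes, such as the co-occurrence of two
chronic conditions in the same patient (multi-morbidity).

This package treats the data as a *system* of switching functions
**F** = {f₁(**x**), …, f_m(**x**)} over inputs **x** = {x₁, …, x_k} and
minimizes them jointly, the way multi-output two-level circuits are
optimized in logic design:

* A **multi-output prime implicant (MOPI)** is a product of literals
  that is a prime implicant of some f_j or of a product of output
  functions f_j·f_l⋯.  Operationally: a cube whose maximal *output tag*
  (the outputs whose off-sets it avoids) is non-empty and shrinks under
  every one-literal cancellation.
* An **irredundant system** is a selection of MOPIs, written into the
  models of their tagged outputs, from which no MOPI and no literal can
  be removed without breaking F-equivalence.
* The **solution** is the set of *all* irredundant systems, enumerated
  exactly with Petrick's method over the MOPI chart (rows = MOPIs,
  columns = (output, on-minterm) pairs).  Several systems means the data
  genuinely underdetermine the structure ("systems ambiguity").

For a single output the result coincides with classical Quine–McCluskey
irredundant sums.  Around the core sit: truth-table construction with
inclusion (consistency) scoring and threshold assignment, don't-care
handling for unobserved configurations, consistency/coverage fit
statistics, ascending input-tuple mining, and logic-diagram (logigram)
export with shared-gate fan-out.

## Worked example

Two outcomes over inputs x, y, z, specified by their on-sets
f₁ = Σm(1,3,7), f₂ = Σm(2,6,7) (minterm 7 = xyz is the only
configuration where both outcomes occur):

```python
import cora
from cora import datasets

spec = datasets.two_function_demo()
sol = cora.solve(spec)
```

Running `python examples/two_output_minimization.py` prints:

```
multi-output prime implicants:
  yz'    -> f2
  yz     -> f1
  x'z    -> f1
  xy     -> f2
  xyz    -> f1, f2

2 irredundant systems:
S*1:
  x'z + xyz <=> f1
  yz' + xyz <=> f2
S*2:
  yz + x'z <=> f1
  yz' + xy <=> f2
```

`xyz` is prime for the *product* f₁·f₂ but for neither output alone, so
single-output minimization can never propose S\*1 — the reading in which
one complex cause (xyz) produces the complex effect f₁f₂.  S\*2 is
exactly what two separate minimizations find.  Both systems fit the data
perfectly; the ambiguity is a property of the data, not of the
algorithm.

The other bundled examples (`examples/`) cover a multi-morbidity case
table, a three-output system with five-fold ambiguity, an empirical
12-country injury-mortality re-analysis, input-tuple mining, and
logigram export.

## Command line

```sh
cora truthtable --input injury.csv --inputs gnp,mys,apac,unem,roca --outputs mvta,ssii
cora solve      --input injury.csv --inputs ... --outputs ... --inc-threshold 0.6
cora mine       --input injury.csv --inputs ... --outputs ... --inc-threshold 0.6 --cov-threshold 1.0
cora draw       --input injury.csv --inputs ... --outputs ... --system 2 --dot s2.dot --svg s2.svg
```

All subcommands also read a flat YAML config via `--config`; identical
configurations produce byte-identical reports.

## Layout

| module            | contents                                                      |
| ----------------- | ------------------------------------------------------------- |
| `cora.cubes`      | product-term (cube) algebra: merge, expansion, evaluation      |
| `cora.cases`      | case-table CSV I/O, model rendering                           |
| `cora.truthtable` | aggregation, inclusion scores, on/off/dc sets, PLA I/O         |
| `cora.mopi`       | MOPI generation (tagged QMC, expansion search, brute force)    |
| `cora.systems`    | MOPI chart, Petrick enumeration, writing rule, fit statistics  |
| `cora.mining`     | ascending input-tuple search                                   |
| `cora.logigram`   | netlists, gate counts, DOT/SVG export                          |
| `cora.synth`      | random and planted-system data generators for testing          |
| `cora.datasets`   | the bundled example inputs                                     |
| `cora.cli`        | `cora` command                                                 |

See `docs/methods.md` for the method description, parameter defaults and
known limitations.
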