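# Methods

## Model

The data model is a system of Boolean (switching) functions
**F** = {f₁, …, f_m} over k binary inputs.  Each input configuration is
a *minterm*, indexed by its decimal value with the **first declared
input as the most significant bit** (so with inputs (x, y, z), minterm 1
is x'y'z and 3 is x'yz).  Every output partitions the 2^k minterms into
an on-set (output present), an off-set (output absent) and a dc-set
(don't care, unconstrained).

A *cube* is a conjunction of literals; internally a pair of bitmasks
(care positions, polarities), so adjacency merging, containment and
one-literal cancellation are O(1) integer operations.

### From cases to functions

Cases sharing an input configuration are pooled into a truth-table row
with a per-output **inclusion score** Inc = (cases with output 1)/n.
The assignment rule is a single threshold: a row with n ≥ `n_threshold`
cases gets output value 1 iff Inc ≥ `inc_threshold`, else 0; rows with
fewer cases, and all unobserved configurations (the logical
remainders), are don't-care.  There is no separate "contradictory"
state: contradictory rows (0 < Inc < 1) fall under the same cut.
Raising the threshold can only move rows from 1 to 0 (monotonicity).

Defaults: `inc_threshold = 0.6`, `n_threshold = 1`.  0.6 is the
smallest score the bundled empirical example assigns a 1; it is this
package's default, and both parameters are explicit everywhere they
matter.  Because unobserved configurations are always dc, the method is
indifferent to the remainder/solution-type debates of classical QCA:
don't-cares are used exactly when they shorten a prime implicant.

### Multi-output prime implicants

The **output tag** of a cube is the maximal set of outputs whose
off-sets it avoids; it equals the largest product function the cube
implies, and it shrinks monotonically as literals are cancelled.  A
cube is a **MOPI** iff

1. its tag is non-empty,
2. no one-literal cancellation keeps a tag that is a superset, and
3. it covers at least one on-minterm of a tagged output (usefulness —
   cubes living entirely in don't-care space can never mark a chart
   column and are discarded).

Condition 2 is equivalent to the textbook definition (a prime implicant
of some f_j or of a product of output functions): the proof sketch
lives in `cora/mopi.py`.

Two generation routes produce the identical set and are property-tested
against each other and against literal 3^k enumeration:

* **on-dc** (default): tagged Quine–McCluskey.  Seeds are all minterms
  in on ∪ dc of at least one output, tagged with those outputs; merged
  cubes carry the intersection of their parents' tags (dropped when
  empty); a cube is checked off only by a merge that preserves its full
  tag.  Survivors pass through the explicit primality and usefulness
  filters.
* **on-off**: breadth-first literal cancellation seeded from
  on-minterms, pruning cubes whose tag empties.  Preferable when the
  dc-space dwarfs the off-sets.

### Irredundant systems

The **MOPI chart** has one row per MOPI and one column per
(output, on-minterm) pair; a row marks a column when its tag contains
the output and its cube covers the minterm.  **Petrick's method** turns
the chart into a product-of-sums over columns and expands it to a
sum-of-products with absorption (X + XY = X) applied after every
distribution step; the surviving terms are exactly the
inclusion-minimal covering row sets.  Implementation notes:

* Terms are integer bitmasks over row indices; absorption uses a
  per-row bucket index so only plausible absorbers are tested.
* **No row- or column-dominance pruning.**  Dominance elimination can
  delete rows that participate in non-minimum irredundant covers, and
  the solution is defined as *all* of them.  Only duplicate columns
  (identical mark sets) are collapsed, which cannot change the cover
  set.  Reported charts retain dominated rows for the same reason.
* The expansion is capped (default 10⁶ terms, checked before
  absorption); charts over data with many inputs and few observed
  configurations can have astronomically many irredundant systems, and
  the cap converts that into an explicit capacity error suggesting
  tuple mining.  The cap is a resource guard, not an approximation: no
  returned solution is ever truncated.

**Writing rule**: a selected MOPI is written into the model of every
tagged output in which it covers at least one on-minterm.  A shared
MOPI is retained in a model even when a shorter disjunct of the same
model absorbs it (e.g. `mys·roca + roca`): cancellation operates at the
system level, because removing the term there would hide the shared
cause the system asserts.  A MOPI covering only don't-care minterms of
some tagged output is *not* written into that output's model.

Systems and within-model disjuncts are ordered canonically (selected
set size, then row order; literal count, then positional string), so
all reports are byte-reproducible.  No stage uses randomness.

### Fit statistics

For a model M of output o over cases:
consistency = #(M=1 ∧ o=1)/#(M=1) (undefined when M matches no case),
coverage = #(M=1 ∧ o=1)/#(o=1).  Each case row counts once; replication
weights are deliberately unsupported — frequency replication is the
analyst's decision, made upstream in the case table.

### Tuple mining

Any system found with input set X that uses only inputs Y ⊆ X must,
ceteris paribus, also be found when solving on exactly Y.  Mining
exploits this in reverse: candidate input tuples are tested in
ascending size (lexicographic within size); for each tuple the case
table is projected, the truth table rebuilt at `inc_threshold`, and the
solution computed.  A tuple **passes** when at least one of its systems
reaches `cov_threshold` coverage for *every* output; this per-output
all-must-pass reading is an interpretation made by this package, and
both thresholds are mandatory (no silent defaults in mining).  Row
consistency at `inc_threshold` is enforced upstream by the assignment
rule and recorded per output.  `first_size` mode stops after the first
size with a hit and reports *all* passing tuples of that size;
`exhaustive` tests every size up to `max_k`.  The number of candidate
tuples is capped (default 10⁵).

### Logigrams

A system maps onto a two-level circuit: multi-literal cubes become AND
gates, multi-term models OR gates, single literals wire a rail directly
and negation is an inverter marker at the source end of a wire.  With
sharing enabled, a cube written into several models is one AND gate
fanning out to each consuming OR gate, so the shared-gate count equals
the number of distinct multi-literal cubes across models.  Inverters
are deduplicated per rail.  Netlist evaluation by 0/1 propagation
reproduces model evaluation exactly (tested exhaustively for small k).
Export is plain DOT and a simple three-column SVG; faithful
MIL-STD-806B glyphs are a cosmetic non-goal.

## Synthetic data

`cora.synth` provides the generators the property tests run on:

* `random_spec` emulates the *shape* of configurational data: only a
  drawn number of configurations (default between max(3, k) and 24,
  mirroring the bundled studies' 7-of-32 and 11-of-16) carry assigned
  values; everything else is a remainder.  It does **not** emulate
  correlated inputs, case weights or measurement error — passing tests
  show algorithmic exactness on realistic sparsity, not robustness to
  noisy measurement.
* `plant_system`/`cases_from_models` work backwards from known
  two-level models over a relevant input subset, with optional
  irrelevant padding inputs and per-output bit-flip noise.  At noise 0
  with full-factorial sampling, solving recovers the planted functions
  exactly and padding never enters a system — the basis of the mining
  superset-property tests.

## Problem sizes and numerical choices

All computations are exact integer/bit arithmetic; there are no
tolerances.  MOPI generation is refused above 20 inputs (capacity
error pointing to mining); the brute-force oracle is limited to 10.
The property suites run 200 random specs with k ≤ 8 and m ≤ 3 for MOPI
oracle equivalence, and perform full exhaustive-subset system
verification on every resulting chart with ≤ 15 rows — beyond that the
2^rows oracle, not the implementation, is the bottleneck.  These sizes
keep the whole suite under a minute on one core while covering the
regime configurational studies occupy.

## Known limitations

* Binary inputs and outputs only; no multi-valued levels, no fuzzy-set
  membership, and no calibration of continuous variables.
* Missing values are rejected; the method is defined on complete data.
* The objective is fixed to system irredundancy; cost-weighted gate
  objectives (aP + bQ + cR) and minimal-sum filtering are out of scope.
* Exact enumeration is inherently exponential in adversarial charts;
  the capacity errors are the designed failure mode, with tuple mining
  as the practical escape hatch.
* In principle a minimal chart cover could contain a MOPI written into
  only part of its tag whose literal cancellation stays F-equivalent;
  no such case arises in any bundled or property-tested data, and the
  writing rule's dc-restriction (above) is the relevant safeguard.
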