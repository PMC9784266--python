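"""MOPI charts, Petrick enumeration of irredundant systems, fit statistics.

The chart is a covering table whose rows are the MOPIs and whose columns
are the (output, on-minterm) pairs; a row marks a column when its tag
contains the output and its cube covers the minterm.  An irredundant
system is an inclusion-minimal row selection covering every column, with
each selected MOPI written into the model of every tagged output in
which it covers at least one on-minterm.  The solution is the set of ALL
such systems — when several exist the data genuinely underdetermine the
causal structure ("systems ambiguity"), and none is privileged.

Petrick's method enumerates the minimal covers exactly: the
product-of-sums over columns is expanded to a sum-of-products with
absorption (X + XY = X) applied after every distribution step, which
keeps exactly the inclusion-minimal transversals.  No row- or
column-dominance pruning is applied: dominance can delete rows that
participate in non-minimum irredundant covers, and the solution must
contain all of them.  Only duplicate columns (identical mark sets)
are collapsed, which cannot change the cover set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .cases import CaseTable, format_model
from .cubes import Cube, canonical_order, covers, evaluate_model
from .mopi import TaggedImplicant, generate_mopis
from .truthtable import FunctionSpec, aggregate, assign_outputs, function_spec

__all__ = [
    "MopiChart",
    "System",
    "Solution",
    "build_chart",
    "essential_rows",
    "enumerate_irredundant_systems",
    "write_models",
    "model_fit",
    "solve",
]

PETRICK_TERM_CAP = 10**6


class PetrickCapacityError(RuntimeError):
    pass


@dataclass(frozen=True)
class MopiChart:
    rows: tuple[TaggedImplicant, ...]
    columns: tuple[tuple[str, int], ...]  # (output name, on-minterm)
    marks: tuple[frozenset[int], ...]  # per column: indices of marking rows
    input_names: tuple[str, ...]
    spec: FunctionSpec

    def row_marks(self, i: int) -> frozenset[int]:
        return frozenset(c for c, rows in enumerate(self.marks) if i in rows)

    def report(self) -> str:
        """Text grid: one row per MOPI, 'x' where it marks a column."""
        heads = [f"{o}:{m}" for o, m in self.columns]
        label_w = max(
            (len(r.cube.to_expression(self.input_names)) for r in self.rows), default=1
        )
        lines = [" " * (label_w + 2) + "  ".join(heads)]
        for i, r in enumerate(self.rows):
            cells = [
                ("x" if i in self.marks[c] else ".").center(len(heads[c]))
                for c in range(len(self.columns))
            ]
            lines.append(r.cube.to_expression(self.input_names).ljust(label_w + 2) + "  ".join(cells))
        return "\n".join(lines)


@dataclass(frozen=True)
class System:
    selected: tuple[TaggedImplicant, ...]
    models: tuple[tuple[str, tuple[Cube, ...]], ...]  # (output, cubes) in output order

    def model(self, output: str) -> tuple[Cube, ...]:
        return dict(self.models)[output]

    def selected_cubes(self) -> frozenset[Cube]:
        return frozenset(ti.cube for ti in self.selected)

    def inputs_used(self, input_names: Sequence[str]) -> frozenset[str]:
        used = set()
        for ti in self.selected:
            for p, s in enumerate(ti.cube.states()):
                if s != "-":
                    used.add(input_names[p])
        return frozenset(used)

    def report(self, input_names: Sequence[str]) -> str:
        return "\n".join(
            format_model(list(cubes), out, input_names) for out, cubes in self.models
        )


@dataclass(frozen=True)
class Solution:
    systems: tuple[System, ...]
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    parameters: tuple[tuple[str, object], ...] = ()

    def __len__(self) -> int:
        return len(self.systems)

    def report(self) -> str:
        blocks = []
        for i, s in enumerate(self.systems, 1):
            blocks.append(f"S*{i}:\n" + s.report(self.input_names))
        return "\n\n".join(blocks)

    def to_records(self) -> list[dict]:
        """Machine-readable dump: one record per system."""
        return [
            {
                "system": i + 1,
                "selected": [str(ti.cube) for ti in s.selected],
                "models": {
                    out: [c.to_expression(self.input_names) for c in cubes]
                    for out, cubes in s.models
                },
            }
            for i, s in enumerate(self.systems)
        ]


def build_chart(mopis: Sequence[TaggedImplicant], spec: FunctionSpec,
                input_names: Sequence[str] | None = None) -> MopiChart:
    """Covering table over (output, on-minterm) columns."""
    names = tuple(input_names) if input_names else tuple(
        f"x{i + 1}" for i in range(spec.width)
    )
    columns = tuple(
        (out, m)
        for j, out in enumerate(spec.output_names)
        for m in sorted(spec.on[j])
    )
    marks = []
    for out, m in columns:
        rows = frozenset(
            i for i, ti in enumerate(mopis) if out in ti.tag and covers(ti.cube, m)
        )
        if not rows:
            raise RuntimeError(
                f"on-minterm {m} of output {out} is covered by no MOPI; "
                "inconsistent chart construction"
            )
        marks.append(rows)
    return MopiChart(tuple(mopis), columns, tuple(marks), names, spec)


def essential_rows(chart: MopiChart) -> set[TaggedImplicant]:
    """MOPIs that are the unique mark of at least one column.

    These appear in every irredundant system.
    """
    out = set()
    for rows in chart.marks:
        if len(rows) == 1:
            (i,) = rows
            out.add(chart.rows[i])
    return out


def _petrick_covers(marks: Sequence[frozenset[int]], cap: int = PETRICK_TERM_CAP) -> list[frozenset[int]]:
    """All inclusion-minimal covering row sets of the chart columns.

    Terms of the expanding product-of-sums are bitmasks over row
    indices; absorption (X + XY = X) runs after every distribution step
    over a per-row bucket index, so only plausible absorbers are tried.
    """
    # collapse duplicate columns; they constrain identically
    unique = sorted(set(marks), key=len)
    cols = []
    for col in unique:
        m = 0
        for r in col:
            m |= 1 << r
        cols.append(m)
    terms: list[int] = [0]
    for col in cols:
        raw = set()
        for t in terms:
            if t & col:
                raw.add(t)  # already satisfied: X + XY absorbs the product
            else:
                rest = col
                while rest:
                    bit = rest & -rest
                    rest ^= bit
                    raw.add(t | bit)
        if len(raw) > cap:
            raise PetrickCapacityError(
                f"Petrick expansion exceeded {cap} terms; try mining a smaller "
                "input tuple or different thresholds"
            )
        # absorption: keep inclusion-minimal terms, smallest first; an
        # absorber of t contains only rows of t, so it lives in the
        # bucket of t's lowest set bit among others — scan t's buckets
        ordered = sorted(raw, key=lambda t: t.bit_count())
        kept: list[int] = []
        bucket: dict[int, list[int]] = {}
        for t in ordered:
            absorbed = False
            rest = t
            while rest and not absorbed:
                bit = rest & -rest
                rest ^= bit
                for k in bucket.get(bit, ()):
                    if k & ~t == 0:
                        absorbed = True
                        break
            if not absorbed:
                kept.append(t)
                low = t & -t
                bucket.setdefault(low, []).append(t)
        terms = kept
    return [frozenset(_bits(t)) for t in terms]


def _bits(mask: int) -> list[int]:
    out = []
    while mask:
        bit = mask & -mask
        out.append(bit.bit_length() - 1)
        mask ^= bit
    return out


def write_models(selected: Sequence[TaggedImplicant], spec: FunctionSpec
                 ) -> tuple[tuple[str, tuple[Cube, ...]], ...]:
    """Writing rule: a MOPI enters output j's model iff j is in its tag and
    its cube covers at least one on-minterm of j.

    A shared MOPI is written into every such output even when another
    disjunct of the same model absorbs it (e.g. mys·roca next to roca):
    cancellation operates at the system level, not within one sum.
    """
    models = []
    for j, out in enumerate(spec.output_names):
        on_mask = spec.on_mask(j)
        cubes = [
            ti.cube
            for ti in selected
            if out in ti.tag and ti.cube.minterm_mask() & on_mask
        ]
        cubes.sort(key=canonical_order)
        models.append((out, tuple(cubes)))
    return tuple(models)


def enumerate_irredundant_systems(chart: MopiChart) -> Solution:
    """All irredundant systems of the chart, via Petrick's method.

    Systems are ordered by selected-set size, then lexicographically by
    chart row index, so reports are reproducible.
    """
    covers_ = _petrick_covers(chart.marks)
    keyed = sorted(
        (len(c), tuple(sorted(c))) for c in covers_
    )
    systems = []
    for _, rows in keyed:
        selected = tuple(chart.rows[i] for i in rows)
        systems.append(System(selected, write_models(selected, chart.spec)))
    return Solution(
        tuple(systems), chart.input_names, chart.spec.output_names
    )


def model_fit(model: Sequence[Cube], output: str, cases: CaseTable
              ) -> tuple[float | None, float]:
    """Consistency and coverage of a model over case-level data.

    consistency = P(output=1 | model=1), None (undefined) when the model
    matches no case; coverage = P(model=1 | output=1).
    """
    j = cases.output_names.index(output)
    n_model = n_both = n_out = 0
    for i in range(cases.n_cases):
        hit = evaluate_model(model, cases.minterm(i)) == 1
        pos = cases.outputs[i, j] == 1
        n_model += hit
        n_out += pos
        n_both += hit and pos
    consistency = float(n_both / n_model) if n_model else None
    coverage = float(n_both / n_out) if n_out else 0.0
    return consistency, coverage


def solve(
    data: CaseTable | FunctionSpec,
    inc_threshold: float = 0.6,
    n_threshold: int = 1,
    algorithm: str = "on-dc",
) -> Solution:
    """End-to-end pipeline: cases or spec → solution.

    From cases: aggregate → assign outputs under the thresholds → derive
    on/off/dc sets.  Then: MOPI generation → chart → Petrick.  The whole
    pipeline is deterministic.
    """
    if isinstance(data, CaseTable):
        tt = assign_outputs(aggregate(data), inc_threshold, n_threshold)
        spec = function_spec(tt)
        input_names = data.input_names
    else:
        spec = data
        input_names = tuple(f"x{i + 1}" for i in range(spec.width))
    mopis = generate_mopis(spec, algorithm)
    chart = build_chart(mopis, spec, input_names)
    sol = enumerate_irredundant_systems(chart)
    params = (
        ("inc_threshold", inc_threshold),
        ("n_threshold", n_threshold),
        ("algorithm", algorithm),
    )
    return Solution(sol.systems, sol.input_names, sol.output_names, params)
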