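"""Truth tables with inclusion scores, and multi-output function specs.

Cases sharing an input configuration are pooled into one truth-table row
with a per-output inclusion (consistency) score, the fraction of the
row's cases in which that output is present.  A threshold rule then
assigns each observed row an output value; configurations never observed
(the logical remainders) are don't-cares, as are rows with too few cases.

The resulting on/off/dc minterm partition per output — a
:class:`FunctionSpec` — is the input to prime-implicant generation.
It can also be specified directly from minterm lists or a Berkeley PLA
file, for completely or incompletely specified functions given without
case data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Mapping, Sequence, TextIO

from .cases import CaseTable
from .cubes import parse_cube

__all__ = [
    "TruthTable",
    "TruthTableRow",
    "FunctionSpec",
    "DC",
    "aggregate",
    "assign_outputs",
    "function_spec",
    "spec_from_minterms",
    "read_pla",
    "write_pla",
]

DC = "-"  # don't-care marker for assigned output values


@dataclass(frozen=True)
class TruthTableRow:
    minterm: int
    n: int
    inclusion: tuple[float, ...]  # per output, #(output=1)/n
    value: tuple[object, ...] | None = None  # per output: 1, 0 or DC; None before assignment


@dataclass(frozen=True)
class TruthTable:
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    rows: tuple[TruthTableRow, ...]
    inc_threshold: float | None = None
    n_threshold: int | None = None

    @property
    def width(self) -> int:
        return len(self.input_names)

    @property
    def assigned(self) -> bool:
        return all(r.value is not None for r in self.rows)

    def configuration(self, minterm: int) -> str:
        return format(minterm, f"0{self.width}b")

    def report(self) -> str:
        """Plain-text table: configuration, n, Inc per output, assigned values."""
        head = list(self.input_names) + ["n"]
        head += [f"Inc({o})" for o in self.output_names]
        if self.assigned:
            head += [f"f({o})" for o in self.output_names]
        lines = ["\t".join(head)]
        for r in self.rows:
            cells = list(self.configuration(r.minterm)) + [str(r.n)]
            cells += [f"{x:.2f}" for x in r.inclusion]
            if self.assigned:
                cells += [str(v) for v in r.value]
            lines.append("\t".join(cells))
        return "\n".join(lines)


@dataclass(frozen=True)
class FunctionSpec:
    """Per-output partition of the 2**width minterms into on/off/dc sets."""

    width: int
    output_names: tuple[str, ...]
    on: tuple[frozenset[int], ...]
    off: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        space = frozenset(range(1 << self.width))
        for name, on_j, off_j in zip(self.output_names, self.on, self.off):
            if on_j & off_j:
                raise ValueError(f"on/off sets of {name} overlap: {sorted(on_j & off_j)}")
            if not (on_j | off_j) <= space:
                raise ValueError(f"minterms of {name} out of range")

    @property
    def n_outputs(self) -> int:
        return len(self.output_names)

    def dc(self, j: int) -> frozenset[int]:
        return frozenset(range(1 << self.width)) - self.on[j] - self.off[j]

    def off_mask(self, j: int) -> int:
        m = 0
        for x in self.off[j]:
            m |= 1 << x
        return m

    def on_mask(self, j: int) -> int:
        m = 0
        for x in self.on[j]:
            m |= 1 << x
        return m


def aggregate(cases: CaseTable) -> TruthTable:
    """Pool cases into one row per observed input configuration.

    Rows are ordered by ascending minterm index.  Inclusion scores are
    exact case fractions; no output values are assigned yet.
    """
    if cases.n_cases == 0:
        raise ValueError("empty case table")
    buckets: dict[int, list[int]] = {}
    for i in range(cases.n_cases):
        buckets.setdefault(cases.minterm(i), []).append(i)
    rows = []
    for m in sorted(buckets):
        idx = buckets[m]
        n = len(idx)
        inc = tuple(
            sum(int(cases.outputs[i, j]) for i in idx) / n
            for j in range(len(cases.output_names))
        )
        rows.append(TruthTableRow(m, n, inc))
    return TruthTable(cases.input_names, cases.output_names, tuple(rows))


def assign_outputs(tt: TruthTable, inc_threshold: float = 0.6, n_threshold: int = 1) -> TruthTable:
    """Threshold rule: value 1 iff Inc >= inc_threshold, else 0.

    Rows with fewer than ``n_threshold`` cases are dropped to don't-care.
    Raising ``inc_threshold`` can only move rows from 1 to 0, never the
    reverse.
    """
    if not 0 < inc_threshold <= 1:
        raise ValueError(f"inc_threshold must be in (0, 1], got {inc_threshold}")
    if n_threshold < 1:
        raise ValueError(f"n_threshold must be >= 1, got {n_threshold}")
    rows = []
    for r in tt.rows:
        if r.n < n_threshold:
            value: tuple[object, ...] = tuple(DC for _ in r.inclusion)
        else:
            value = tuple(1 if inc >= inc_threshold else 0 for inc in r.inclusion)
        rows.append(replace(r, value=value))
    return TruthTable(tt.input_names, tt.output_names, tuple(rows), inc_threshold, n_threshold)


def function_spec(tt: TruthTable) -> FunctionSpec:
    """Derive on/off sets from an assigned truth table; the rest is dc."""
    if not tt.assigned:
        raise ValueError("outputs not assigned; call assign_outputs first")
    on = [set() for _ in tt.output_names]
    off = [set() for _ in tt.output_names]
    for r in tt.rows:
        for j, v in enumerate(r.value):
            if v == 1:
                on[j].add(r.minterm)
            elif v == 0:
                off[j].add(r.minterm)
    return FunctionSpec(
        tt.width,
        tt.output_names,
        tuple(frozenset(s) for s in on),
        tuple(frozenset(s) for s in off),
    )


def spec_from_minterms(
    width: int,
    on: Mapping[str, Sequence[int]],
    dc: Mapping[str, Sequence[int]] | None = None,
) -> FunctionSpec:
    """Build a spec from per-output on-set (and optional dc-set) lists.

    The off-set of each output is the complement of on ∪ dc, so omitting
    ``dc`` gives a completely specified function.
    """
    dc = dc or {}
    space = frozenset(range(1 << width))
    names = tuple(on)
    on_sets, off_sets = [], []
    for name in names:
        on_j = frozenset(on[name])
        dc_j = frozenset(dc.get(name, ()))
        if not on_j <= space or not dc_j <= space:
            bad = sorted((on_j | dc_j) - space)
            raise ValueError(f"minterms {bad} out of range for width {width}")
        if on_j & dc_j:
            raise ValueError(f"on and dc sets of {name} overlap: {sorted(on_j & dc_j)}")
        on_sets.append(on_j)
        off_sets.append(space - on_j - dc_j)
    return FunctionSpec(width, names, tuple(on_sets), tuple(off_sets))


# -- Berkeley PLA interchange ------------------------------------------


class PlaFormatError(ValueError):
    pass


class PlaContradictionError(ValueError):
    """A minterm is asserted both on and off for the same output."""


def read_pla(stream: TextIO | str) -> FunctionSpec:
    """Read a Berkeley PLA file with .type fr semantics (the default).

    In the output part, '1' puts the covered minterms of that output in
    the on-set, '0' in the off-set, and '-' leaves them don't-care.
    Conflicting assertions for the same (minterm, output) raise
    :class:`PlaContradictionError`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    ni = no = None
    names: list[str] | None = None
    lines: list[tuple[str, str]] = []
    for raw in stream:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("~"):
            raise PlaFormatError("'~' comment lines are not supported")
        if line.startswith("."):
            parts = line.split()
            key = parts[0]
            if key == ".i":
                ni = int(parts[1])
            elif key == ".o":
                no = int(parts[1])
            elif key == ".ob":
                names = parts[1:]
            elif key == ".type":
                if parts[1] != "fr":
                    raise PlaFormatError(f"unsupported .type {parts[1]!r}")
            elif key in (".p", ".ilb", ".e", ".end"):
                pass
            else:
                raise PlaFormatError(f"unsupported directive {key}")
            continue
        parts = line.split()
        if len(parts) != 2:
            raise PlaFormatError(f"malformed cube line {line!r}")
        lines.append((parts[0], parts[1]))
    if ni is None or no is None:
        raise PlaFormatError("missing .i or .o declaration")
    out_names = tuple(names) if names else tuple(f"f{j + 1}" for j in range(no))
    if len(out_names) != no:
        raise PlaFormatError(".ob names do not match .o count")
    on = [set() for _ in range(no)]
    off = [set() for _ in range(no)]
    for inp, outp in lines:
        if len(inp) != ni or len(outp) != no:
            raise PlaFormatError(f"line width disagrees with .i/.o: {inp} {outp}")
        if not set(inp) <= {"0", "1", "-"} or not set(outp) <= {"0", "1", "-"}:
            raise PlaFormatError(f"bad characters in line {inp} {outp}")
        cube = parse_cube(inp)
        for m in cube.minterms():
            for j, ch in enumerate(outp):
                if ch == "1":
                    if m in off[j]:
                        raise PlaContradictionError(
                            f"minterm {m} asserted both on and off for output {out_names[j]}"
                        )
                    on[j].add(m)
                elif ch == "0":
                    if m in on[j]:
                        raise PlaContradictionError(
                            f"minterm {m} asserted both on and off for output {out_names[j]}"
                        )
                    off[j].add(m)
    return FunctionSpec(
        ni, out_names, tuple(frozenset(s) for s in on), tuple(frozenset(s) for s in off)
    )


def write_pla(spec: FunctionSpec, stream: TextIO) -> None:
    """Write a canonical minterm-level PLA (.type fr) for ``spec``."""
    relevant = sorted({m for j in range(spec.n_outputs) for m in spec.on[j] | spec.off[j]})
    stream.write(f".i {spec.width}\n.o {spec.n_outputs}\n")
    stream.write(".ob " + " ".join(spec.output_names) + "\n")
    stream.write(".type fr\n")
    stream.write(f".p {len(relevant)}\n")
    for m in relevant:
        inp = format(m, f"0{spec.width}b")
        outp = "".join(
            "1" if m in spec.on[j] else "0" if m in spec.off[j] else "-"
            for j in range(spec.n_outputs)
        )
        stream.write(f"{inp} {outp}\n")
    stream.write(".e\n")
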