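"""Logic-diagram (logigram) export: two-level gate netlists, DOT and SVG.

A system's models translate into a circuit the obvious way: each
multi-literal cube is an AND gate, each multi-term model an OR gate, and
negations become inverter markers on the source end of a wire.  With
shared gates enabled, a cube written into several models becomes a
single AND gate fanning out to every consuming OR gate — the circuit
picture of a common cause feeding a complex effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .cubes import Cube

__all__ = ["Netlist", "Wire", "build_netlist", "count_gates", "to_dot", "to_svg", "evaluate_netlist"]


@dataclass(frozen=True)
class Wire:
    source: str  # node id: "rail:<name>", "and:<n>", "or:<n>"
    dest: str  # node id, or "out:<name>"
    negated: bool = False  # inverter marker at the source end


@dataclass(frozen=True)
class Netlist:
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    and_gates: tuple[tuple[str, Cube], ...]  # (gate id, cube)
    or_gates: tuple[tuple[str, str], ...]  # (gate id, output name)
    wires: tuple[Wire, ...]

    def used_rails(self) -> tuple[str, ...]:
        used = {
            w.source.split(":", 1)[1] for w in self.wires if w.source.startswith("rail:")
        }
        return tuple(n for n in self.input_names if n in used)


def _cube_literals(cube: Cube, names: Sequence[str]) -> list[tuple[str, bool]]:
    """(input name, negated) per literal, in declaration order."""
    out = []
    for p, s in enumerate(cube.states()):
        if s != "-":
            out.append((names[p], s == "0"))
    return out


def build_netlist(
    models: Mapping[str, Sequence[Cube]] | Sequence[tuple[str, Sequence[Cube]]],
    input_names: Sequence[str],
    shared: bool = True,
) -> Netlist:
    """Gate-level circuit for a set of per-output models.

    shared=True merges identical multi-literal cubes across outputs into
    one AND gate with fan-out (joint optimization's payoff); shared=False
    instantiates one gate per occurrence (separate circuits).
    """
    items = list(models.items()) if isinstance(models, Mapping) else list(models)
    if not items:
        raise ValueError("empty model map")
    and_gates: list[tuple[str, Cube]] = []
    gate_of: dict[Cube, str] = {}
    or_gates: list[tuple[str, str]] = []
    wires: list[Wire] = []

    def and_gate_for(cube: Cube) -> str:
        if shared and cube in gate_of:
            return gate_of[cube]
        gid = f"and:{len(and_gates)}"
        and_gates.append((gid, cube))
        gate_of.setdefault(cube, gid)
        for name, neg in _cube_literals(cube, input_names):
            wires.append(Wire(f"rail:{name}", gid, neg))
        return gid

    for out, cubes in items:
        terms = []
        for cube in cubes:
            lits = _cube_literals(cube, input_names)
            if len(lits) >= 2:
                terms.append(("gate", and_gate_for(cube), False))
            elif len(lits) == 1:
                name, neg = lits[0]
                terms.append(("rail", f"rail:{name}", neg))
            else:  # universal cube: constant-1 source
                terms.append(("const", "const:1", False))
        if len(terms) >= 2:
            oid = f"or:{len(or_gates)}"
            or_gates.append((oid, out))
            for _, src, neg in terms:
                wires.append(Wire(src, oid, neg))
            wires.append(Wire(oid, f"out:{out}"))
        elif len(terms) == 1:
            _, src, neg = terms[0]
            wires.append(Wire(src, f"out:{out}", neg))
        # empty model: output is constantly 0, no wire

    # deduplicate fan-out wires into the same gate (shared AND feeding one OR twice
    # cannot happen; identical rail wires into the same AND can for repeated builds)
    seen = set()
    uniq = []
    for w in wires:
        if (w.source, w.dest, w.negated) not in seen:
            seen.add((w.source, w.dest, w.negated))
            uniq.append(w)
    return Netlist(
        tuple(input_names), tuple(out for out, _ in items),
        tuple(and_gates), tuple(or_gates), tuple(uniq),
    )


def count_gates(n: Netlist) -> tuple[int, int, int]:
    """(AND count, OR count, inverter count).

    Inverters are deduplicated per rail: negated uses of one input share
    a single inverter however many gates consume it.
    """
    inverted_rails = {
        w.source for w in n.wires if w.negated and w.source.startswith("rail:")
    }
    return len(n.and_gates), len(n.or_gates), len(inverted_rails)


def evaluate_netlist(n: Netlist, minterm: int) -> dict[str, int]:
    """Propagate 0/1 rail values through the gates; returns output values."""
    width = len(n.input_names)
    value: dict[str, int] = {"const:1": 1}
    for p, name in enumerate(n.input_names):
        value[f"rail:{name}"] = (minterm >> (width - 1 - p)) & 1

    fan_in: dict[str, list[Wire]] = {}
    for w in n.wires:
        fan_in.setdefault(w.dest, []).append(w)

    def signal(w: Wire) -> int:
        v = value[w.source]
        return 1 - v if w.negated else v

    for gid, _ in n.and_gates:
        value[gid] = int(all(signal(w) for w in fan_in.get(gid, [])))
    for gid, _ in n.or_gates:
        value[gid] = int(any(signal(w) for w in fan_in.get(gid, [])))
    out = {}
    for name in n.output_names:
        ws = fan_in.get(f"out:{name}", [])
        out[name] = int(any(signal(w) for w in ws)) if ws else 0
    return out


def to_dot(n: Netlist) -> str:
    """Deterministic Graphviz DOT rendering of the netlist.

    Rails are plaintext sources on the left, outputs double circles on
    the right; a negated wire carries an odot arrow-tail at its source
    end (the inverter marker).
    """
    lines = [
        "digraph logigram {",
        "  rankdir=LR;",
        "  node [fontname=Helvetica];",
    ]
    for name in n.used_rails():
        lines.append(f'  "rail:{name}" [shape=plaintext, label="{name}"];')
    if any(w.source == "const:1" for w in n.wires):
        lines.append('  "const:1" [shape=plaintext, label="1"];')
    for gid, cube in n.and_gates:
        lines.append(f'  "{gid}" [shape=invhouse, orientation=270, label="AND"];')
    for gid, out in n.or_gates:
        lines.append(f'  "{gid}" [shape=house, orientation=270, label="OR"];')
    for name in n.output_names:
        lines.append(f'  "out:{name}" [shape=doublecircle, label="{name}"];')
    for w in n.wires:
        attrs = []
        if w.negated:
            attrs.append("dir=both")
            attrs.append("arrowtail=odot")
        attr = (" [" + ", ".join(attrs) + "]") if attrs else ""
        lines.append(f'  "{w.source}" -> "{w.dest}"{attr};')
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_svg(n: Netlist) -> str:
    """Self-contained SVG with a simple three-column layout.

    Rails on the left, gates in the middle, outputs on the right; AND
    gates are D-shaped, OR gates shield-shaped, negation is a small open
    circle at the source end of a wire.  Layout is deterministic.
    """
    rails = n.used_rails()
    col_x = {"rail": 60, "and": 220, "or": 380, "out": 520}
    pos: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(rails):
        pos[f"rail:{name}"] = (col_x["rail"], 40 + 50 * i)
    if any(w.source == "const:1" for w in n.wires):
        pos["const:1"] = (col_x["rail"], 40 + 50 * len(rails))
    for i, (gid, _) in enumerate(n.and_gates):
        pos[gid] = (col_x["and"], 40 + 60 * i)
    for i, (gid, _) in enumerate(n.or_gates):
        pos[gid] = (col_x["or"], 40 + 60 * i)
    for i, name in enumerate(n.output_names):
        pos[f"out:{name}"] = (col_x["out"], 40 + 60 * i)
    height = 80 + 60 * max(len(rails) + 1, len(n.and_gates), len(n.or_gates), len(n.output_names))
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="600" height="{height}" '
        'font-family="Helvetica" font-size="12">'
    ]
    for w in n.wires:
        x1, y1 = pos[w.source]
        x2, y2 = pos.get(w.dest, pos.get(w.dest, (0, 0)))
        if w.dest not in pos:
            continue
        parts.append(
            f'<line x1="{x1 + 18}" y1="{y1}" x2="{x2 - 18}" y2="{y2}" stroke="black"/>'
        )
        if w.negated:
            parts.append(
                f'<circle cx="{x1 + 22}" cy="{y1}" r="4" fill="white" stroke="black"/>'
            )
    for name in rails:
        x, y = pos[f"rail:{name}"]
        parts.append(f'<text x="{x - 30}" y="{y + 4}">{name}</text>')
        parts.append(f'<circle cx="{x + 14}" cy="{y}" r="2"/>')
    if "const:1" in pos:
        x, y = pos["const:1"]
        parts.append(f'<text x="{x - 30}" y="{y + 4}">1</text>')
    for gid, cube in n.and_gates:
        x, y = pos[gid]
        parts.append(
            f'<path d="M {x - 16} {y - 14} h 14 a 14 14 0 0 1 0 28 h -14 z" '
            'fill="white" stroke="black"/>'
        )
        parts.append(f'<text x="{x - 13}" y="{y + 4}">&amp;</text>')
    for gid, _ in n.or_gates:
        x, y = pos[gid]
        parts.append(
            f'<path d="M {x - 18} {y - 14} q 10 14 0 28 q 22 -4 30 -14 '
            f'q -8 -10 -30 -14 z" fill="white" stroke="black"/>'
        )
        parts.append(f'<text x="{x - 10}" y="{y + 4}">≥1</text>')
    for name in n.output_names:
        x, y = pos[f"out:{name}"]
        parts.append(f'<circle cx="{x}" cy="{y}" r="14" fill="white" stroke="black"/>')
        parts.append(f'<text x="{x + 20}" y="{y + 4}">{name}</text>')
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
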