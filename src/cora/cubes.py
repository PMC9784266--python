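"""Product terms (cubes) over k binary inputs.

A cube is a conjunction of literals, e.g. ``x'z`` over inputs (x, y, z).
Each input position is in one of three states: asserted (1), negated (0)
or absent (``-``).  Internally a cube is a pair of bitmasks, ``care``
(which positions carry a literal) and ``bits`` (the literal's polarity),
so merging, containment and expansion are O(1) integer operations.

Bit order convention, fixed project-wide: the FIRST declared input is the
most significant bit of a minterm index, so with inputs (x, y, z) the
minterm 1 is x'y'z (binary 001) and 3 is x'yz (011).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Cube",
    "cube_from_minterm",
    "covers",
    "merge_adjacent",
    "expansions",
    "evaluate_model",
    "parse_cube",
    "format_cube",
]


class DimensionError(ValueError):
    """Cube widths (input counts) do not agree."""


@dataclass(frozen=True, order=True)
class Cube:
    """A product of literals over ``width`` binary inputs.

    ``care`` has a 1-bit at every position carrying a literal; ``bits``
    holds the asserted/negated polarity there (and is 0 elsewhere).
    Position p (0 = first declared input) maps to bit ``width - 1 - p``.
    """

    width: int
    care: int
    bits: int

    def __post_init__(self) -> None:
        full = (1 << self.width) - 1
        if self.care & ~full:
            raise ValueError("care mask exceeds width")
        if self.bits & ~self.care:
            raise ValueError("bits set outside care mask")

    # -- basic geometry -------------------------------------------------

    @property
    def n_literals(self) -> int:
        return self.care.bit_count()

    @property
    def n_dashes(self) -> int:
        return self.width - self.n_literals

    def states(self) -> tuple[str, ...]:
        """Per-position states, '0' / '1' / '-', first input first."""
        out = []
        for p in range(self.width):
            b = 1 << (self.width - 1 - p)
            if not self.care & b:
                out.append("-")
            else:
                out.append("1" if self.bits & b else "0")
        return tuple(out)

    def __str__(self) -> str:
        return "".join(self.states())

    def minterms(self) -> Iterator[int]:
        """All minterm indices covered, ascending; 2**n_dashes of them."""
        free = [1 << i for i in range(self.width) if not self.care & (1 << i)]
        base = self.bits
        for sel in range(1 << len(free)):
            m = base
            for j, bit in enumerate(free):
                if sel >> j & 1:
                    m |= bit
            yield m

    def minterm_mask(self) -> int:
        """Bitset over [0, 2**width) of the covered minterms."""
        mask = 0
        for m in self.minterms():
            mask |= 1 << m
        return mask

    def contains(self, other: "Cube") -> bool:
        """True iff every minterm of ``other`` is covered by self."""
        if self.width != other.width:
            raise DimensionError(f"width mismatch: {self.width} vs {other.width}")
        return (self.care & ~other.care) == 0 and (
            (self.bits ^ other.bits) & self.care
        ) == 0

    # -- rendering ------------------------------------------------------

    def to_expression(self, names: Sequence[str]) -> str:
        """Render in literal notation, e.g. ``x'z`` or ``mys·roca``.

        Single-character names are juxtaposed; longer names are joined
        with the middle-dot conjunction sign. The universal cube renders
        as "1".
        """
        if len(names) != self.width:
            raise DimensionError("name list length != cube width")
        parts = []
        for p, s in enumerate(self.states()):
            if s == "-":
                continue
            parts.append(names[p] + ("'" if s == "0" else ""))
        if not parts:
            return "1"
        sep = "" if all(len(n) == 1 for n in names) else "·"
        return sep.join(parts)


def cube_from_minterm(index: int, width: int) -> Cube:
    """The fully specified cube covering exactly one minterm."""
    if not 0 <= index < (1 << width):
        raise ValueError(f"minterm index {index} out of range for width {width}")
    full = (1 << width) - 1
    return Cube(width, full, index)


def covers(c: Cube, m: int) -> bool:
    """True iff every literal of c agrees with the corresponding bit of m."""
    if not 0 <= m < (1 << c.width):
        raise DimensionError(f"minterm {m} out of range for width {c.width}")
    return ((m ^ c.bits) & c.care) == 0


def merge_adjacent(a: Cube, b: Cube) -> Cube | None:
    """Quine–McCluskey adjacency: combine two cubes differing in one literal.

    Returns the merged cube (that literal replaced by a dash) when a and b
    share the same dash pattern and differ in exactly one specified
    position; returns None otherwise.  The result covers exactly the
    union of the operands' minterms.
    """
    if a.width != b.width:
        raise DimensionError(f"width mismatch: {a.width} vs {b.width}")
    if a.care != b.care:
        return None
    diff = a.bits ^ b.bits
    if diff == 0 or diff & (diff - 1):
        return None  # zero or >1 differing positions
    return Cube(a.width, a.care & ~diff, a.bits & ~diff)


def expansions(c: Cube) -> set[Cube]:
    """One cube per literal of c, with that literal cancelled.

    Each result strictly contains c; the universal cube has none.
    """
    out = set()
    rest = c.care
    while rest:
        bit = rest & -rest
        rest ^= bit
        out.add(Cube(c.width, c.care ^ bit, c.bits & ~bit))
    return out


def evaluate_model(model: Iterable[Cube], m: int) -> int:
    """Evaluate a disjunction of cubes at minterm m; empty model is 0."""
    for c in model:
        if covers(c, m):
            return 1
    return 0


# -- text forms ---------------------------------------------------------


def parse_cube(text: str, names: Sequence[str] | None = None) -> Cube:
    """Parse either positional form ("0-1") or literal form ("x'z").

    Literal form needs ``names``; it accepts juxtaposed single-character
    names, "·"/"*" separated names, and postfix apostrophe negation.
    "1" denotes the universal cube.
    """
    text = text.strip()
    if names is not None and not set(text) <= {"0", "1", "-"}:
        return _parse_literals(text, names)
    if set(text) <= {"0", "1", "-"} and (names is None or len(text) == len(names)):
        width = len(text)
        care = bits = 0
        for p, ch in enumerate(text):
            b = 1 << (width - 1 - p)
            if ch != "-":
                care |= b
                if ch == "1":
                    bits |= b
        return Cube(width, care, bits)
    if names is None:
        raise ValueError(f"cannot parse cube {text!r} without input names")
    return _parse_literals(text, names)


def _parse_literals(text: str, names: Sequence[str]) -> Cube:
    width = len(names)
    if text == "1":
        return Cube(width, 0, 0)
    pos = {n: p for p, n in enumerate(names)}
    tokens: list[str] = []
    if "·" in text or "*" in text:
        tokens = [t for t in text.replace("*", "·").split("·") if t]
    else:
        # greedy longest-name-first scan handles juxtaposed names
        i = 0
        ordered = sorted(names, key=len, reverse=True)
        while i < len(text):
            for n in ordered:
                if text.startswith(n, i):
                    j = i + len(n)
                    if j < len(text) and text[j] == "'":
                        j += 1
                    tokens.append(text[i:j])
                    i = j
                    break
            else:
                raise ValueError(f"unknown literal at {text[i:]!r}")
    care = bits = 0
    for tok in tokens:
        neg = tok.endswith("'")
        name = tok[:-1] if neg else tok
        if name not in pos:
            raise ValueError(f"unknown input name {name!r}")
        b = 1 << (width - 1 - pos[name])
        if care & b:
            raise ValueError(f"input {name!r} appears twice in {text!r}")
        care |= b
        if not neg:
            bits |= b
    return Cube(width, care, bits)


def format_cube(c: Cube, names: Sequence[str]) -> str:
    return c.to_expression(names)


def canonical_order(c: Cube) -> tuple[int, str]:
    """Sort key used project-wide: fewer literals first, then positional string."""
    return (c.n_literals, str(c))
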