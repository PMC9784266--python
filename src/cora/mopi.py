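"""Multi-output prime implicant (MOPI) generation.

A MOPI of a system of functions F = {f_1, ..., f_m} is a cube that is a
prime implicant of some individual output function or of a product of
output functions.  Operationally we carry each cube's *output tag* — the
maximal set of outputs whose off-sets the cube avoids — and use:

    a cube c with non-empty tag T(c) is a MOPI  iff
    no one-literal expansion c' of c has T(c') ⊇ T(c).

Proof sketch of the equivalence with the products-of-functions phrasing:
the product function over T(c) is the largest product that c implies
(implying f_j means avoiding off_j, and T(c) collects exactly those j).
c is a PI of that product iff no literal can be cancelled while still
implying it, i.e. iff no expansion keeps a tag containing T(c).  If some
expansion c' had T(c') ⊋ T(c) that is impossible since T is monotone
decreasing under expansion (c' covers more minterms), so the condition
reduces to "no expansion has a tag superset".  Conversely a PI of a
smaller product P ⊂ T(c) is never listed separately: its tag is still
T(c) and the cube is the same object.

Two generation routes are provided — a tagged Quine–McCluskey merge over
on ∪ dc ("on-dc") and an expansion search against the off-sets
("on-off") — plus a literal brute-force enumeration of all 3**k cubes
used as the oracle in tests.  All three return identical sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .cubes import Cube, canonical_order, cube_from_minterm, expansions
from .truthtable import FunctionSpec

__all__ = ["TaggedImplicant", "output_tag", "is_mopi", "generate_mopis", "brute_force_mopis"]

#: generation is refused above this input count; use mining to shrink the pool
HARD_WIDTH_LIMIT = 20
BRUTE_FORCE_LIMIT = 10


class CapacityError(RuntimeError):
    pass


@dataclass(frozen=True)
class TaggedImplicant:
    """A cube together with its maximal output tag."""

    cube: Cube
    tag: frozenset[str]

    def __post_init__(self) -> None:
        if not self.tag:
            raise ValueError("tag must be non-empty")

    def to_text(self, input_names, output_order) -> str:
        members = ",".join(o for o in output_order if o in self.tag)
        return f"{self.cube.to_expression(input_names)}\t{members}"


def _tag_bits(cube: Cube, off_masks: list[int]) -> int:
    """Tag as a bitmask over output indices (bit j set iff cube avoids off_j)."""
    cov = cube.minterm_mask()
    t = 0
    for j, off in enumerate(off_masks):
        if not cov & off:
            t |= 1 << j
    return t


def output_tag(cube: Cube, spec: FunctionSpec) -> frozenset[str]:
    """The maximal set of outputs whose off-set the cube does not touch."""
    if cube.width != spec.width:
        raise ValueError(f"width mismatch: cube {cube.width}, spec {spec.width}")
    bits = _tag_bits(cube, [spec.off_mask(j) for j in range(spec.n_outputs)])
    return frozenset(
        spec.output_names[j] for j in range(spec.n_outputs) if bits >> j & 1
    )


def _covers_some_on(cube: Cube, spec: FunctionSpec, tag_bits: int) -> bool:
    cov = cube.minterm_mask()
    for j in range(spec.n_outputs):
        if tag_bits >> j & 1 and cov & spec.on_mask(j):
            return True
    return False


def is_mopi(cube: Cube, spec: FunctionSpec) -> bool:
    """Primality + usefulness test straight from the definition.

    True iff the cube implies at least one output function (non-empty
    tag), no one-literal cancellation preserves a tag superset, and the
    cube covers at least one on-minterm of a tagged output (cubes lying
    entirely in don't-care space can never appear in a chart).
    """
    off_masks = [spec.off_mask(j) for j in range(spec.n_outputs)]
    t = _tag_bits(cube, off_masks)
    if t == 0:
        return False
    for exp in expansions(cube):
        if _tag_bits(exp, off_masks) & t == t:
            return False
    return _covers_some_on(cube, spec, t)


def _finalize(candidates: Iterable[Cube], spec: FunctionSpec) -> list[TaggedImplicant]:
    """Apply the explicit primality/usefulness filters and order canonically."""
    out = []
    for cube in set(candidates):
        if is_mopi(cube, spec):
            out.append(TaggedImplicant(cube, output_tag(cube, spec)))
    out.sort(key=lambda ti: canonical_order(ti.cube))
    return out


def _on_dc_candidates(spec: FunctionSpec) -> set[Cube]:
    """Tagged Quine–McCluskey merge over the on ∪ dc space.

    Seeds are the minterms lying in on ∪ dc of at least one output,
    tagged with all such outputs.  Adjacent cubes merge into a cube
    tagged with the intersection of their tags (dropped when empty); a
    cube is checked off only by a merge whose result carries the cube's
    own full tag — checked-off cubes cannot be prime, survivors are the
    candidates.
    """
    space = range(1 << spec.width)
    current: dict[Cube, int] = {}
    for m in space:
        t = 0
        for j in range(spec.n_outputs):
            if m not in spec.off[j]:
                t |= 1 << j
        if t:
            current[cube_from_minterm(m, spec.width)] = t
    survivors: set[Cube] = set()
    while current:
        merged: dict[Cube, int] = {}
        checked: set[Cube] = set()
        # group by dash pattern, then by popcount of value bits, so only
        # genuinely adjacent pairs are tried
        by_pattern: dict[int, dict[int, list[Cube]]] = {}
        for cube in current:
            by_pattern.setdefault(cube.care, {}).setdefault(
                cube.bits.bit_count(), []
            ).append(cube)
        for care, groups in by_pattern.items():
            for cnt, cubes in groups.items():
                uppers = groups.get(cnt + 1, [])
                for a in cubes:
                    for b in uppers:
                        diff = a.bits ^ b.bits
                        if diff & (diff - 1):
                            continue
                        t = current[a] & current[b]
                        if not t:
                            continue
                        res = Cube(a.width, care & ~diff, a.bits & ~diff)
                        merged[res] = merged.get(res, 0) | t
                        if t == current[a]:
                            checked.add(a)
                        if t == current[b]:
                            checked.add(b)
        survivors.update(c for c in current if c not in checked)
        current = merged
    return survivors


def _on_off_candidates(spec: FunctionSpec) -> set[Cube]:
    """Expansion search seeded from on-minterms, pruned by the off-sets.

    Grows cubes by cancelling literals as long as the cube still implies
    at least one output function; every useful MOPI contains an
    on-minterm of a tagged output and is therefore reached from that
    minterm's seed cube through tag-preserving intermediate cubes.
    """
    off_masks = [spec.off_mask(j) for j in range(spec.n_outputs)]
    seeds = {m for j in range(spec.n_outputs) for m in spec.on[j]}
    frontier = {cube_from_minterm(m, spec.width) for m in seeds}
    seen: set[Cube] = set()
    while frontier:
        nxt: set[Cube] = set()
        for cube in frontier:
            if cube in seen:
                continue
            seen.add(cube)
            for exp in expansions(cube):
                if exp not in seen and _tag_bits(exp, off_masks):
                    nxt.add(exp)
        frontier = nxt
    return seen


def generate_mopis(
    spec: FunctionSpec, algorithm: Literal["on-dc", "on-off"] = "on-dc"
) -> list[TaggedImplicant]:
    """The complete MOPI set of ``spec``, canonically ordered.

    Both algorithmic routes return the identical set; "on-off" tends to
    win when the don't-care space dwarfs the off-sets, "on-dc"
    otherwise.
    """
    if spec.width > HARD_WIDTH_LIMIT:
        raise CapacityError(
            f"{spec.width} inputs exceeds the limit of {HARD_WIDTH_LIMIT}; "
            "consider mining a smaller input tuple first"
        )
    if algorithm == "on-dc":
        candidates = _on_dc_candidates(spec)
    elif algorithm == "on-off":
        candidates = _on_off_candidates(spec)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return _finalize(candidates, spec)


def brute_force_mopis(spec: FunctionSpec) -> list[TaggedImplicant]:
    """Oracle: test all 3**k cubes literally against the definition."""
    if spec.width > BRUTE_FORCE_LIMIT:
        raise CapacityError(f"brute force limited to {BRUTE_FORCE_LIMIT} inputs")

    def all_cubes(width: int):
        def rec(p: int, care: int, bits: int):
            if p == width:
                yield Cube(width, care, bits)
                return
            b = 1 << (width - 1 - p)
            yield from rec(p + 1, care, bits)  # dash
            yield from rec(p + 1, care | b, bits)  # negated
            yield from rec(p + 1, care | b, bits | b)  # asserted
        yield from rec(0, 0, 0)

    return _finalize((c for c in all_cubes(spec.width) if is_mopi(c, spec)), spec)
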