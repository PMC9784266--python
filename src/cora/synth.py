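"""Synthetic case-table and function-spec generators for testing.

Planted-model generation works backwards from a known two-level
structure: draw per-output disjunctions of cubes over a subset of the
inputs, evaluate them on input configurations, optionally flip output
bits with a noise rate, and emit the result as a case table.  At noise
zero and full factorial sampling, solving recovers functions exactly
equal to the planted ones, and any irrelevant padding inputs stay out of
the recovered systems — the property the mining module relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cases import CaseTable
from .cubes import Cube, evaluate_model
from .truthtable import FunctionSpec, spec_from_minterms

__all__ = ["PlantedSystem", "random_cube", "random_spec", "plant_system", "cases_from_models"]


@dataclass(frozen=True)
class PlantedSystem:
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    models: tuple[tuple[str, tuple[Cube, ...]], ...]

    def evaluate(self, minterm: int) -> tuple[int, ...]:
        return tuple(
            evaluate_model(list(cubes), minterm) for _, cubes in self.models
        )


def random_cube(rng: np.random.Generator, width: int, min_literals: int = 1) -> Cube:
    """A uniform random cube with at least ``min_literals`` literals."""
    n_lit = int(rng.integers(min_literals, width + 1))
    positions = rng.choice(width, size=n_lit, replace=False)
    care = bits = 0
    for p in positions:
        b = 1 << (width - 1 - int(p))
        care |= b
        if rng.integers(2):
            bits |= b
    return Cube(width, care, bits)


def random_spec(
    rng: np.random.Generator,
    width: int,
    n_outputs: int,
    n_observed: int | None = None,
) -> FunctionSpec:
    """A random incompletely specified multi-output function.

    Emulates the shape of configurational case data: only ``n_observed``
    input configurations carry an assigned value (1 or 0 per output,
    uniformly); every other configuration is an unobserved remainder and
    hence don't-care.  Comparative studies observe far fewer
    configurations than the 2**k possible ones — 7 of 32, 11 of 16 in
    the bundled examples — and the default draws a count in that range.
    Each output is forced to a non-empty on-set so a chart always
    exists.
    """
    space = 1 << width
    if n_observed is None:
        hi = min(space, 24)
        lo = min(space, max(3, width))
        n_observed = int(rng.integers(lo, hi + 1))
    observed = rng.choice(space, size=min(n_observed, space), replace=False)
    on: dict[str, list[int]] = {}
    dc: dict[str, list[int]] = {}
    rest = [m for m in range(space) if m not in set(int(x) for x in observed)]
    for j in range(n_outputs):
        name = f"f{j + 1}"
        values = rng.integers(0, 2, len(observed))
        on[name] = [int(m) for m, v in zip(observed, values) if v]
        if not on[name]:
            on[name] = [int(observed[int(rng.integers(len(observed)))])]
        dc[name] = rest
    return spec_from_minterms(width, on, dc)


def plant_system(
    rng: np.random.Generator,
    n_relevant: int,
    n_irrelevant: int,
    n_outputs: int,
    terms_per_output: int = 2,
) -> PlantedSystem:
    """Plant per-output models over the first ``n_relevant`` inputs only.

    The remaining inputs are causally irrelevant padding: they never
    appear in any planted cube, so solutions on the full input set must
    coincide with solutions on the relevant subset (the superset
    property mining exploits).
    """
    width = n_relevant + n_irrelevant
    names = tuple(f"x{i + 1}" for i in range(width))
    outputs = tuple(f"f{j + 1}" for j in range(n_outputs))
    models = []
    for out in outputs:
        cubes = []
        for _ in range(terms_per_output):
            c = random_cube(rng, n_relevant, min_literals=1)
            # embed the relevant-width cube into the full width (leading inputs)
            shift = n_irrelevant
            cubes.append(Cube(width, c.care << shift, c.bits << shift))
        models.append((out, tuple(cubes)))
    return PlantedSystem(names, outputs, tuple(models))


def cases_from_models(
    planted: PlantedSystem,
    rng: np.random.Generator | None = None,
    n_cases: int | None = None,
    noise: float = 0.0,
) -> CaseTable:
    """Materialize a case table from planted models.

    With ``n_cases`` None every input configuration appears exactly once
    (full factorial); otherwise configurations are drawn uniformly with
    replacement.  ``noise`` is the per-output bit-flip probability.
    """
    width = len(planted.input_names)
    if n_cases is None:
        minterms = list(range(1 << width))
    else:
        if rng is None:
            raise ValueError("sampling cases requires an rng")
        minterms = [int(m) for m in rng.integers(0, 1 << width, n_cases)]
    inputs = np.array(
        [[(m >> (width - 1 - p)) & 1 for p in range(width)] for m in minterms],
        dtype=np.int8,
    )
    outputs = np.array([planted.evaluate(m) for m in minterms], dtype=np.int8)
    if noise > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        flips = rng.random(outputs.shape) < noise
        outputs = np.where(flips, 1 - outputs, outputs).astype(np.int8)
    ids = tuple(f"c{i + 1}" for i in range(len(minterms)))
    return CaseTable(ids, planted.input_names, planted.output_names, inputs, outputs)
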