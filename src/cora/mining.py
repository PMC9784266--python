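"""Input-tuple mining: ascending search for the smallest sufficient input sets.

Any system found with a given input pool must also be found, ceteris
paribus, when the analysis is restricted to exactly the inputs appearing
in that system.  Mining exploits this superset property in reverse: it
tests singletons first, then pairs, and so on, solving the analysis on
each candidate tuple and keeping the tuples whose solutions meet the
researcher's fit criteria.  Smaller explanations are preferred purely on
the number of inputs involved (Occam's razor over variables, not over
the number of prime implicants in a sum).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

from .cases import CaseTable
from .systems import Solution, model_fit, solve

__all__ = ["MiningResult", "TupleRecord", "mine"]

TUPLE_CAP = 10**5


class MiningCapacityError(RuntimeError):
    pass


@dataclass(frozen=True)
class TupleRecord:
    inputs: tuple[str, ...]
    passed: bool
    #: per output: (consistency, coverage) of the best system's model,
    #: or None when the solution has no system
    fit: tuple[tuple[str, float | None, float], ...]
    n_systems: int


@dataclass(frozen=True)
class MiningResult:
    tested: tuple[TupleRecord, ...]
    passing: tuple[tuple[tuple[str, ...], Solution], ...]
    parameters: tuple[tuple[str, object], ...]

    def report(self) -> str:
        lines = ["tuple\tsize\tpass\tsystems\tfit(output: cons/cov)"]
        for r in self.tested:
            fit = "; ".join(
                f"{o}: {('%.3f' % c) if c is not None else 'NA'}/{v:.3f}"
                for o, c, v in r.fit
            )
            lines.append(
                f"{','.join(r.inputs)}\t{len(r.inputs)}\t"
                f"{'yes' if r.passed else 'no'}\t{r.n_systems}\t{fit}"
            )
        return "\n".join(lines)


def _evaluate_tuple(
    cases: CaseTable,
    inputs: tuple[str, ...],
    inc_threshold: float,
    cov_threshold: float,
    n_threshold: int,
) -> tuple[TupleRecord, Solution]:
    sub = cases.restrict(inputs)
    sol = solve(sub, inc_threshold=inc_threshold, n_threshold=n_threshold)
    best_fit: tuple | None = None
    passed = False
    for system in sol.systems:
        fit = tuple(
            (out, *model_fit(list(cubes), out, sub)) for out, cubes in system.models
        )
        ok = all(cov >= cov_threshold for _, _, cov in fit)
        if best_fit is None or (ok and not passed):
            best_fit = fit
        if ok:
            passed = True
            break
    if best_fit is None:  # no system at all (e.g. all outputs constant 0)
        best_fit = tuple((out, None, 0.0) for out in cases.output_names)
    return TupleRecord(inputs, passed, best_fit, len(sol.systems)), sol


def mine(
    cases: CaseTable,
    pool: Sequence[str],
    inc_threshold: float,
    cov_threshold: float,
    max_k: int | None = None,
    mode: Literal["first_size", "exhaustive"] = "first_size",
    n_threshold: int = 1,
    tuple_cap: int = TUPLE_CAP,
) -> MiningResult:
    """Test input tuples of ascending size against the fit criteria.

    A tuple passes when its solution contains at least one system whose
    model for EVERY output reaches ``cov_threshold`` coverage over the
    cases (row consistency is enforced upstream by ``inc_threshold``
    during truth-table assignment and is recorded per output).

    ``first_size`` stops after the first size at which at least one
    tuple passes — all passing tuples of that size are reported;
    ``exhaustive`` tests every size up to ``max_k``.
    """
    pool = tuple(pool)
    unknown = [n for n in pool if n not in cases.input_names]
    if unknown:
        raise ValueError(f"pool names not in case table: {unknown}")
    if max_k is None:
        max_k = len(pool)
    if not 1 <= max_k <= len(pool):
        raise ValueError(f"max_k must be in [1, {len(pool)}], got {max_k}")
    total = sum(_ncr(len(pool), k) for k in range(1, max_k + 1))
    if total > tuple_cap:
        raise MiningCapacityError(
            f"{total} candidate tuples exceed the cap of {tuple_cap}"
        )
    tested: list[TupleRecord] = []
    passing: list[tuple[tuple[str, ...], Solution]] = []
    for k in range(1, max_k + 1):
        found_at_size = False
        for combo in itertools.combinations(pool, k):
            rec, sol = _evaluate_tuple(
                cases, combo, inc_threshold, cov_threshold, n_threshold
            )
            tested.append(rec)
            if rec.passed:
                found_at_size = True
                passing.append((combo, sol))
        if found_at_size and mode == "first_size":
            break
    return MiningResult(
        tuple(tested),
        tuple(passing),
        (
            ("inc_threshold", inc_threshold),
            ("cov_threshold", cov_threshold),
            ("max_k", max_k),
            ("mode", mode),
        ),
    )


def _ncr(n: int, k: int) -> int:
    import math

    return math.comb(n, k)
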