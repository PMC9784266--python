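"""Case-level data: reading, validation and model reports.

A :class:`CaseTable` holds one row per case (patient group, country, ...)
with binary input and output columns.  The declared order of the input
names — not the column order in the file — fixes the minterm bit order
used everywhere downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from .cubes import Cube

__all__ = ["CaseTable", "read_cases_csv", "write_cases_csv", "format_model", "parse_model"]


class SchemaError(ValueError):
    """A declared column is missing from the file."""


@dataclass(frozen=True)
class CaseTable:
    """Binary observations: cases × (inputs, outputs)."""

    case_ids: tuple[str, ...]
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    inputs: np.ndarray  # shape (n_cases, n_inputs), dtype int8, values 0/1
    outputs: np.ndarray  # shape (n_cases, n_outputs)

    def __post_init__(self) -> None:
        if not self.input_names or not self.output_names:
            raise ValueError("input_names and output_names must be non-empty")
        if set(self.input_names) & set(self.output_names):
            raise ValueError("input and output names overlap")
        if len(set(self.case_ids)) != len(self.case_ids):
            dup = sorted({c for c in self.case_ids if self.case_ids.count(c) > 1})
            raise ValueError(f"duplicate case ids: {dup}")
        for arr, names in ((self.inputs, self.input_names), (self.outputs, self.output_names)):
            if arr.shape != (len(self.case_ids), len(names)):
                raise ValueError("value matrix shape does not match declared names")
            if not np.isin(arr, (0, 1)).all():
                raise ValueError("all case values must be 0 or 1")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def width(self) -> int:
        return len(self.input_names)

    def minterm(self, row: int) -> int:
        """Decimal configuration index of a case (first input = MSB)."""
        idx = 0
        for v in self.inputs[row]:
            idx = (idx << 1) | int(v)
        return idx

    def restrict(self, input_subset: Sequence[str]) -> "CaseTable":
        """Project onto a subset of inputs (order taken from the subset)."""
        missing = [n for n in input_subset if n not in self.input_names]
        if missing:
            raise SchemaError(f"unknown inputs: {missing}")
        cols = [self.input_names.index(n) for n in input_subset]
        return CaseTable(
            self.case_ids,
            tuple(input_subset),
            self.output_names,
            self.inputs[:, cols].copy(),
            self.outputs.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.hstack([self.inputs, self.outputs]),
            columns=list(self.input_names) + list(self.output_names),
            index=list(self.case_ids),
        )
        df.index.name = "case"
        return df


def read_cases_csv(
    source: TextIO | str,
    input_names: Sequence[str],
    output_names: Sequence[str],
) -> CaseTable:
    """Read a header-full CSV of binary case data.

    The header must contain every declared input and output column (in
    any order); an unnamed first column, if present, supplies case ids,
    otherwise rows are numbered c1, c2, ...  Cells must be 0 or 1.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    first = df.columns[0]
    if first.startswith("Unnamed") or first.strip() == "":
        df = df.rename(columns={first: "_case_"})
        ids = tuple(str(v).strip() for v in df["_case_"])
    else:
        declared = set(input_names) | set(output_names)
        if first not in declared:
            ids = tuple(str(v).strip() for v in df[first])
        else:
            ids = tuple(f"c{i + 1}" for i in range(len(df)))
    missing = [c for c in list(input_names) + list(output_names) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")

    def parse_block(names: Sequence[str]) -> np.ndarray:
        mat = np.empty((len(df), len(names)), dtype=np.int8)
        for j, name in enumerate(names):
            for i, raw in enumerate(df[name]):
                val = str(raw).strip()
                if val not in ("0", "1"):
                    raise ValueError(
                        f"non-binary value {raw!r} at row {i + 1}, column {name!r}"
                    )
                mat[i, j] = int(val)
        return mat

    return CaseTable(ids, tuple(input_names), tuple(output_names), parse_block(input_names), parse_block(output_names))


def write_cases_csv(table: CaseTable, stream: TextIO) -> None:
    table.to_frame().to_csv(stream)


def format_model(model: Sequence[Cube], output_name: str, input_names: Sequence[str]) -> str:
    """Render a disjunction of cubes, e.g. ``mys·roca + roca <=> mvta``.

    Disjuncts are joined in the given order (callers pass canonical
    order); an empty model renders as "0".
    """
    if not model:
        body = "0"
    else:
        body = " + ".join(c.to_expression(input_names) for c in model)
    return f"{body} <=> {output_name}"


def parse_model(text: str, input_names: Sequence[str]) -> tuple[list[Cube], str]:
    """Inverse of :func:`format_model`; returns (cubes, output name)."""
    from .cubes import parse_cube

    lhs, _, rhs = text.partition("<=>")
    rhs = rhs.strip()
    lhs = lhs.strip()
    if lhs == "0":
        return [], rhs
    cubes = [parse_cube(t.strip(), input_names) for t in lhs.split("+")]
    return cubes, rhs
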