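"""Charts, irredundant-system enumeration, writing rule, fit statistics."""

import itertools

import numpy as np
import pytest

from cora import datasets
from cora.cubes import evaluate_model, expansions, parse_cube
from cora.mopi import generate_mopis
from cora.synth import random_spec
from cora.systems import (
    build_chart,
    enumerate_irredundant_systems,
    essential_rows,
    model_fit,
    solve,
    write_models,
)
from cora.truthtable import aggregate, assign_outputs, function_spec, spec_from_minterms

INJ = ("gnp", "mys", "apac", "unem", "roca")
XYZ = ("x", "y", "z")


@pytest.fixture(scope="module")
def injuries_spec():
    return function_spec(assign_outputs(aggregate(datasets.injury_rates()), 0.6, 1))


def exhaustive_minimal_covers(chart):
    """Oracle: scan all row subsets for inclusion-minimal covers."""
    n = len(chart.rows)
    assert n <= 15
    covers = []
    for k in range(n + 1):
        for sub in itertools.combinations(range(n), k):
            s = set(sub)
            if all(s & col for col in chart.marks) and not any(c <= s for c in covers):
                covers.append(frozenset(sub))
    return set(covers)


def f_equivalent(system, spec):
    for j, out in enumerate(spec.output_names):
        model = list(system.model(out))
        if any(evaluate_model(model, m) != 1 for m in spec.on[j]):
            return False
        if any(evaluate_model(model, m) != 0 for m in spec.off[j]):
            return False
    return True


class TestBuildChart:
    def test_injury_chart_shape(self, injuries_spec):
        chart = build_chart(generate_mopis(injuries_spec), injuries_spec, INJ)
        assert len(chart.rows) == 11
        assert chart.columns == (
            ("mvta", 3), ("mvta", 5), ("mvta", 7), ("mvta", 23), ("mvta", 31),
            ("ssii", 24), ("ssii", 30), ("ssii", 31),
        )
        i = next(
            i for i, r in enumerate(chart.rows)
            if r.cube.to_expression(INJ) == "mys·roca"
        )
        assert chart.row_marks(i) == {
            chart.columns.index(("mvta", 31)), chart.columns.index(("ssii", 31))
        }

    def test_demo_chart_shared_row(self, demo2spec):
        chart = build_chart(generate_mopis(demo2spec), demo2spec, XYZ)
        assert len(chart.rows) == 5 and len(chart.columns) == 6
        i = next(i for i, r in enumerate(chart.rows) if str(r.cube) == "111")
        assert chart.row_marks(i) == {
            chart.columns.index(("f1", 7)), chart.columns.index(("f2", 7))
        }

    def test_single_column_chart(self):
        spec = spec_from_minterms(2, {"f": (3,)}, {"f": (0, 1, 2)})
        chart = build_chart(generate_mopis(spec), spec)
        assert len(chart.columns) == 1

    def test_every_row_and_column_marked(self, demo3spec):
        chart = build_chart(generate_mopis(demo3spec), demo3spec)
        assert all(chart.marks)
        for i in range(len(chart.rows)):
            assert chart.row_marks(i)


class TestEssentialRows:
    def test_single_output_essentials_of_injury_data(self, injuries_spec):
        for out, expected in (("mvta", "roca"), ("ssii", "mys")):
            j = injuries_spec.output_names.index(out)
            single = spec_from_minterms(
                5, {out: sorted(injuries_spec.on[j])}, {out: sorted(injuries_spec.dc(j))}
            )
            chart = build_chart(generate_mopis(single), single, INJ)
            ess = {ti.cube.to_expression(INJ) for ti in essential_rows(chart)}
            assert ess == {expected}

    def test_no_essentials_when_all_columns_doubly_marked(self, demo3spec):
        chart = build_chart(generate_mopis(demo3spec), demo3spec)
        doubly = all(len(c) >= 2 for c in chart.marks)
        if doubly:
            assert essential_rows(chart) == set()


class TestEnumerateSystems:
    def test_demo_two_systems(self, demo2spec):
        sol = solve(demo2spec)
        assert len(sol) == 2
        got = [
            {
                out: {c.to_expression(XYZ) for c in cubes}
                for out, cubes in s.models
            }
            for s in sol.systems
        ]
        assert {"f1": {"xyz", "x'z"}, "f2": {"xyz", "yz'"}} in got
        assert {"f1": {"yz", "x'z"}, "f2": {"xy", "yz'"}} in got

    def test_injury_four_systems_memberships(self, injuries_spec):
        chart = build_chart(generate_mopis(injuries_spec), injuries_spec, INJ)
        sol = enumerate_irredundant_systems(chart)
        selected = {
            frozenset(ti.cube.to_expression(INJ) for ti in s.selected)
            for s in sol.systems
        }
        assert selected == {
            frozenset({"roca", "mys"}),
            frozenset({"roca", "mys·roca", "roca'"}),
            frozenset({"mys'", "mys·roca", "mys"}),
            frozenset({"mys'", "mys·roca", "roca'"}),
        }

    def test_one_column_chart_yields_singletons(self):
        spec = spec_from_minterms(2, {"f": (3,)}, {"f": (1,)})
        chart = build_chart(generate_mopis(spec), spec)
        sol = enumerate_irredundant_systems(chart)
        assert all(len(s.selected) == 1 for s in sol.systems)
        assert len(sol) == len({m for m in chart.marks[0]})

    def test_matches_exhaustive_subset_oracle(self, demo2spec, demo3spec, injuries_spec):
        for spec in (demo2spec, demo3spec, injuries_spec):
            chart = build_chart(generate_mopis(spec), spec)
            got = {
                frozenset(chart.rows.index(ti) for ti in s.selected)
                for s in enumerate_irredundant_systems(chart).systems
            }
            assert got == exhaustive_minimal_covers(chart)


class TestWritingRule:
    def test_shared_mopi_retained_despite_absorption(self, injuries_spec):
        # mys·roca stays in mvta's sum although roca absorbs it there
        mopis = generate_mopis(injuries_spec)
        by_expr = {ti.cube.to_expression(INJ): ti for ti in mopis}
        selected = (by_expr["roca"], by_expr["mys·roca"], by_expr["roca'"])
        models = dict(write_models(selected, injuries_spec))
        assert [c.to_expression(INJ) for c in models["mvta"]] == ["roca", "mys·roca"]
        assert [c.to_expression(INJ) for c in models["ssii"]] == ["roca'", "mys·roca"]

    def test_single_output_rows_partition(self, demo2spec):
        mopis = generate_mopis(demo2spec)
        singles = tuple(ti for ti in mopis if len(ti.tag) == 1)
        models = dict(write_models(singles, demo2spec))
        written = [c for cubes in models.values() for c in cubes]
        assert sorted(map(str, written)) == sorted(str(ti.cube) for ti in singles)


class TestModelFit:
    def test_printed_fit_values(self):
        cases = datasets.injury_rates()
        cons, cov = model_fit([parse_cube("mys", INJ)], "ssii", cases)
        assert (cons, cov) == (0.75, 1.0)
        cons, cov = model_fit([parse_cube("roca", INJ)], "mvta", cases)
        assert (cons, cov) == (1.0, 1.0)

    def test_empty_model_is_undefined_consistency(self):
        cases = datasets.injury_rates()
        cons, cov = model_fit([], "mvta", cases)
        assert cons is None and cov == 0.0


class TestSolve:
    def test_multimorbidity_structure(self, patients):
        """One system; the diabetes model shares a two-literal complex
        cause with the depression model, which adds the bare marital and
        family-history literals."""
        sol = solve(patients, inc_threshold=1.0)
        assert len(sol) == 1
        (system,) = sol.systems
        a = system.model("a")
        e = system.model("e")
        assert len(a) == 2 and len(e) == 3
        shared = set(a) & set(e)
        assert set(a) <= set(e)  # every complex cause of diabetes recurs for depression
        assert sorted(c.n_literals for c in shared) == [1, 2]
        singles = {c.to_expression(patients.input_names) for c in e if c.n_literals == 1}
        assert singles == {"f", "m"}
        # the shared two-literal conjunction combines income and marital status
        two = next(c for c in shared if c.n_literals == 2)
        assert {s != "-" for s in two.states()}  # sanity
        lits = {
            patients.input_names[p]
            for p, s in enumerate(two.states())
            if s != "-"
        }
        assert lits == {"i", "m"}

    def test_demo3_five_systems_max_sharing(self, demo3spec):
        sol = solve(demo3spec)
        assert len(sol) == 5
        sharing = [
            len(set(s.model("f1")) & set(s.model("f2"))) for s in sol.systems
        ]
        assert max(sharing) == 3

    def test_single_output_equals_classic_irredundant_sums(self, rng):
        """With one output the systems are exactly the irredundant sums
        of classic single-function minimization."""
        for _ in range(10):
            spec = random_spec(rng, int(rng.integers(2, 5)), 1)
            chart = build_chart(generate_mopis(spec), spec)
            if len(chart.rows) > 15:
                continue
            got = {
                frozenset(s.selected_cubes())
                for s in enumerate_irredundant_systems(chart).systems
            }
            assert got == {
                frozenset(chart.rows[i].cube for i in cover)
                for cover in exhaustive_minimal_covers(chart)
            }

    def test_renaming_inputs_and_outputs_is_immaterial(self, injuries):
        from cora.cases import CaseTable

        perm_in = [2, 0, 4, 1, 3]
        perm_out = [1, 0]
        renamed = CaseTable(
            injuries.case_ids,
            tuple(injuries.input_names[i] for i in perm_in),
            tuple(injuries.output_names[j] for j in perm_out),
            injuries.inputs[:, perm_in],
            injuries.outputs[:, perm_out],
        )
        sol_a = solve(injuries, 0.6)
        sol_b = solve(renamed, 0.6)
        def literals(c, names):
            return frozenset(
                (names[p], s) for p, s in enumerate(c.states()) if s != "-"
            )

        def key(sol, names):
            return {
                frozenset(
                    (out, frozenset(literals(c, names) for c in cubes))
                    for out, cubes in s.models
                )
                for s in sol.systems
            }
        assert key(sol_a, injuries.input_names) == key(sol_b, renamed.input_names)


class TestSystemInvariants:
    @staticmethod
    @pytest.fixture(scope="class")
    def solved_fixtures():
        specs = [
            datasets.two_function_demo(),
            datasets.three_function_demo(),
            function_spec(assign_outputs(aggregate(datasets.injury_rates()), 0.6, 1)),
        ]
        return [(spec, solve(spec)) for spec in specs]

    def test_f_equivalence(self, solved_fixtures):
        for spec, sol in solved_fixtures:
            for s in sol.systems:
                assert f_equivalent(s, spec)

    def test_cover_irredundancy(self, solved_fixtures):
        for spec, sol in solved_fixtures:
            chart = build_chart(generate_mopis(spec), spec)
            for s in sol.systems:
                rows = {chart.rows.index(ti) for ti in s.selected}
                for r in rows:
                    reduced = rows - {r}
                    assert any(not (reduced & col) for col in chart.marks)

    def test_literal_irredundancy(self, solved_fixtures):
        """Cancelling any literal of any selected MOPI (in every model
        where it is written) breaks F-equivalence."""
        for spec, sol in solved_fixtures:
            for s in sol.systems:
                for ti in s.selected:
                    for exp in expansions(ti.cube):
                        mutated_models = {
                            out: [exp if c == ti.cube else c for c in cubes]
                            for out, cubes in s.models
                        }
                        broken = False
                        for j, out in enumerate(spec.output_names):
                            model = mutated_models[out]
                            if any(evaluate_model(model, m) != 1 for m in spec.on[j]) or any(
                                evaluate_model(model, m) != 0 for m in spec.off[j]
                            ):
                                broken = True
                        assert broken

    def test_no_selected_set_contains_another(self, solved_fixtures):
        for _, sol in solved_fixtures:
            sels = [set(s.selected) for s in sol.systems]
            for a, b in itertools.permutations(sels, 2):
                assert not a < b
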