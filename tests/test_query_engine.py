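import random

import pytest

from boolmerge.datamodel import Dataset
from boolmerge.query_engine import (
    And,
    DatasetRef,
    Not,
    Or,
    QueryError,
    evaluate,
    parse_query,
    switch_touch_point,
)

from oracle import brute_force_query, engine_groups_as_sets, random_instance

KNOWN = {"A", "B", "C", "E", "U"}


def simple(name, ids):
    return Dataset.from_records(name, [[i, ""] for i in ids], ["id", "v"])


A = DatasetRef("A")
B = DatasetRef("B")
C = DatasetRef("C")


class TestParsePrecedence:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("A - B + C", And(Not(A, B), C)),  # subtraction binds before AND
            ("A + B U C", Or(And(A, B), C)),  # AND binds before OR
            ("A - B - C", Not(Not(A, B), C)),  # same operator: left to right
            ("A + B + C", And(And(A, B), C)),
            ("A U B U C", Or(Or(A, B), C)),
            ("A + (B U C)", And(A, Or(B, C))),  # parentheses override
            ("(A U B) + C", And(Or(A, B), C)),
            ("A U B + C - B", Or(A, And(B, Not(C, B)))),
        ],
    )
    def test_ast_shape(self, text, expected):
        assert parse_query(text, KNOWN).root == expected

    def test_quoted_names_and_reserved_union_keyword(self):
        expr = parse_query('"U" U "my set"', {"U", "my set"})
        assert expr.root == Or(DatasetRef("U"), DatasetRef("my set"))

    def test_dataset_names_in_first_appearance_order(self):
        expr = parse_query("B + A U B", KNOWN)
        assert expr.dataset_names() == ["B", "A"]


class TestParseErrors:
    @pytest.mark.parametrize(
        "text, match",
        [
            ("A + (B U C", "unbalanced"),
            ("A ) B", "unbalanced"),
            ("A + + B", "dangling operator"),
            ("A +", "unexpected end"),
            ("+ A", "dangling operator"),
            ("A D", "unexpected token"),
            ("A + Z", "unknown dataset"),
            ("", "empty query"),
            ('A + "B', "unterminated"),
        ],
    )
    def test_rejected_with_position_info(self, text, match):
        with pytest.raises(QueryError, match=match):
            parse_query(text, KNOWN)

    def test_error_carries_position(self):
        with pytest.raises(QueryError) as exc:
            parse_query("A + Z", KNOWN)
        assert exc.value.position == 4


class TestEvaluatePlainStrings:
    @pytest.fixture
    def two(self):
        return {"A": simple("A", ["x", "y"]), "B": simple("B", ["y", "z"])}

    def test_intersection(self, two):
        res = evaluate("A + B", two)
        assert res.group_count == 1
        assert res.dataset.rows[0].values["id"] == "y"

    def test_union(self, two):
        assert evaluate("A U B", two).group_count == 3

    def test_subtraction(self, two):
        res = evaluate("A - B", two)
        assert [r.values["id"] for r in res.dataset.rows] == ["x"]

    def test_intersection_with_empty_dataset_is_empty_not_an_error(self, two):
        two["E"] = simple("E", [])
        res = evaluate("A + E", two)
        assert res.group_count == 0
        assert res.dataset.columns[:2] == ["id", "aliases"]

    def test_alias_off_reduction_matches_plain_set_algebra(
        self, variant_registry, variant_dataset, parent_dataset
    ):
        datasets = {"variants": variant_dataset, "parents": parent_dataset}
        res = evaluate(
            "variants + parents", datasets, registry=variant_registry,
            use_aliases=False,
        )
        assert res.group_count == 0  # no shared strings without aliasing


class TestEvaluateWithAliases:
    def test_family_merges_into_one_surviving_group(
        self, variant_registry, variant_dataset, parent_dataset
    ):
        datasets = {"variants": variant_dataset, "parents": parent_dataset}
        res = evaluate("variants + parents", datasets, registry=variant_registry)
        assert res.group_count == 1
        assert res.dataset.rows[0].values["aliases"] == (
            "CG6995;CG6995-PA;CG6995-PC;FPpp00084077;NP_001034066"
        )

    def test_oracle_equivalence_on_random_instances(self):
        rng = random.Random(42)
        from oracle import random_ast, referenced_datasets

        for _ in range(300):
            datasets, registry = random_instance(rng)
            ast = random_ast(rng, list(datasets))
            from boolmerge.query_engine import QueryExpression

            res = evaluate(
                QueryExpression(root=ast, source_text="<random>"),
                datasets,
                registry=registry,
            )
            universe = referenced_datasets(ast, datasets)
            assert engine_groups_as_sets(res.groups, universe) == brute_force_query(
                ast, datasets, registry
            )


class TestAlgebraicIdentities:
    """Identities over group-sets. Group identity is the member set, which
    depends on the consolidation universe (the datasets a query names), so
    each comparison phrases both sides over one universe: within {A, B},
    'A + (A U B)' denotes A's own group-set."""

    def test_identities_hold_on_seeded_fixtures(self):
        rng = random.Random(99)
        for _ in range(50):
            datasets, registry = random_instance(rng, max_datasets=3)
            names = list(datasets)
            a, b = names[0], names[1]
            sub = {a: datasets[a], b: datasets[b]}

            def gs(q):
                res = evaluate(q, sub, registry=registry)
                return engine_groups_as_sets(res.groups, sub)

            a_in_ab = gs(f"{a} + ({a} U {b})")
            b_in_ab = gs(f"{b} + ({b} U {a})")
            assert gs(f"{a} + {a}") == gs(a)
            assert gs(f"{a} U {a}") == gs(a)
            assert gs(f"{a} - {a}") == set()
            assert gs(f"{a} + {b}") == gs(f"{b} + {a}")
            assert gs(f"{a} U {b}") == gs(f"{b} U {a}")
            assert not gs(f"{a} - {b}") & b_in_ab
            assert gs(f"{a} + {b}") <= a_in_ab
            assert gs(f"{a} U {b}") >= a_in_ab | b_in_ab


class TestAssembleOutput:
    def test_prefixed_columns_and_aggregation(self):
        a = Dataset.from_records("A", [["g1", "a"], ["g1", "b"]], ["id", "val"])
        b = Dataset.from_records("B", [["g1", "zz"]], ["id", "note"])
        res = evaluate("A + B", {"A": a, "B": b})
        assert res.dataset.columns == ["id", "aliases", "A.val", "B.note"]
        row = res.dataset.rows[0].values
        assert row["A.val"] == "a; b"
        assert row["B.note"] == "zz"

    def test_union_leaves_absent_source_cells_empty(self):
        a = Dataset.from_records("A", [["g1", "a"]], ["id", "val"])
        b = Dataset.from_records("B", [["g2", "zz"]], ["id", "note"])
        res = evaluate("A U B", {"A": a, "B": b})
        by_id = {r.values["id"]: r.values for r in res.dataset.rows}
        assert by_id["g1"]["B.note"] == ""
        assert by_id["g2"]["A.val"] == ""

    def test_output_row_order_is_group_first_appearance(self):
        a = Dataset.from_records("A", [["g2", ""], ["g1", ""]], ["id", "v"])
        b = Dataset.from_records("B", [["g1", ""], ["g3", ""]], ["id", "v"])
        res = evaluate("A U B", {"A": a, "B": b})
        assert [r.values["id"] for r in res.dataset.rows] == ["g2", "g1", "g3"]


class TestSwitchTouchPoint:
    @pytest.fixture
    def drug_table(self):
        return Dataset.from_records(
            "drugs",
            [["aspirin", "PTGS1"], ["imatinib", "ABL1"], ["orphan", ""]],
            ["drug", "target"],
        )

    def test_switch_to_current_column_is_identity(self, drug_table):
        res = switch_touch_point(drug_table, "drug")
        assert res.n_dropped == 0
        assert res.dataset.identifiers() == drug_table.identifiers()

    def test_rekey_drug_table_on_target(self, drug_table):
        res = switch_touch_point(drug_table, "target")
        assert res.dataset.id_column == "target"
        assert res.dataset.identifiers() == ["PTGS1", "ABL1"]
        assert res.n_dropped == 1

    def test_empty_cells_dropped_and_counted(self):
        ds = Dataset.from_records(
            "d", [["a", "t1"], ["b", ""], ["c", ""]], ["x", "y"]
        )
        res = switch_touch_point(ds, "y")
        assert res.n_dropped == 2
        assert len(res.dataset) == 1

    def test_unknown_column_rejected(self, drug_table):
        with pytest.raises(QueryError, match="unknown column"):
            switch_touch_point(drug_table, "nope")

    def test_keep_empty_raises_on_empty_cell(self, drug_table):
        with pytest.raises(QueryError):
            switch_touch_point(drug_table, "target", drop_empty=False)
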