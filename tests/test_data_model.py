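"""Domain types, CSV round-trips and validation."""

import datetime

import pandas as pd
import pytest

from microprospect.data_model import (
    AssociationRule,
    ContextSpec,
    IntegrityError,
    Item,
    MiningError,
    Record,
    SchemaError,
    Thresholds,
    TransactionDatabase,
    itemset_tokens,
    load_database,
    parse_itemset,
    parse_predicate,
    read_rules,
    validate_database,
    write_database,
    write_rules,
)
from microprospect.synthetic_data import DEFAULT_CONTEXT_SPECS, GeneratorConfig, generate

from conftest import item, make_worked_rule, RULE1_PREDICATES


class TestItem:
    def test_identity_is_the_full_triple(self):
        assert Item("Apd", "X1", ">=") == Item("Apd", "X1", ">=")
        assert Item("Apd", "X1", ">=") != Item("Apd", "X1", "<=")
        assert Item("Apd", "X1", ">=") != Item("Apd", "X2", ">=")

    def test_token_round_trip(self):
        it = Item("Pheh", "X2", "<=")
        assert Item.from_token(it.token()) == it

    def test_unknown_relation_rejected(self):
        with pytest.raises(ValueError):
            Item("Apd", "X1", "~")

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("is_a (Apd, >=X1)", Item("Apd", "X1", ">=")),
            ("is_a (Pheh, <=X2)", Item("Pheh", "X2", "<=")),
            ("diff_of (Aio.Rps, >X3)", Item("diff_of(Aio.Rps)", "X3", ">")),
            ("color_of (soil, Y1)", Item("color_of(soil)", "Y1", "==")),
            ("close_to (Prospect, rock)", Item("close_to(Prospect)", "rock", "==")),
            ("found (MP, true)", Item("MP", "true", "==")),
        ],
    )
    def test_parse_predicate(self, text, expected):
        assert parse_predicate(text) == expected

    def test_itemset_serialization_is_canonical(self):
        items = [Item("B", "1"), Item("A", "1"), Item("C", "1")]
        assert itemset_tokens(items) == itemset_tokens(reversed(items))
        assert parse_itemset(itemset_tokens(items)) == frozenset(items)


class TestTypes:
    def test_context_spec_ordering_enforced(self):
        with pytest.raises(ValueError):
            ContextSpec("rainfall", 300, 100)

    def test_thresholds_validation(self):
        with pytest.raises(ValueError):
            Thresholds(ms=0, mc=0.5, mi=0.0)
        with pytest.raises(ValueError):
            Thresholds(ms=0.5, mc=1.5, mi=0.0)
        assert Thresholds(ms=3, mc=0.5, mi=0.0).ms_fraction(10) == pytest.approx(0.3)
        assert Thresholds(ms=0.3, mc=0.5, mi=0.0).ms_fraction(10) == pytest.approx(0.3)

    def test_rule_disjointness_enforced(self):
        with pytest.raises(MiningError):
            AssociationRule(
                antecedent=frozenset({item("A")}),
                consequent=frozenset({item("A")}),
                antecedent_negated=False,
                consequent_negated=False,
                support=0.5,
                confidence=0.5,
                interest=0.0,
                interval=1,
            )


def small_db():
    specs = list(DEFAULT_CONTEXT_SPECS)
    recs = [
        Record(
            prospect_id=f"P{i}",
            site="s1",
            interval=i,
            date_of_evaluation=datetime.date(2015, 1, i),
            raw_values={"Nmob": 340.0},
            context_values={s.name: (s.civ + s.cfv) / 2 for s in specs},
            prospect=True,
        )
        for i in (1, 2)
    ]
    return TransactionDatabase(recs, specs, ["Nmob", "Apd"])


class TestDatabaseIO:
    def test_load_two_row_csv(self, tmp_path):
        db = small_db()
        path = tmp_path / "db.csv"
        write_database(db, path)
        loaded = load_database(path, ["Nmob", "Apd"], db.context_specs)
        assert len(loaded.records) == 2
        assert loaded.intervals == [1, 2]

    def test_missing_context_column_is_schema_error(self, tmp_path):
        db = small_db()
        path = tmp_path / "db.csv"
        write_database(db, path)
        df = pd.read_csv(path).drop(columns=["rainfall"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="rainfall"):
            load_database(path, ["Nmob", "Apd"], db.context_specs)

    def test_duplicate_site_interval_is_integrity_error(self, tmp_path):
        db = small_db()
        db.records[1].date_of_evaluation = db.records[0].date_of_evaluation
        path = tmp_path / "db.csv"
        write_database(db, path)
        with pytest.raises(IntegrityError):
            load_database(path, ["Nmob", "Apd"], db.context_specs)

    def test_non_numeric_context_names_row(self, tmp_path):
        db = small_db()
        path = tmp_path / "db.csv"
        write_database(db, path)
        df = pd.read_csv(path)
        df["rainfall"] = df["rainfall"].astype(object)
        df.loc[1, "rainfall"] = "soggy"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="row 3"):
            load_database(path, ["Nmob", "Apd"], db.context_specs)

    def test_synthetic_fixture_round_trips(self, tmp_path):
        config = GeneratorConfig(n_sites=6, n_intervals=4, seed=7)
        db = generate(config)
        path = tmp_path / "db.csv"
        write_database(db, path)
        loaded = load_database(path, db.indicator_columns, db.context_specs)
        assert len(loaded.records) == len(db.records)
        for a, b in zip(loaded.records, sorted(db.records, key=lambda r: (r.site, r.interval, r.prospect_id))):
            assert (a.site, a.interval, a.prospect) == (b.site, b.interval, b.prospect)
            assert a.raw_values == pytest.approx(b.raw_values)
            assert a.context_values == pytest.approx(b.context_values)

    def test_row_order_independence(self, tmp_path):
        config = GeneratorConfig(n_sites=4, n_intervals=3, seed=3)
        db = generate(config)
        path1, path2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_database(db, path1)
        pd.read_csv(path1).sample(frac=1, random_state=0).to_csv(path2, index=False)
        d1 = load_database(path1, db.indicator_columns, db.context_specs)
        d2 = load_database(path2, db.indicator_columns, db.context_specs)
        assert [r.prospect_id for r in d1.records] == [r.prospect_id for r in d2.records]
        assert [r.interval for r in d1.records] == [r.interval for r in d2.records]


class TestValidation:
    def test_well_formed_db_has_empty_report(self):
        assert validate_database(small_db()) == []

    def test_duplicate_site_interval_reported(self):
        db = small_db()
        db.records[1].interval = 1
        assert any("duplicate" in f for f in validate_database(db))

    def test_unknown_context_variable_reported(self):
        db = small_db()
        db.records[0].context_values["barometric"] = 7.0
        assert any("barometric" in f for f in validate_database(db))


class TestRuleSerialization:
    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "rules.csv"
        write_rules([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert read_rules(path) == []

    def test_shared_antecedent_rows_adjacent(self, tmp_path):
        ant = frozenset({item("A"), item("B")})
        rules = [
            AssociationRule(ant, frozenset({item("C")}), False, False, 0.4, 0.8, 0.1, 1),
            AssociationRule(frozenset({item("D")}), frozenset({item("E")}), False, False, 0.45, 0.9, 0.1, 1),
            AssociationRule(ant, frozenset({item("E")}), False, False, 0.3, 0.6, 0.1, 1),
        ]
        path = tmp_path / "rules.csv"
        write_rules(rules, path)
        ants = pd.read_csv(path)["antecedent"].tolist()
        first, last = ants.index(itemset_tokens(ant)), len(ants) - 1 - ants[::-1].index(itemset_tokens(ant))
        assert last - first == 1  # both rows of the shared antecedent adjacent

    def test_round_trip_is_exact(self, tmp_path):
        rules = [
            make_worked_rule(RULE1_PREDICATES, 8, 1),
            AssociationRule(
                frozenset({item("A")}), frozenset({item("B")}),
                True, False, 1 / 3, 2 / 7, 0.123456789012345, 2,
                supp_antecedent=2 / 3, supp_consequent=1 / 7, context_adjusted=True,
            ),
        ]
        path = tmp_path / "rules.csv"
        write_rules(rules, path)
        got = read_rules(path)
        assert sorted(got, key=str) == sorted(rules, key=str)

    def test_oversized_consequent_rejected(self, tmp_path):
        rule = AssociationRule(
            frozenset({item("A")}),
            frozenset(item(c) for c in "BCDEFGHI"),  # 8 consequent items
            False, False, 0.5, 0.5, 0.1, 1,
        )
        with pytest.raises(ValueError, match="7"):
            write_rules([rule], tmp_path / "rules.csv")
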