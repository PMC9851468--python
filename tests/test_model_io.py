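"""Domain-type invariants and file round-trips."""

import math

import pytest

from fcdbaudit.errors import IntegrityError, ParseError, UnitError
from fcdbaudit.io import (
    PanelDialect,
    harmonize_component,
    load_synonyms,
    read_corpus,
    read_panel,
    write_corpus,
    write_panel,
)
from fcdbaudit.model import (
    ComponentValue,
    Document,
    FCDBPanel,
    UnitSpec,
    ValueStatus,
    fatty_acid_class,
)
from fcdbaudit.synth import PanelConfig, generate_panel


class TestComponentValue:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(status=ValueStatus.QUANTIFIED, quantity=None),
            dict(status=ValueStatus.QUANTIFIED, quantity=-1.0),
            dict(status=ValueStatus.ZERO_REPORTED, quantity=3.0),
            dict(status=ValueStatus.NOT_REPORTED, quantity=5.0),
            dict(status=ValueStatus.QUANTIFIED, quantity=1.0, year=1850),
            dict(status=ValueStatus.QUANTIFIED, quantity=1.0, year=2150),
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(IntegrityError):
            ComponentValue("f", "d", "SFA", **kwargs)

    def test_zero_reported_normalizes_quantity(self):
        rec = ComponentValue("f", "d", "SFA", ValueStatus.ZERO_REPORTED)
        assert rec.quantity == 0.0
        assert rec.is_reported and not rec.is_nonzero

    def test_duplicate_triple_rejected_by_panel(self):
        a = ComponentValue("oilA", "db1", "FA16:0", ValueStatus.QUANTIFIED, 43.5)
        b = ComponentValue("oilA", "db1", "FA16:0", ValueStatus.QUANTIFIED, 43.6)
        with pytest.raises(IntegrityError, match="duplicate"):
            FCDBPanel([a, b])

    @pytest.mark.parametrize(
        "comp,expected",
        [
            ("FA16:0", "SFA"),
            ("FA18:1", "MUFA"),
            ("FA18:2", "PUFA"),
            ("FA18:3", "PUFA"),
            ("FA18:1t", "TFA"),
            ("SFA", None),
            ("vitamin_e", None),
        ],
    )
    def test_fatty_acid_classification(self, comp, expected):
        assert fatty_acid_class(comp) == expected


class TestPanelIO:
    def test_units_converted_and_statuses_read(self, tmp_path):
        f = tmp_path / "panel.csv"
        f.write_text(
            "food_id,db_id,component_id,quantity,unit,status,year,source_kind,source_ref\n"
            "oilA,db1,vitamin_e,25.63,mg/100g,quantified,2004,literature,Souci 2004\n"
            "oilA,db1,FA18:3,0,g/100g,zero_reported,1979,compiled,\n"
            "oilA,db1,vitamin_k1,,g/100g,not_reported,,,\n"
        )
        panel = read_panel(f)
        assert len(panel) == 3
        rec = panel.get("oilA", "db1", "vitamin_e")
        assert rec.quantity == 25.63 * 1e-3  # mg -> g, exact float product
        assert panel.get("oilA", "db1", "FA18:3").status is ValueStatus.ZERO_REPORTED
        assert panel.get("oilA", "db1", "vitamin_k1").quantity is None

    def test_duplicate_rows_rejected(self, tmp_path):
        f = tmp_path / "dup.csv"
        f.write_text(
            "food_id,db_id,component_id,quantity,unit,status\n"
            "oilA,db1,FA16:0,43.5,g/100g,quantified\n"
            "oilA,db1,FA16:0,43.6,g/100g,quantified\n"
        )
        with pytest.raises(IntegrityError):
            read_panel(f)

    def test_unknown_unit_and_malformed_row(self, tmp_path):
        f = tmp_path / "bad_unit.csv"
        f.write_text(
            "food_id,db_id,component_id,quantity,unit,status\n"
            "oilA,db1,FA16:0,43.5,stone/100g,quantified\n"
        )
        with pytest.raises(UnitError, match="line 2"):
            read_panel(f)
        g = tmp_path / "bad_row.csv"
        g.write_text(
            "food_id,db_id,component_id,quantity,unit,status\n"
            "oilA,db1,FA16:0,notanumber,g/100g,quantified\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            read_panel(g)

    @pytest.mark.parametrize("zeros_are,expected", [
        ("zero_reported", ValueStatus.ZERO_REPORTED),
        ("not_reported", ValueStatus.NOT_REPORTED),
    ])
    def test_legacy_numeric_dialect(self, tmp_path, zeros_are, expected):
        # no status column: semantics of a literal 0 come from the dialect
        f = tmp_path / "legacy.tsv"
        f.write_text(
            "food_id\tdb_id\tcomponent_id\tquantity\tunit\n"
            "oilA\tdb1\tFA16:0\t43.5\tg/100g\n"
            "oilA\tdb1\tFA18:3\t0\tg/100g\n"
            "oilA\tdb1\tvitamin_k1\t\tg/100g\n"
        )
        panel = read_panel(f, PanelDialect(zeros_are=zeros_are))
        assert panel.get("oilA", "db1", "FA16:0").status is ValueStatus.QUANTIFIED
        assert panel.get("oilA", "db1", "FA18:3").status is expected
        assert panel.get("oilA", "db1", "vitamin_k1").status is ValueStatus.NOT_REPORTED

    def test_round_trip_identity_on_generated_panel(self, tmp_path):
        panel, _ = generate_panel(PanelConfig(n_foods=3, n_dbs=2, n_components=12, seed=7))
        path = tmp_path / "panel.tsv"
        write_panel(panel, path)
        reread = read_panel(path)
        assert reread == FCDBPanel(panel.records)  # index sets recomputed on load


class TestCorpusIO:
    def test_references_kept_and_self_citation_dropped(self, tmp_path, caplog):
        f = tmp_path / "corpus.jsonl"
        f.write_text(
            '{"doc_id": "A", "title": "Palm oil", "references": ["B", "Z"]}\n'
            '{"doc_id": "B", "title": "Oil palm", "references": ["B"]}\n'
        )
        with caplog.at_level("WARNING"):
            docs = read_corpus(f)
        assert [d.doc_id for d in docs] == ["A", "B"]
        assert docs[0].references == ("B", "Z")  # dangling ref kept
        assert docs[1].references == ()
        assert any("cites itself" in r.message for r in caplog.records)

    def test_duplicate_and_missing_doc_id(self, tmp_path):
        f = tmp_path / "dup.jsonl"
        f.write_text('{"doc_id": "A", "title": "x"}\n{"doc_id": "A", "title": "y"}\n')
        with pytest.raises(IntegrityError):
            read_corpus(f)
        g = tmp_path / "anon.jsonl"
        g.write_text('{"title": "no id"}\n')
        with pytest.raises(ParseError):
            read_corpus(g)

    def test_round_trip_identity(self, tmp_path):
        docs = [
            Document("A", "Palm oil", "Composition study", 2001, ("B",)),
            Document("B", "Elaeis guineensis", "", None, ()),
        ]
        path = tmp_path / "corpus.jsonl"
        write_corpus(docs, path)
        assert read_corpus(path) == docs


class TestHarmonize:
    def test_synonym_lookups(self):
        table = load_synonyms()
        assert harmonize_component("Fatty acids, total monounsaturated", table) == "MUFA"
        assert harmonize_component("palmitic acid", table) == "FA16:0"

    def test_passthrough_is_namespaced_and_logged(self, caplog):
        with caplog.at_level("INFO"):
            out = harmonize_component("vitamin K1 (unmapped)", {})
        assert out == "raw:vitamin K1 (unmapped)"
        assert any("unmapped" in r.message for r in caplog.records)

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            harmonize_component("   ", {})


def test_unit_spec_rejects_unknown_factor():
    with pytest.raises(IntegrityError):
        UnitSpec("kg/100g", 1e3)
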