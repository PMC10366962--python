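"""Knowledge-base model, serialisation dialects, mapping and SPARQL."""

import pytest

from medscreen import (
    AlertTemplate,
    ConceptRef,
    KnowledgeBase,
    TriggerEntry,
    load_kb,
    map_local,
    query_kb,
    save_kb,
)
from medscreen.errors import (
    KBFormatError,
    KBIntegrityError,
    QuerySyntaxError,
    UnmappedConceptError,
)

PREFIX = "PREFIX ms: <https://medscreen.example/kb#> PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#> "


@pytest.mark.parametrize("dialect,name", [("json", "kb.json"), ("turtle", "kb.ttl"),
                                          ("csv-dir", "kbdir")])
def test_save_load_round_trip(kb, tmp_path, dialect, name):
    """Every dialect reproduces the KB structurally on reload."""
    target = tmp_path / name
    save_kb(kb, target, dialect)
    reloaded = load_kb(target, dialect)
    assert reloaded.canonical() == kb.canonical()


@pytest.mark.parametrize("dialect,name", [("json", "kb.json"), ("csv-dir", "kbdir")])
def test_empty_kb_round_trips(tmp_path, dialect, name):
    empty = KnowledgeBase()
    save_kb(empty, tmp_path / name, dialect)
    assert load_kb(tmp_path / name, dialect).canonical() == empty.canonical()


def test_demo_kb_has_entries_in_every_collection(kb):
    for coll in (kb.form_route_weights, kb.frequency_weights,
                 kb.product_instruction_weights, kb.dbi_entries,
                 kb.trigger_entries, kb.alert_templates,
                 kb.concept_maps, kb.unit_conversions):
        assert len(coll) >= 1


def test_dangling_template_reference_is_an_integrity_error(kb, tmp_path):
    broken = kb.model_copy(deep=True)
    broken.trigger_entries.append(TriggerEntry(
        ingredient=ConceptRef(id="demo:ing/x", label="X"),
        lab_test=ConceptRef(id="demo:lab/x", label="X lab"),
        lab_unit="mg/dL", low=0, high=1,
        alert_template_id="tpl-nonexistent"))
    with pytest.raises(KBIntegrityError, match="tpl-nonexistent"):
        broken.validate_integrity()
    # the error also fires at load time
    save_kb(broken, tmp_path / "kb.json", "json")
    with pytest.raises(KBIntegrityError):
        load_kb(tmp_path / "kb.json", "json")


def test_duplicate_form_route_weight_rejected(kb):
    broken = kb.model_copy(deep=True)
    broken.form_route_weights.append(broken.form_route_weights[0].model_copy())
    with pytest.raises(KBIntegrityError, match="more than one entry"):
        broken.validate_integrity()


def test_conflicting_concept_labels_rejected(kb):
    broken = kb.model_copy(deep=True)
    dup = broken.dbi_entries[0].model_copy(deep=True, update={
        "ingredient": ConceptRef(id=broken.dbi_entries[0].ingredient.id, label="Other name")})
    broken.dbi_entries.append(dup)
    with pytest.raises(KBIntegrityError, match="conflicting labels"):
        broken.validate_integrity()


def test_parse_failure_names_file_and_line(tmp_path):
    bad = tmp_path / "kb.json"
    bad.write_text('{"version": "x",\n  broken')
    with pytest.raises(KBFormatError) as exc:
        load_kb(bad, "json")
    assert "kb.json" in str(exc.value)
    assert exc.value.line is not None


def test_missing_path_is_a_format_error(tmp_path):
    with pytest.raises(KBFormatError):
        load_kb(tmp_path / "nope.json", "json")


def test_csv_dir_missing_column_reports_file(kb, tmp_path):
    save_kb(kb, tmp_path / "kbdir", "csv-dir")
    f = tmp_path / "kbdir" / "dbi_entries.csv"
    lines = f.read_text().splitlines()
    lines[0] = lines[0].replace("min_effective_daily_dose", "wrong_name")
    f.write_text("\n".join(lines) + "\n")
    with pytest.raises(KBFormatError, match="dbi_entries.csv"):
        load_kb(tmp_path / "kbdir", "csv-dir")


def test_map_local_resolves_and_misses(kb):
    ref = map_local(kb, "LOC-TAB-ORAL", "demo")
    assert ref.id == "form:oral-tablet"
    with pytest.raises(UnmappedConceptError) as exc:
        map_local(kb, "LOC-UNKNOWN", "demo")
    assert exc.value.local_code == "LOC-UNKNOWN"


def test_map_local_keys_on_code_and_vocabulary(kb):
    """The same code may map differently per source vocabulary."""
    from medscreen import LocalConceptMap
    from medscreen.demo import ONCE_DAILY, ORAL_TABLET

    kb2 = kb.model_copy(deep=True)
    kb2.concept_maps += [
        LocalConceptMap(local_code="X1", local_vocabulary="voc-a", canonical=ORAL_TABLET),
        LocalConceptMap(local_code="X1", local_vocabulary="voc-b", canonical=ONCE_DAILY),
    ]
    kb2.validate_integrity()
    assert map_local(kb2, "X1", "voc-a").id == "form:oral-tablet"
    assert map_local(kb2, "X1", "voc-b").id == "freq:once-daily"


def test_sparql_dbi_ingredients_include_alprazolam(kb):
    rows = query_kb(kb, PREFIX + """
        SELECT ?label WHERE {
          ?e a ms:DBIEntry ; ms:ingredient ?i . ?i rdfs:label ?label .
        }""")
    assert "Alprazolam" in {r["label"] for r in rows}


def test_sparql_empty_graph_zero_rows():
    rows = query_kb(KnowledgeBase(), PREFIX + "SELECT ?s WHERE { ?s a ms:DBIEntry }")
    assert rows == []


def test_sparql_counts_match_typed_collections(kb):
    """Cross-representation consistency between graph and typed model."""
    for cls, coll in [("DBIEntry", kb.dbi_entries),
                      ("TriggerEntry", kb.trigger_entries),
                      ("FormRouteWeight", kb.form_route_weights),
                      ("AlertTemplate", kb.alert_templates)]:
        rows = query_kb(kb, PREFIX + f"SELECT (COUNT(?s) AS ?n) WHERE {{ ?s a ms:{cls} }}")
        assert rows[0]["n"] == len(coll), cls


def test_malformed_sparql_raises_query_error(kb):
    with pytest.raises(QuerySyntaxError):
        query_kb(kb, "SELECT WHERE { this is not sparql")


def test_conversion_factor_identity_and_table(kb):
    assert kb.conversion_factor("mg", "mg") == 1.0
    assert kb.conversion_factor("MG ", "mg") == 1.0  # normalized
    assert kb.conversion_factor("mcg", "mg") == 0.001
    assert kb.conversion_factor("µg", "mg") == 0.001  # µg spelling
    assert kb.conversion_factor("mL", "mg") is None


def test_template_lookup(kb):
    assert kb.template("tpl-mrci-high").intervention == "global_drug"
    assert kb.template("missing") is None
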