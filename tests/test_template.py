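"""Template document: serialization, validation, and object management."""
import json

import pytest

from glyphstack.errors import GlyphstackError, TemplateValidationError
from glyphstack.template import (bundled_templates, delete_object, duplicate_object,
                                 load_template, remap_variables, save_template,
                                 set_layer_order, set_visibility, template_to_dict,
                                 validate_document)


@pytest.fixture
def wound_doc(templates):
    return json.loads(save_template(templates["wound"]))


class TestRoundTrip:
    @pytest.mark.parametrize("name", ["wound", "multiplexed-cell"])
    def test_save_load_is_canonical_identity(self, templates, name):
        doc = save_template(templates[name])
        assert save_template(load_template(doc)) == doc

    def test_loaded_template_equals_original(self, templates):
        t = templates["wound"]
        t2 = load_template(save_template(t))
        assert t2.name == t.name
        assert [o.id for o in t2.objects] == [o.id for o in t.objects]
        assert t2.objects[0].bindings == t.objects[0].bindings


# each mutation violates exactly one schema rule; the error must name the field
MUTATIONS = [
    ("missing format_version", lambda d: d.pop("format_version"), "format_version"),
    ("numeric name", lambda d: d.update(name=7), "name"),
    ("non-integer seed", lambda d: d.update(seed="x"), "seed"),
    ("empty objects", lambda d: d.update(objects=[]), "objects"),
    ("missing object id", lambda d: d["objects"][0].pop("id"), "objects[0].id"),
    ("duplicate ids", lambda d: d["objects"][1].update(id=d["objects"][0]["id"]),
     "duplicate object id"),
    ("unknown shape kind", lambda d: d["objects"][0]["shape"].update(kind="hexagram"),
     "shape.kind"),
    ("non-positive dimension", lambda d: d["objects"][0]["shape"].update(side=-5),
     "shape.side"),
    ("too few custom vertices",
     lambda d: d["objects"][0].update(shape={"kind": "custom", "vertices": [[0, 0], [1, 1]]}),
     "vertices"),
    ("zero scale", lambda d: d["objects"][0]["transform"].update(scale=[0, 1]),
     "transform.scale"),
    ("bad translation", lambda d: d["objects"][0]["transform"].update(translation=[1]),
     "translation"),
    ("non-integer z_order", lambda d: d["objects"][0].update(z_order=1.5), "z_order"),
    ("non-boolean visible", lambda d: d["objects"][0].update(visible="yes"), "visible"),
    ("bad fill colour", lambda d: d["objects"][0]["style"].update(fill="red"), "style.fill"),
    ("negative stroke width", lambda d: d["objects"][0]["style"].update(stroke_width=-1),
     "stroke_width"),
    ("unknown element",
     lambda d: d["objects"][0]["bindings"][0].update(element="sparkles"), "sparkles"),
    ("element bound twice",
     lambda d: d["objects"][0]["bindings"].append(dict(d["objects"][0]["bindings"][0])),
     "bound more than once"),
    ("empty variable", lambda d: d["objects"][0]["bindings"][0].update(variable=""),
     "variable"),
    ("unknown symbol",
     lambda d: d["objects"][0]["bindings"][0]["static"].update(symbol="heart"), "symbol"),
    ("unknown mesh orientation",
     lambda d: d["objects"][0]["bindings"][1]["static"].update(mesh_orientation="spiral"),
     "mesh_orientation"),
    ("unknown palette",
     lambda d: d["objects"][0]["bindings"][0].update(element="fill_gradient")
     or d["objects"][0]["bindings"][0]["static"].update(colour_map="Rainbow"), "colour_map"),
    ("zero density", lambda d: d["objects"][0]["bindings"][1]["static"].update(density_max=0),
     "density_max"),
    ("bad layout mode", lambda d: d["layout"].update(mode="spiral"), "layout.mode"),
    ("zero page size", lambda d: d["layout"].update(page_size=0), "page_size"),
    ("negative canvas", lambda d: d["layout"].update(canvas=[-10, 100]), "canvas"),
    ("positional without axes",
     lambda d: d["layout"].update(mode="positional", x_variable=None, y_variable=None),
     "x_variable"),
    ("overlapping linked groups",
     lambda d: d["normalization"].update(linked_groups=[["a", "b"], ["b", "c"]]),
     "another group"),
    ("bad normalization mode", lambda d: d["normalization"].update(mode="zscore"),
     "normalization.mode"),
]


class TestValidation:
    @pytest.mark.parametrize("label,mutate,needle", MUTATIONS, ids=[m[0] for m in MUTATIONS])
    def test_mutated_document_rejected_with_field_path(self, wound_doc, label, mutate, needle):
        mutate(wound_doc)
        errs = validate_document(wound_doc)
        assert errs, f"mutation '{label}' slipped through validation"
        assert any(needle in e for e in errs)

    def test_bundled_documents_validate_clean(self, templates):
        for t in templates.values():
            assert validate_document(template_to_dict(t)) == []

    def test_all_failures_reported_not_just_first(self, wound_doc):
        wound_doc.pop("format_version")
        wound_doc["objects"][0]["shape"]["kind"] = "hexagram"
        wound_doc["layout"]["page_size"] = 0
        with pytest.raises(TemplateValidationError) as exc:
            load_template(json.dumps(wound_doc))
        assert len(exc.value.errors) >= 3

    def test_malformed_json(self):
        with pytest.raises(TemplateValidationError, match="JSON"):
            load_template("{not json")

    def test_empty_document_lists_missing_fields(self):
        errs = validate_document({})
        assert any("format_version" in e for e in errs)
        assert any("objects" in e for e in errs)


class TestRemap:
    def test_remap_updates_only_the_target(self, templates):
        t = remap_variables(templates["wound"], {"wound_area_change": "delta_area"},
                            columns=["delta_area", "cell_number", "cell_area"])
        assert "delta_area" in t.bound_variables()
        assert "wound_area_change" not in t.bound_variables()
        assert "cell_number" in t.bound_variables()

    def test_identity_mapping_is_noop(self, templates):
        t = templates["wound"]
        t2 = remap_variables(t, {}, columns=t.bound_variables())
        assert save_template(t2) == save_template(t)

    def test_missing_target_column_is_named(self, templates):
        with pytest.raises(GlyphstackError, match="foo"):
            remap_variables(templates["wound"], {"cell_number": "foo"},
                            columns=["wound_area_change", "cell_area"])


class TestObjectManagement:
    def test_duplicate_copies_bindings_under_fresh_id(self, templates):
        t = templates["multiplexed-cell"]
        t2 = duplicate_object(t, "nucleus")
        assert len(t2.objects) == len(t.objects) + 1
        copy = t2.object_by_id("nucleus-copy")
        assert copy.bindings == t.object_by_id("nucleus").bindings
        assert copy.z_order == max(o.z_order for o in t2.objects)

    def test_duplicate_twice_gets_numbered_id(self, templates):
        t = duplicate_object(duplicate_object(templates["wound"], "well"), "well")
        ids = {o.id for o in t.objects}
        assert {"well", "well-copy", "well-copy2"} <= ids

    def test_duplicating_hidden_object_stays_hidden(self, templates):
        t = set_visibility(templates["wound"], "wound", False)
        t = duplicate_object(t, "wound")
        assert not t.object_by_id("wound-copy").visible

    def test_duplicate_then_delete_restores_template(self, templates):
        t = templates["wound"]
        t2 = delete_object(duplicate_object(t, "well"), "well-copy")
        assert save_template(t2) == save_template(t)

    def test_unknown_id_errors(self, templates):
        for op in (lambda t: duplicate_object(t, "ghost"),
                   lambda t: set_visibility(t, "ghost", False),
                   lambda t: set_layer_order(t, "ghost", "up")):
            with pytest.raises(GlyphstackError, match="ghost"):
                op(templates["wound"])

    def test_move_top_object_up_is_noop(self, templates):
        t = templates["wound"]
        top = t.objects_in_z_order()[-1].id
        assert save_template(set_layer_order(t, top, "up")) == save_template(t)

    def test_move_swaps_neighbours(self, templates):
        t = templates["multiplexed-cell"]
        before = [o.id for o in t.objects_in_z_order()]
        t2 = set_layer_order(t, "nucleus", "down")
        after = [o.id for o in t2.objects_in_z_order()]
        i = before.index("nucleus")
        assert after[i] == before[i - 1] and after[i - 1] == "nucleus"

    def test_hide_then_show_is_involution(self, templates):
        t = templates["wound"]
        t2 = set_visibility(set_visibility(t, "well", False), "well", True)
        assert save_template(t2) == save_template(t)

    def test_z_order_stays_a_permutation(self, templates):
        import random
        rng = random.Random(0)
        t = templates["multiplexed-cell"]
        ids = [o.id for o in t.objects]
        for _ in range(30):
            t = set_layer_order(t, rng.choice(ids), rng.choice(["up", "down"]))
        assert sorted(o.z_order for o in t.objects) == list(range(len(ids)))


class TestBundledDesigns:
    def test_wound_template_binds_the_three_measurements(self, templates):
        t = templates["wound"]
        assert len(t.objects) == 2
        by_el = {(o.id, b.element): b.variable for o in t.objects for b in o.bindings}
        assert by_el[("well", "fill_gradient")] == "cell_area"
        assert by_el[("well", "mesh")] == "cell_number"
        assert by_el[("wound", "length")] == "wound_area_change"

    def test_multiplexed_template_binds_ten_variables(self, templates):
        t = templates["multiplexed-cell"]
        assert len(t.bound_variables()) == 10

    def test_three_cell_outlines_carry_border_symbols(self, templates):
        t = templates["multiplexed-cell"]
        cells = [o for o in t.objects if o.id.startswith("cell-")
                 and any(b.element == "border_symbols" for b in o.bindings)]
        assert len(cells) == 3
        assert {b.variable for o in cells for b in o.bindings
                if b.element == "border_symbols"} == {"pAKT", "p4EBP1", "pS6"}
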