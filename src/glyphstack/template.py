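"""Glyph templates: an ordered stack of shaped objects with variable bindings.

A template is the dataset-independent blueprint of a composite glyph. It
serializes losslessly to a versioned JSON project document (the schema is this
package's own; field naming is original). Validation collects *every* failure
with a path to the offending field rather than stopping at the first.

Two designs ship with the package: ``wound`` (a well square whose colour and
mesh density encode cell area and cell number, with an inner wound rectangle
whose height encodes the change in wound area) and ``multiplexed-cell`` (a
cell-context hierarchy binding ten markers of a multiplexed imaging panel).
"""
from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field, replace

from . import encodings as enc
from .errors import GlyphstackError, TemplateValidationError
from .geometry import Transform
from .palettes import SEQUENTIAL
from .render import LAYOUT_MODES, LayoutSpec
from .datamodel import NORMALIZE_MODES, NormalizationSpec

FORMAT_VERSION = "1"

SHAPE_KINDS = ("circle", "ellipse", "square", "rectangle", "custom")

_SHAPE_DIMS = {
    "circle": ("r",), "ellipse": ("rx", "ry"), "square": ("side",),
    "rectangle": ("width", "height"),
}

#: external symbol spelling in the JSON document
_SYMBOL_OUT = {"x_cross": "x"}
_SYMBOL_IN = {"x": "x_cross"}

_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}$")


@dataclass(frozen=True)
class BaseStyle:
    """Static fill/stroke of an object (before any data binding)."""

    fill: tuple[int, int, int] | None = (230, 230, 230)
    stroke: tuple[int, int, int] | None = (40, 40, 40)
    stroke_width: float = 1.0


@dataclass(frozen=True)
class GlyphObject:
    """One shaped layer of a composite glyph."""

    id: str
    name: str
    shape_kind: str
    shape_params: dict
    transform: Transform = field(default_factory=Transform)
    z_order: int = 0
    visible: bool = True
    base_style: BaseStyle = field(default_factory=BaseStyle)
    bindings: tuple[enc.ElementBinding, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "bindings", tuple(self.bindings))


@dataclass(frozen=True)
class Template:
    """Ordered object stack plus layout and normalization directives."""

    name: str
    objects: tuple[GlyphObject, ...]
    layout: LayoutSpec = field(default_factory=LayoutSpec)
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    seed: int = 0
    format_version: str = FORMAT_VERSION

    def __post_init__(self):
        objs = tuple(self.objects)
        ids = [o.id for o in objs]
        if len(set(ids)) != len(ids):
            raise GlyphstackError(f"duplicate object id(s) in template '{self.name}'")
        # z_order is kept a total order 0..n-1 (ties broken by id)
        ranked = sorted(objs, key=lambda o: (o.z_order, o.id))
        objs = tuple(replace(o, z_order=i) for i, o in enumerate(ranked))
        # restore the original sequence order (presentation order is z order anyway)
        object.__setattr__(self, "objects", tuple(sorted(objs, key=lambda o: o.z_order)))

    def objects_in_z_order(self):
        return sorted(self.objects, key=lambda o: o.z_order)

    def object_by_id(self, oid: str) -> GlyphObject:
        for o in self.objects:
            if o.id == oid:
                return o
        raise GlyphstackError(f"no object with id '{oid}' in template '{self.name}'")

    def bound_variables(self) -> list[str]:
        out = []
        for o in self.objects:
            for b in o.bindings:
                if b.variable not in out:
                    out.append(b.variable)
        return out


# -- serialization -----------------------------------------------------------

def _colour_out(c):
    return None if c is None else "#%02x%02x%02x" % c


def _colour_in(s):
    if s is None:
        return None
    return tuple(int(s[i:i + 2], 16) for i in (1, 3, 5))


def _static_to_dict(s: enc.StaticProps) -> dict:
    return {
        "symbol": _SYMBOL_OUT.get(s.symbol, s.symbol),
        "fill_direction": s.fill_direction,
        "mesh_orientation": s.mesh_orientation,
        "colour": _colour_out(s.colour),
        "colour_map": s.colour_map,
        "stroke_size": s.stroke_size,
        "symbol_size": s.symbol_size,
        "density_max": s.density_max,
    }


def template_to_dict(t: Template) -> dict:
    return {
        "format_version": t.format_version,
        "name": t.name,
        "seed": t.seed,
        "normalization": {
            "mode": t.normalization.mode,
            "linked_groups": [sorted(g) for g in t.normalization.linked_groups],
        },
        "layout": {
            "mode": t.layout.mode,
            "page_size": t.layout.page_size,
            "sort_variable": t.layout.sort_variable,
            "x_variable": t.layout.x_variable,
            "y_variable": t.layout.y_variable,
            "canvas": list(t.layout.canvas),
            "glyph_extent": t.layout.glyph_extent,
        },
        "objects": [
            {
                "id": o.id,
                "name": o.name,
                "shape": {"kind": o.shape_kind, **{
                    k: (v if k != "vertices" else [list(p) for p in v])
                    for k, v in o.shape_params.items()}},
                "transform": {
                    "translation": list(o.transform.translation),
                    "rotation_deg": o.transform.rotation_deg,
                    "scale": [o.transform.scale_x, o.transform.scale_y],
                },
                "z_order": o.z_order,
                "visible": o.visible,
                "style": {
                    "fill": _colour_out(o.base_style.fill),
                    "stroke": _colour_out(o.base_style.stroke),
                    "stroke_width": o.base_style.stroke_width,
                },
                "bindings": [
                    {"element": b.element, "variable": b.variable,
                     "static": _static_to_dict(b.static)}
                    for b in o.bindings
                ],
            }
            for o in t.objects
        ],
    }


def save_template(t: Template) -> str:
    """Canonical JSON text: sorted keys, two-space indent, trailing newline."""
    return json.dumps(template_to_dict(t), sort_keys=True, indent=2) + "\n"


# -- validation --------------------------------------------------------------

def _is_num(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def validate_document(doc) -> list[str]:
    """Schema + semantic validation; returns every problem found."""
    errs: list[str] = []
    if not isinstance(doc, dict):
        return ["document: top level must be a JSON object"]
    fv = doc.get("format_version")
    if not isinstance(fv, str):
        errs.append("format_version: required string field is missing or not a string")
    if "name" in doc and not isinstance(doc["name"], str):
        errs.append("name: must be a string")
    if "seed" in doc and not isinstance(doc["seed"], int):
        errs.append("seed: must be an integer")

    norm = doc.get("normalization", {})
    if not isinstance(norm, dict):
        errs.append("normalization: must be an object")
        norm = {}
    if norm.get("mode", "auto") not in NORMALIZE_MODES:
        errs.append(f"normalization.mode: '{norm.get('mode')}' is not one of {NORMALIZE_MODES}")
    groups = norm.get("linked_groups", [])
    seen: set[str] = set()
    if not isinstance(groups, list):
        errs.append("normalization.linked_groups: must be a list of column-name lists")
        groups = []
    for gi, g in enumerate(groups):
        if not isinstance(g, list) or not all(isinstance(c, str) for c in g):
            errs.append(f"normalization.linked_groups[{gi}]: must be a list of column names")
            continue
        dup = seen & set(g)
        if dup:
            errs.append(f"normalization.linked_groups[{gi}]: column(s) {sorted(dup)} "
                        "already appear in another group")
        seen |= set(g)

    lay = doc.get("layout", {})
    if not isinstance(lay, dict):
        errs.append("layout: must be an object")
        lay = {}
    mode = lay.get("mode", "grid")
    if mode not in LAYOUT_MODES:
        errs.append(f"layout.mode: '{mode}' is not one of {LAYOUT_MODES}")
    if not (isinstance(lay.get("page_size", 16), int) and lay.get("page_size", 16) >= 1):
        errs.append("layout.page_size: must be an integer >= 1")
    canvas = lay.get("canvas", [800, 600])
    if (not isinstance(canvas, list) or len(canvas) != 2
            or not all(_is_num(c) and c > 0 for c in canvas)):
        errs.append("layout.canvas: must be two positive numbers [width, height]")
    if "glyph_extent" in lay and not (_is_num(lay["glyph_extent"]) and lay["glyph_extent"] > 0):
        errs.append("layout.glyph_extent: must be a positive number")
    if mode == "positional":
        for k in ("x_variable", "y_variable"):
            if not isinstance(lay.get(k), str):
                errs.append(f"layout.{k}: positional layout requires a bound column name")

    objects = doc.get("objects")
    if not isinstance(objects, list) or len(objects) == 0:
        errs.append("objects: a template needs a non-empty object list")
        objects = []
    ids: set[str] = set()
    for i, o in enumerate(objects):
        p = f"objects[{i}]"
        if not isinstance(o, dict):
            errs.append(f"{p}: must be an object")
            continue
        oid = o.get("id")
        if not isinstance(oid, str) or not oid:
            errs.append(f"{p}.id: required non-empty string")
        elif oid in ids:
            errs.append(f"{p}.id: duplicate object id '{oid}'")
        else:
            ids.add(oid)
        if "name" in o and not isinstance(o["name"], str):
            errs.append(f"{p}.name: must be a string")
        if "z_order" in o and not isinstance(o["z_order"], int):
            errs.append(f"{p}.z_order: must be an integer")
        if "visible" in o and not isinstance(o["visible"], bool):
            errs.append(f"{p}.visible: must be a boolean")

        shape = o.get("shape")
        if not isinstance(shape, dict) or "kind" not in shape:
            errs.append(f"{p}.shape: required object with a 'kind' field")
        else:
            kind = shape["kind"]
            if kind not in SHAPE_KINDS:
                errs.append(f"{p}.shape.kind: '{kind}' is not one of {SHAPE_KINDS}")
            elif kind == "custom":
                verts = shape.get("vertices")
                if (not isinstance(verts, list) or len(verts) < 3
                        or not all(isinstance(v, list) and len(v) == 2
                                   and all(_is_num(c) for c in v) for v in verts)):
                    errs.append(f"{p}.shape.vertices: custom shape needs >= 3 [x, y] points")
            else:
                for dim in _SHAPE_DIMS[kind]:
                    val = shape.get(dim)
                    if not (_is_num(val) and val > 0):
                        errs.append(f"{p}.shape.{dim}: {kind} needs a positive '{dim}'")

        tf = o.get("transform", {})
        if not isinstance(tf, dict):
            errs.append(f"{p}.transform: must be an object")
            tf = {}
        scale = tf.get("scale", [1, 1])
        if (not isinstance(scale, list) or len(scale) != 2
                or not all(_is_num(s) and s > 0 for s in scale)):
            errs.append(f"{p}.transform.scale: must be two strictly positive factors")
        tr = tf.get("translation", [0, 0])
        if not isinstance(tr, list) or len(tr) != 2 or not all(_is_num(c) for c in tr):
            errs.append(f"{p}.transform.translation: must be two numbers [dx, dy]")
        if "rotation_deg" in tf and not _is_num(tf["rotation_deg"]):
            errs.append(f"{p}.transform.rotation_deg: must be a number")

        style = o.get("style", {})
        if not isinstance(style, dict):
            errs.append(f"{p}.style: must be an object")
            style = {}
        for key in ("fill", "stroke"):
            c = style.get(key, "#000000")
            if c is not None and not (isinstance(c, str) and _HEX_RE.match(c)):
                errs.append(f"{p}.style.{key}: must be '#rrggbb' or null, got {c!r}")
        if "stroke_width" in style and not (_is_num(style["stroke_width"])
                                            and style["stroke_width"] > 0):
            errs.append(f"{p}.style.stroke_width: must be a positive number")

        bindings = o.get("bindings", [])
        if not isinstance(bindings, list):
            errs.append(f"{p}.bindings: must be a list")
            bindings = []
        seen_elements: set[str] = set()
        for j, b in enumerate(bindings):
            q = f"{p}.bindings[{j}]"
            if not isinstance(b, dict):
                errs.append(f"{q}: must be an object")
                continue
            el = b.get("element")
            if el not in enc.ELEMENTS:
                errs.append(f"{q}.element: '{el}' is not one of {enc.ELEMENTS}")
            elif el in seen_elements:
                errs.append(f"{q}.element: element '{el}' bound more than once on this object")
            else:
                seen_elements.add(el)
            if not isinstance(b.get("variable"), str) or not b.get("variable"):
                errs.append(f"{q}.variable: required non-empty column name")
            st = b.get("static", {})
            if not isinstance(st, dict):
                errs.append(f"{q}.static: must be an object")
                continue
            sym = st.get("symbol", "dot")
            if _SYMBOL_IN.get(sym, sym) not in enc.SYMBOLS:
                errs.append(f"{q}.static.symbol: '{sym}' is not one of "
                            f"{tuple(_SYMBOL_OUT.get(s, s) for s in enc.SYMBOLS)}")
            if st.get("fill_direction", "left_to_right") not in enc.FILL_DIRECTIONS:
                errs.append(f"{q}.static.fill_direction: '{st.get('fill_direction')}' "
                            f"is not one of {enc.FILL_DIRECTIONS}")
            if st.get("mesh_orientation", "vertical") not in enc.MESH_ORIENTATIONS:
                errs.append(f"{q}.static.mesh_orientation: '{st.get('mesh_orientation')}' "
                            f"is not one of {enc.MESH_ORIENTATIONS}")
            if el == "fill_gradient" and st.get("colour_map", "Reds") not in SEQUENTIAL:
                errs.append(f"{q}.static.colour_map: unknown palette "
                            f"'{st.get('colour_map')}'")
            c = st.get("colour", "#000000")
            if c is not None and not (isinstance(c, str) and _HEX_RE.match(c)):
                errs.append(f"{q}.static.colour: must be '#rrggbb', got {c!r}")
            dm = st.get("density_max", 10)
            if not (isinstance(dm, int) and dm >= 1):
                errs.append(f"{q}.static.density_max: must be an integer >= 1")
            for key in ("stroke_size", "symbol_size"):
                if key in st and not (_is_num(st[key]) and st[key] > 0):
                    errs.append(f"{q}.static.{key}: must be a positive number")
    return errs


def load_template(document: str) -> Template:
    """Parse and validate a JSON project document into a Template."""
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise TemplateValidationError([f"document: not well-formed JSON ({exc})"]) from exc
    errs = validate_document(doc)
    if errs:
        raise TemplateValidationError(errs)

    norm = doc.get("normalization", {})
    layout = doc.get("layout", {})
    objects = []
    for o in doc["objects"]:
        shape = dict(o["shape"])
        kind = shape.pop("kind")
        if kind == "custom":
            shape["vertices"] = [tuple(p) for p in shape["vertices"]]
        tf = o.get("transform", {})
        style = o.get("style", {})
        bindings = []
        for b in o.get("bindings", []):
            st = b.get("static", {})
            kwargs = {}
            if "symbol" in st:
                kwargs["symbol"] = _SYMBOL_IN.get(st["symbol"], st["symbol"])
            for k in ("fill_direction", "mesh_orientation", "colour_map",
                      "stroke_size", "symbol_size", "density_max"):
                if k in st and st[k] is not None:
                    kwargs[k] = st[k]
            if st.get("colour") is not None:
                kwargs["colour"] = _colour_in(st["colour"])
            bindings.append(enc.ElementBinding(b["element"], b["variable"],
                                               enc.StaticProps(**kwargs)))
        objects.append(GlyphObject(
            id=o["id"],
            name=o.get("name", o["id"]),
            shape_kind=kind,
            shape_params=shape,
            transform=Transform(
                translation=tuple(tf.get("translation", (0.0, 0.0))),
                rotation_deg=float(tf.get("rotation_deg", 0.0)),
                scale_x=float(tf.get("scale", (1.0, 1.0))[0]),
                scale_y=float(tf.get("scale", (1.0, 1.0))[1]),
            ),
            z_order=int(o.get("z_order", 0)),
            visible=bool(o.get("visible", True)),
            base_style=BaseStyle(
                fill=_colour_in(style.get("fill", "#e6e6e6")),
                stroke=_colour_in(style.get("stroke", "#282828")),
                stroke_width=float(style.get("stroke_width", 1.0)),
            ),
            bindings=tuple(bindings),
        ))
    return Template(
        name=doc.get("name", "untitled"),
        objects=tuple(objects),
        layout=LayoutSpec(
            mode=layout.get("mode", "grid"),
            page_size=int(layout.get("page_size", 16)),
            sort_variable=layout.get("sort_variable"),
            x_variable=layout.get("x_variable"),
            y_variable=layout.get("y_variable"),
            canvas=tuple(layout.get("canvas", (800.0, 600.0))),
            glyph_extent=float(layout.get("glyph_extent", 120.0)),
        ),
        normalization=NormalizationSpec(
            linked_groups=tuple(frozenset(g) for g in norm.get("linked_groups", [])),
            mode=norm.get("mode", "auto"),
        ),
        seed=int(doc.get("seed", 0)),
        format_version=doc["format_version"],
    )


# -- object management -------------------------------------------------------

def remap_variables(template: Template, mapping: dict[str, str],
                    columns=None) -> Template:
    """Rewrite binding variables old→new; untouched bindings are preserved.

    If ``columns`` (the target table's column names) is given, every new name
    must exist there.
    """
    if columns is not None:
        cols = set(columns)
        missing = [f"'{old}'→'{new}'" for old, new in mapping.items() if new not in cols]
        if missing:
            raise GlyphstackError(
                "remap target column(s) not in the data: " + ", ".join(missing))
    new_objects = []
    for o in template.objects:
        bindings = tuple(
            replace(b, variable=mapping.get(b.variable, b.variable)) for b in o.bindings)
        new_objects.append(replace(o, bindings=bindings))
    return replace(template, objects=tuple(new_objects))


def duplicate_object(template: Template, oid: str) -> Template:
    """Deep-copy an object under a fresh deterministic id, on top of the stack."""
    src = template.object_by_id(oid)
    existing = {o.id for o in template.objects}
    new_id = f"{oid}-copy"
    k = 2
    while new_id in existing:
        new_id = f"{oid}-copy{k}"
        k += 1
    max_z = max(o.z_order for o in template.objects)
    dup = replace(copy.deepcopy(src), id=new_id, name=f"{src.name} (copy)", z_order=max_z + 1)
    return replace(template, objects=tuple(template.objects) + (dup,))


def delete_object(template: Template, oid: str) -> Template:
    template.object_by_id(oid)
    return replace(template, objects=tuple(o for o in template.objects if o.id != oid))


def set_layer_order(template: Template, oid: str, direction: str) -> Template:
    """Swap an object's z order with its neighbour ('up' or 'down'); no-op at the ends."""
    if direction not in ("up", "down"):
        raise GlyphstackError(f"direction must be 'up' or 'down', got '{direction}'")
    obj = template.object_by_id(oid)
    ordered = template.objects_in_z_order()
    i = ordered.index(obj)
    j = i + 1 if direction == "up" else i - 1
    if j < 0 or j >= len(ordered):
        return template
    other = ordered[j]
    new_objects = []
    for o in template.objects:
        if o.id == obj.id:
            new_objects.append(replace(o, z_order=other.z_order))
        elif o.id == other.id:
            new_objects.append(replace(o, z_order=obj.z_order))
        else:
            new_objects.append(o)
    return replace(template, objects=tuple(new_objects))


def set_visibility(template: Template, oid: str, visible: bool) -> Template:
    template.object_by_id(oid)
    return replace(template, objects=tuple(
        replace(o, visible=visible) if o.id == oid else o for o in template.objects))


# -- bundled templates ---------------------------------------------------------

#: one-stroke cell-like outline (rounded blob, drawn clockwise on a y-down canvas)
_CELL_OUTLINE = [
    (0.0, -1.0), (0.55, -0.88), (0.92, -0.48), (1.0, 0.05), (0.82, 0.6),
    (0.42, 0.93), (-0.1, 1.0), (-0.62, 0.85), (-0.95, 0.42), (-1.0, -0.12),
    (-0.8, -0.62), (-0.45, -0.92),
]


def _cell_object(oid, name, scale, colour, variable, z) -> GlyphObject:
    verts = [(x * scale, y * scale) for x, y in _CELL_OUTLINE]
    return GlyphObject(
        id=oid, name=name, shape_kind="custom",
        shape_params={"vertices": verts, "smooth": True},
        z_order=z,
        base_style=BaseStyle(fill=None, stroke=(150, 150, 150), stroke_width=0.8),
        bindings=(enc.ElementBinding("border_symbols", variable, enc.StaticProps(
            symbol="dot", colour=colour, symbol_size=2.2)),),
    )


def _wound_template() -> Template:
    well = GlyphObject(
        id="well", name="Well", shape_kind="square", shape_params={"side": 100},
        z_order=0,
        base_style=BaseStyle(fill=(254, 224, 210), stroke=(60, 60, 60), stroke_width=1.5),
        bindings=(
            enc.ElementBinding("fill_gradient", "cell_area",
                               enc.StaticProps(colour_map="Reds")),
            enc.ElementBinding("mesh", "cell_number", enc.StaticProps(
                mesh_orientation="grid", colour=(80, 80, 80), stroke_size=0.7,
                density_max=12)),
        ),
    )
    wound = GlyphObject(
        id="wound", name="Wound", shape_kind="rectangle",
        shape_params={"width": 26, "height": 84},
        z_order=1,
        base_style=BaseStyle(fill=(247, 247, 247), stroke=(40, 40, 40), stroke_width=1.2),
        bindings=(enc.ElementBinding("length", "wound_area_change", enc.StaticProps()),),
    )
    return Template(
        name="wound", objects=(well, wound),
        layout=LayoutSpec(mode="grid", page_size=12, canvas=(900.0, 700.0),
                          glyph_extent=150.0),
    )


def _multiplexed_template() -> Template:
    context = GlyphObject(
        id="context", name="Cell context", shape_kind="square", shape_params={"side": 130},
        z_order=0,
        base_style=BaseStyle(fill=None, stroke=(120, 120, 120), stroke_width=1.0),
        bindings=(enc.ElementBinding("mesh", "cell_density", enc.StaticProps(
            mesh_orientation="grid", colour=(130, 130, 130), stroke_size=0.6,
            density_max=10)),),
    )
    cell_ps6 = _cell_object("cell-ps6", "Cell outline (pS6)", 52.0, (27, 120, 55), "pS6", 1)
    cell_p4ebp1 = _cell_object("cell-p4ebp1", "Cell outline (p4EBP1)", 47.0,
                               (230, 97, 1), "p4EBP1", 2)
    cell_pakt = GlyphObject(
        id="cell-pakt", name="Cell outline (pAKT)", shape_kind="custom",
        shape_params={"vertices": [(x * 42.0, y * 42.0) for x, y in _CELL_OUTLINE],
                      "smooth": True},
        z_order=3,
        base_style=BaseStyle(fill=(250, 250, 250), stroke=(150, 150, 150), stroke_width=0.8),
        bindings=(
            enc.ElementBinding("border_symbols", "pAKT", enc.StaticProps(
                symbol="dot", colour=(84, 39, 143), symbol_size=2.2)),
            enc.ElementBinding("fill_symbols", "CAV1", enc.StaticProps(
                symbol="x_cross", colour=(99, 99, 99), symbol_size=2.6)),
        ),
    )
    golgi = GlyphObject(
        id="golgi", name="Golgi", shape_kind="circle", shape_params={"r": 10},
        transform=Transform(translation=(-20.0, 12.0)), z_order=4,
        base_style=BaseStyle(fill=(199, 233, 180), stroke=(60, 60, 60), stroke_width=0.8),
        bindings=(enc.ElementBinding("fill_gradient", "GM130",
                                     enc.StaticProps(colour_map="YlGnBu")),),
    )
    centrosome = GlyphObject(
        id="centrosome", name="Centrosome", shape_kind="circle", shape_params={"r": 5},
        transform=Transform(translation=(22.0, 16.0)), z_order=5,
        base_style=BaseStyle(fill=(199, 233, 180), stroke=(60, 60, 60), stroke_width=0.8),
        bindings=(enc.ElementBinding("fill_gradient", "PCNT",
                                     enc.StaticProps(colour_map="YlGnBu")),),
    )
    nucleus = GlyphObject(
        id="nucleus", name="Nucleus", shape_kind="circle", shape_params={"r": 17},
        transform=Transform(translation=(2.0, -8.0)), z_order=6,
        base_style=BaseStyle(fill=(237, 248, 177), stroke=(60, 60, 60), stroke_width=0.8),
        bindings=(
            enc.ElementBinding("fill_gradient", "YAP",
                               enc.StaticProps(colour_map="YlGnBu")),
            enc.ElementBinding("border_symbols", "NUPS", enc.StaticProps(
                symbol="dot", colour=(203, 24, 29), symbol_size=1.8)),
            enc.ElementBinding("fill_symbols", "PCNA", enc.StaticProps(
                symbol="dot", colour=(33, 113, 181), symbol_size=1.6)),
        ),
    )
    return Template(
        name="multiplexed-cell",
        objects=(context, cell_ps6, cell_p4ebp1, cell_pakt, golgi, centrosome, nucleus),
        layout=LayoutSpec(mode="positional", x_variable="umap1", y_variable="umap2",
                          canvas=(1000.0, 800.0), glyph_extent=170.0),
    )


def bundled_templates() -> dict[str, Template]:
    """The shipped template portfolio, keyed by name."""
    return {"wound": _wound_template(), "multiplexed-cell": _multiplexed_template()}
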