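"""Resolve a template against normalized data into a drawable Scene.

A Scene is a resolution-independent tree: ordered groups (one per composite
glyph, each with a translate+scale placement) of primitive draw items. The
same Scene serializes to SVG (deterministic bytes: fixed attribute order and
float formatting) or rasterizes to PNG via Pillow.

Rendering is a pure function of (template, table, page, seed): element paint
order within an object is base shape, then area encodings (gradient colour,
fill symbols, mesh), then outline encodings (border overlay, border symbols,
spikes), so outline marks are never buried.
"""
from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import encodings as enc
from .errors import ConfigurationError, RenderError
from .geometry import ClosedPath, Transform, make_shape

LAYOUT_MODES = ("grid", "positional")

_FMT = "{:.3f}"


def _f(x: float) -> str:
    s = _FMT.format(float(x))
    return "0.000" if s == "-0.000" else s


def _hexc(colour) -> str:
    if colour is None:
        return "none"
    r, g, b = colour
    return f"#{r:02x}{g:02x}{b:02x}"


def _esc(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
            .replace('"', "&quot;"))


# -- scene model -------------------------------------------------------------

@dataclass
class PathItem:
    """A polyline or closed polygon."""

    points: np.ndarray
    closed: bool = True
    fill: tuple | None = None
    stroke: tuple | None = (0, 0, 0)
    stroke_width: float = 1.0
    opacity: float = 1.0

    def to_svg(self) -> str:
        pts = np.asarray(self.points, dtype=float)
        d = "M " + " L ".join(f"{_f(x)} {_f(y)}" for x, y in pts)
        if self.closed:
            d += " Z"
        return (f'<path d="{d}" fill="{_hexc(self.fill)}" stroke="{_hexc(self.stroke)}" '
                f'stroke-width="{_f(self.stroke_width)}" opacity="{_f(self.opacity)}"/>')


@dataclass
class SymbolItem:
    """One placed glyph symbol (x, asterisk, dash, dot, square, wedge)."""

    symbol: str
    center: tuple[float, float]
    size: float
    colour: tuple = (0, 0, 0)
    opacity: float = 1.0

    def _strokes(self) -> list[np.ndarray]:
        cx, cy = self.center
        r = self.size / 2.0
        if self.symbol == "x_cross":
            return [np.array([[cx - r, cy - r], [cx + r, cy + r]]),
                    np.array([[cx - r, cy + r], [cx + r, cy - r]])]
        if self.symbol == "asterisk":
            arms = []
            for k in range(3):
                th = math.pi * k / 3.0
                dx, dy = r * math.cos(th), r * math.sin(th)
                arms.append(np.array([[cx - dx, cy - dy], [cx + dx, cy + dy]]))
            return arms
        if self.symbol == "dash":
            return [np.array([[cx - r, cy], [cx + r, cy]])]
        return []

    def to_svg(self) -> str:
        cx, cy = self.center
        r = self.size / 2.0
        col = _hexc(self.colour)
        op = _f(self.opacity)
        if self.symbol == "dot":
            return f'<circle cx="{_f(cx)}" cy="{_f(cy)}" r="{_f(r)}" fill="{col}" opacity="{op}"/>'
        if self.symbol == "square":
            return (f'<rect x="{_f(cx - r)}" y="{_f(cy - r)}" width="{_f(2 * r)}" '
                    f'height="{_f(2 * r)}" fill="{col}" opacity="{op}"/>')
        if self.symbol == "wedge":
            pts = [(cx, cy - r), (cx + r, cy + r), (cx - r, cy + r)]
            d = "M " + " L ".join(f"{_f(x)} {_f(y)}" for x, y in pts) + " Z"
            return f'<path d="{d}" fill="{col}" opacity="{op}"/>'
        segs = "".join(
            f'M {_f(a[0])} {_f(a[1])} L {_f(b[0])} {_f(b[1])} ' for a, b in self._strokes())
        w = max(self.size / 6.0, 0.5)
        return (f'<path d="{segs.strip()}" fill="none" stroke="{col}" '
                f'stroke-width="{_f(w)}" opacity="{op}"/>')


@dataclass
class TextItem:
    text: str
    pos: tuple[float, float]
    size: float = 12.0
    colour: tuple = (0, 0, 0)
    bold: bool = False
    anchor: str = "start"  # start | middle | end
    title: str | None = None

    def to_svg(self) -> str:
        x, y = self.pos
        weight = "bold" if self.bold else "normal"
        head = (f'<text x="{_f(x)}" y="{_f(y)}" font-size="{_f(self.size)}" '
                f'font-family="sans-serif" font-weight="{weight}" '
                f'text-anchor="{self.anchor}" fill="{_hexc(self.colour)}">')
        body = _esc(self.text)
        if self.title and self.title != self.text:
            body = f"<title>{_esc(self.title)}</title>" + body
        return head + body + "</text>"


DrawItem = PathItem | SymbolItem | TextItem


@dataclass
class MarkGroup:
    gid: str
    items: list = field(default_factory=list)
    translation: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def to_svg(self) -> str:
        tx, ty = self.translation
        tf = f"translate({_f(tx)} {_f(ty)}) scale({_f(self.scale)})"
        inner = "\n".join("  " + it.to_svg() for it in self.items)
        return f'<g id="{_esc(self.gid)}" transform="{tf}">\n{inner}\n</g>'


@dataclass
class Scene:
    groups: list[MarkGroup]
    width: float
    height: float
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LayoutSpec:
    """How composite glyphs are placed on the canvas.

    ``grid`` tiles the (optionally sorted) rows of one page row-major on a
    near-square grid; ``positional`` scatters all rows by two bound
    coordinate columns.
    """

    mode: str = "grid"
    page_size: int = 16
    sort_variable: str | None = None
    x_variable: str | None = None
    y_variable: str | None = None
    canvas: tuple[float, float] = (800.0, 600.0)
    glyph_extent: float = 120.0

    def __post_init__(self):
        if self.mode not in LAYOUT_MODES:
            raise ConfigurationError(f"unknown layout mode '{self.mode}'")
        if self.page_size < 1:
            raise ConfigurationError("page_size must be >= 1")
        if self.canvas[0] <= 0 or self.canvas[1] <= 0 or self.glyph_extent <= 0:
            raise ConfigurationError("canvas dimensions and glyph_extent must be positive")


# -- glyph resolution --------------------------------------------------------

def object_seed(global_seed: int, object_id: str) -> int:
    """Stable per-object RNG seed (drives the random mesh orientation)."""
    return (int(global_seed) * 1000003 + zlib.crc32(object_id.encode())) % (2 ** 31)


def _value_for(obj, binding, values: dict) -> float:
    if binding.variable not in values:
        raise RenderError(
            f"object '{obj.id}', element '{binding.element}': variable "
            f"'{binding.variable}' not found in the data")
    v = values[binding.variable]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        warnings.warn(
            f"missing value for '{binding.variable}' on object '{obj.id}'; "
            "rendering the element at its zero floor", stacklevel=3)
        return 0.0
    return float(v)


def resolve_object_path(obj, values: dict) -> ClosedPath:
    """Base shape with dimension bindings and placement applied."""
    path = make_shape(obj.shape_kind, **obj.shape_params)
    fx = fy = 1.0
    extra_rot = 0.0
    for b in obj.bindings:
        if b.element == "length":
            fy = enc.encode_length(1.0, _value_for(obj, b, values))
        elif b.element == "width":
            fx = enc.encode_width(1.0, _value_for(obj, b, values))
        elif b.element == "rotation":
            extra_rot = enc.encode_rotation(_value_for(obj, b, values))
    if fx != 1.0 or fy != 1.0:
        path = Transform(scale_x=fx, scale_y=fy).apply(path)
    t = obj.transform
    placed = Transform(translation=t.translation, rotation_deg=t.rotation_deg + extra_rot,
                       scale_x=t.scale_x, scale_y=t.scale_y)
    return placed.apply(path)


def _marks_to_items(markset: enc.MarkSet, opacity: float) -> list:
    items = []
    for m in markset:
        if m.kind == "glyph_symbol":
            items.append(SymbolItem(m.style["symbol"], m.geometry, m.style["size"],
                                    m.style["colour"], opacity))
        elif m.kind == "segment":
            items.append(PathItem(np.array(m.geometry), closed=False, fill=None,
                                  stroke=m.style["colour"],
                                  stroke_width=m.style["stroke_size"], opacity=opacity))
        elif m.kind == "subpath":
            items.append(PathItem(np.asarray(m.geometry), closed=False, fill=None,
                                  stroke=m.style["colour"],
                                  stroke_width=m.style["stroke_size"], opacity=opacity))
    return items


def render_glyph(template, values: dict, seed: int | None = None) -> list:
    """Draw items for one composite glyph, in template design coordinates.

    ``values`` maps column name to normalized value. Objects are processed in
    z order; hidden objects contribute nothing.
    """
    seed = template.seed if seed is None else seed
    items: list = []
    for obj in template.objects_in_z_order():
        if not obj.visible:
            continue
        path = resolve_object_path(obj, values)
        by_element = {b.element: b for b in obj.bindings}

        opacity = 1.0
        if "opacity" in by_element:
            opacity = enc.encode_opacity(_value_for(obj, by_element["opacity"], values))
        fill = obj.base_style.fill
        if "fill_gradient" in by_element:
            b = by_element["fill_gradient"]
            fill = enc.encode_fill_gradient(_value_for(obj, b, values), b.static.colour_map)

        items.append(PathItem(path.vertices, closed=True, fill=fill,
                              stroke=obj.base_style.stroke,
                              stroke_width=obj.base_style.stroke_width, opacity=opacity))
        if "fill_symbols" in by_element:
            b = by_element["fill_symbols"]
            items += _marks_to_items(
                enc.encode_fill_symbols(path, _value_for(obj, b, values), b.static), opacity)
        if "mesh" in by_element:
            b = by_element["mesh"]
            items += _marks_to_items(
                enc.encode_mesh(path, _value_for(obj, b, values), b.static,
                                seed=object_seed(seed, obj.id)), opacity)
        if "border_overlay" in by_element:
            b = by_element["border_overlay"]
            items += _marks_to_items(
                enc.encode_border_overlay(path, _value_for(obj, b, values), b.static), opacity)
        if "border_symbols" in by_element:
            b = by_element["border_symbols"]
            items += _marks_to_items(
                enc.encode_border_symbols(path, _value_for(obj, b, values), b.static), opacity)
        if "spikes" in by_element:
            b = by_element["spikes"]
            items += _marks_to_items(
                enc.encode_spikes(path, _value_for(obj, b, values), b.static), opacity)
    return items


def design_bbox(template) -> tuple[float, float, float, float]:
    """Bounding box of the template in design space at full dimension scale,
    padded by the largest outline-mark reach (spike amplitude, symbol size)."""
    lo = np.array([np.inf, np.inf])
    hi = np.array([-np.inf, -np.inf])
    pad = 0.0
    for obj in template.objects:
        if not obj.visible:
            continue
        path = obj.transform.apply(make_shape(obj.shape_kind, **obj.shape_params))
        xmin, ymin, xmax, ymax = path.bbox
        lo = np.minimum(lo, [xmin, ymin])
        hi = np.maximum(hi, [xmax, ymax])
        for b in obj.bindings:
            if b.element == "spikes":
                pad = max(pad, enc.SPIKE_AMPLITUDE * b.static.stroke_size)
            elif b.element in ("border_symbols", "fill_symbols"):
                pad = max(pad, b.static.symbol_size)
            elif b.element == "border_overlay":
                pad = max(pad, b.static.stroke_size)
    if not np.all(np.isfinite(lo)):
        raise RenderError("template has no visible objects")
    return (float(lo[0] - pad), float(lo[1] - pad), float(hi[0] + pad), float(hi[1] + pad))


# -- layout ------------------------------------------------------------------

def layout(ntable, spec: LayoutSpec, page: int = 0) -> list[tuple[int, tuple[float, float]]]:
    """Per-row canvas placements (row index, glyph centre) for one page.

    Grid mode sorts rows by ``sort_variable`` (stable ascending; input order
    when unset), slices the requested page, and tiles row-major on a
    near-square grid. Positional mode linearly scales the two bound coordinate
    columns to the canvas with a half-glyph margin; all rows land on page 0.
    """
    n = ntable.n_rows
    w, h = spec.canvas
    if spec.mode == "grid":
        n_pages = max(1, math.ceil(n / spec.page_size))
        if page < 0 or page >= n_pages:
            raise RenderError(f"page {page} out of range (dataset has {n_pages} page(s))")
        order = list(range(n))
        if spec.sort_variable is not None:
            if spec.sort_variable not in ntable.frame.columns:
                raise RenderError(f"sort variable '{spec.sort_variable}' not in the data")
            keys = ntable.frame[spec.sort_variable].to_numpy()
            order = list(np.argsort(keys, kind="stable"))
        chunk = order[page * spec.page_size:(page + 1) * spec.page_size]
        ncols = math.ceil(math.sqrt(spec.page_size))
        nrows = math.ceil(spec.page_size / ncols)
        cw, ch = w / ncols, h / nrows
        out = []
        for j, ri in enumerate(chunk):
            r, c = divmod(j, ncols)
            out.append((int(ri), (c * cw + cw / 2.0, r * ch + ch / 2.0)))
        return out

    # positional
    if page != 0:
        raise RenderError("positional layout places all rows on a single page (page 0)")
    if spec.x_variable is None or spec.y_variable is None:
        raise RenderError("positional layout requires both x_variable and y_variable")
    for var in (spec.x_variable, spec.y_variable):
        if var not in ntable.frame.columns:
            raise RenderError(f"positional axis variable '{var}' not in the data")
    margin = spec.glyph_extent / 2.0

    def scaled(var, span):
        x = ntable.frame[var].to_numpy(dtype=float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi == lo:
            return np.full(n, span / 2.0)
        return margin + (x - lo) / (hi - lo) * (span - 2 * margin)

    xs = scaled(spec.x_variable, w)
    ys = scaled(spec.y_variable, h)
    return [(i, (float(xs[i]), float(ys[i]))) for i in range(n)]


def render_page(template, ntable, page: int = 0, seed: int | None = None) -> Scene:
    """One page of composite glyphs as a Scene (one group per data row)."""
    spec = template.layout
    seed = template.seed if seed is None else seed
    placements = layout(ntable, spec, page)
    xmin, ymin, xmax, ymax = design_bbox(template)
    extent = max(xmax - xmin, ymax - ymin)
    s = spec.glyph_extent / extent
    cx0, cy0 = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    labels = ntable.labels
    groups = []
    for ri, (cx, cy) in placements:
        values = ntable.row_values(ri)
        items = render_glyph(template, values, seed=seed)
        label = labels[ri]
        items.append(TextItem(label, (cx0, ymax + 14.0 / s), size=12.0 / s, anchor="middle"))
        half = spec.glyph_extent / 2.0
        if cx < half or cy < half or cx > spec.canvas[0] - half or cy > spec.canvas[1] - half:
            warnings.warn(f"glyph for row {ri} ('{label}') extends beyond the canvas",
                          stacklevel=2)
        groups.append(MarkGroup(gid=f"glyph-{ri}", items=items,
                                translation=(cx - s * cx0, cy - s * cy0), scale=s))
    return Scene(groups, spec.canvas[0], spec.canvas[1],
                 metadata={"page": page, "template": template.name, "seed": seed})


# -- export ------------------------------------------------------------------

def export_svg(scene: Scene) -> str:
    """Serialize a Scene to SVG 1.1 text with deterministic bytes."""
    w, h = _f(scene.width), _f(scene.height)
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="{w}" height="{h}" '
        f'viewBox="0 0 {w} {h}">',
    ]
    parts += [g.to_svg() for g in scene.groups]
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def write_svg(scene: Scene, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(export_svg(scene))


def export_png(scene: Scene, path, dpi: float = 96.0) -> None:
    """Rasterize the Scene at the requested dpi (96 dpi = 1 px per canvas unit)."""
    from PIL import Image, ImageDraw, ImageFont

    k = dpi / 96.0
    W, H = max(1, round(scene.width * k)), max(1, round(scene.height * k))
    base = Image.new("RGBA", (W, H), (255, 255, 255, 255))
    try:
        font_cache: dict[int, ImageFont.ImageFont] = {}

        def font(px):
            px = max(6, round(px))
            if px not in font_cache:
                try:
                    font_cache[px] = ImageFont.load_default(size=px)
                except TypeError:
                    font_cache[px] = ImageFont.load_default()
            return font_cache[px]
    except Exception:  # pragma: no cover
        font = None

    for g in scene.groups:
        tx, ty = g.translation
        s = g.scale

        def T(pts):
            pts = np.atleast_2d(np.asarray(pts, dtype=float))
            return [(float((x * s + tx) * k), float((y * s + ty) * k)) for x, y in pts]

        for it in g.items:
            layer = Image.new("RGBA", (W, H), (0, 0, 0, 0))
            d = ImageDraw.Draw(layer)
            if isinstance(it, PathItem):
                pts = T(it.points)
                a = int(round(255 * it.opacity))
                wd = max(1, round(it.stroke_width * s * k))
                if it.closed and it.fill is not None:
                    d.polygon(pts, fill=(*it.fill, a))
                if it.stroke is not None:
                    seq = pts + [pts[0]] if it.closed else pts
                    d.line(seq, fill=(*it.stroke, a), width=wd)
            elif isinstance(it, SymbolItem):
                (cx, cy), = T([it.center])
                r = it.size / 2.0 * s * k
                a = int(round(255 * it.opacity))
                col = (*it.colour, a)
                if it.symbol == "dot":
                    d.ellipse([cx - r, cy - r, cx + r, cy + r], fill=col)
                elif it.symbol == "square":
                    d.rectangle([cx - r, cy - r, cx + r, cy + r], fill=col)
                elif it.symbol == "wedge":
                    d.polygon([(cx, cy - r), (cx + r, cy + r), (cx - r, cy + r)], fill=col)
                else:
                    wd = max(1, round(it.size / 6.0 * s * k))
                    for seg in it._strokes():
                        d.line(T(seg), fill=col, width=wd)
            elif isinstance(it, TextItem):
                (x, y), = T([it.pos])
                px = it.size * s * k
                f = font(px) if font else None
                txt = it.text
                if f is not None:
                    tw = d.textlength(txt, font=f)
                    if it.anchor == "middle":
                        x -= tw / 2.0
                    elif it.anchor == "end":
                        x -= tw
                    d.text((x, y - px), txt, fill=(*it.colour, 255), font=f)
            base = Image.alpha_composite(base, layer)
    base.convert("RGB").save(path, format="PNG", dpi=(dpi, dpi))
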