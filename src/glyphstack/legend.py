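"""Automatic legend: each bound object in its own panel, every element labelled.

Because templates are free-form we cannot know in advance how objects overlap,
so the legend draws every object separately: one panel per visible object with
at least one binding, an exemplar rendered with every bound value at 0.7 (high
enough that count-based elements show several marks), and one label per
binding placed by a greedy compass-point search so that no two label boxes
overlap. Labels that cannot be placed are listed under the panel rather than
dropped. Long variable names are truncated; the full name travels as an SVG
title element (the static-file stand-in for a hover tooltip).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import encodings as enc
from .errors import GlyphstackError
from .render import (MarkGroup, PathItem, Scene, SymbolItem, TextItem,
                     render_glyph, design_bbox)

#: exemplar value used for every binding in a legend panel
EXEMPLAR_VALUE = 0.7
#: default truncation width for variable-name labels
MAX_LABEL_CHARS = 18

_FONT = 11.0
_CHAR_W = 0.62  # approximate glyph width as a fraction of font size

PANEL_W = 340.0
PANEL_CONTENT = 150.0  # exemplar box edge within the panel
PANEL_PAD = 14.0
TITLE_H = 20.0


def truncate_label(name: str, max_chars: int = MAX_LABEL_CHARS) -> tuple[str, str]:
    """(short label, full name). Names over ``max_chars`` keep the first
    ``max_chars - 1`` characters plus an ellipsis."""
    if max_chars < 4:
        raise GlyphstackError("max_chars must be >= 4")
    if len(name) <= max_chars:
        return name, name
    return name[:max_chars - 1] + "…", name


@dataclass
class LabelBox:
    text: str
    full: str
    x: float  # top-left
    y: float
    w: float
    h: float
    anchor: tuple[float, float]  # the mark position the label points at

    @property
    def rect(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.x + self.w, self.y + self.h)


def _disjoint(a: LabelBox, b: LabelBox) -> bool:
    ax0, ay0, ax1, ay1 = a.rect
    bx0, by0, bx1, by1 = b.rect
    return ax1 <= bx0 or bx1 <= ax0 or ay1 <= by0 or by1 <= ay0


# compass directions, east first, as (dx, dy) on a y-down canvas
_COMPASS = ((1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1))


def place_labels(anchors: list[tuple[str, str, tuple[float, float]]],
                 bounds: tuple[float, float, float, float],
                 font_size: float = _FONT,
                 radii=(18.0, 34.0, 52.0, 74.0)) -> tuple[list[LabelBox], list[tuple[str, str]]]:
    """Greedy non-overlapping label assignment.

    ``anchors`` is a list of (short text, full name, anchor point) in element
    order. Candidates are the anchor offset toward the 8 compass directions at
    increasing radii; the first position whose box stays inside ``bounds`` and
    intersects no placed box wins. Exhausted labels go to the side list —
    nothing is silently dropped.
    """
    placed: list[LabelBox] = []
    side: list[tuple[str, str]] = []
    x0, y0, x1, y1 = bounds
    for text, full, (ax, ay) in anchors:
        w = max(len(text), 1) * _CHAR_W * font_size + 4.0
        h = font_size * 1.3
        found = None
        for r in radii:
            for dx, dy in _COMPASS:
                norm = (dx * dx + dy * dy) ** 0.5
                cx = ax + dx / norm * r
                cy = ay + dy / norm * r
                # box centred vertically on the candidate point; x placement
                # follows the horizontal compass component
                if dx > 0:
                    bx = cx
                elif dx < 0:
                    bx = cx - w
                else:
                    bx = cx - w / 2.0
                box = LabelBox(text, full, bx, cy - h / 2.0, w, h, (ax, ay))
                bx0, by0, bx1, by1 = box.rect
                if bx0 < x0 or by0 < y0 or bx1 > x1 or by1 > y1:
                    continue
                if all(_disjoint(box, other) for other in placed):
                    found = box
                    break
            if found:
                break
        if found:
            placed.append(found)
        else:
            side.append((text, full))
    return placed, side


@dataclass
class LegendPanel:
    object_id: str
    object_name: str
    exemplar_items: list
    labels: list[LabelBox]
    side_list: list[tuple[str, str]]
    height: float


def build_panel(template, obj, font_size: float = _FONT) -> LegendPanel:
    """Render one object alone at the exemplar value and place its labels."""
    solo = replace(template, objects=(replace(obj, visible=True, z_order=0),))
    values = {b.variable: EXEMPLAR_VALUE for b in obj.bindings}
    xmin, ymin, xmax, ymax = design_bbox(solo)
    extent = max(xmax - xmin, ymax - ymin)
    # cap magnification so small objects (and their strokes) are not blown up
    s = min(PANEL_CONTENT / extent, 3.0)
    cx0, cy0 = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    # exemplar sits in the left part of the panel, labels may spill right
    ex_cx = PANEL_PAD + PANEL_CONTENT / 2.0 + 30.0
    ex_cy = TITLE_H + PANEL_PAD + PANEL_CONTENT / 2.0

    def to_panel(p):
        return ((p[0] - cx0) * s + ex_cx, (p[1] - cy0) * s + ex_cy)

    from .render import resolve_object_path

    items = render_glyph(solo, values, seed=template.seed)
    # map exemplar items into panel coordinates
    panel_items = []
    for it in items:
        if isinstance(it, PathItem):
            pts = np.asarray(it.points, dtype=float)
            pts = (pts - [cx0, cy0]) * s + [ex_cx, ex_cy]
            panel_items.append(replace(it, points=pts, stroke_width=it.stroke_width * s))
        elif isinstance(it, SymbolItem):
            panel_items.append(replace(it, center=to_panel(it.center), size=it.size * s))
        elif isinstance(it, TextItem):
            continue  # no row label in legend panels

    path = resolve_object_path(obj, values)
    anchors = []
    order = ("fill_symbols", "mesh", "border_overlay", "border_symbols", "spikes")
    counted = {el: 0 for el in order}
    # how many items each mark-emitting element contributed, in paint order
    for b in obj.bindings:
        if b.element in order:
            counted[b.element] = len(_element_markset(path, b, template.seed, obj.id))
    slices = {}
    cursor = 1  # skip the base shape item
    for el in order:
        slices[el] = panel_items[cursor:cursor + counted[el]]
        cursor += counted[el]
    scalar_spots = {
        "length": ((path.bbox[0] + path.bbox[2]) / 2.0, path.bbox[1]),
        "width": (path.bbox[2], (path.bbox[1] + path.bbox[3]) / 2.0),
        "fill_gradient": tuple(path.centroid),
        "rotation": (path.bbox[2], path.bbox[1]),
        "opacity": tuple(path.centroid),
    }
    for b in obj.bindings:
        short, full = truncate_label(b.variable)
        if b.element in order:
            slice_items = slices[b.element]
            if slice_items:
                mid = slice_items[len(slice_items) // 2]
                if isinstance(mid, SymbolItem):
                    a = mid.center
                else:
                    pts = np.asarray(mid.points)
                    a = tuple(pts[len(pts) // 2])
            else:
                a = to_panel(path.centroid)
            anchors.append((short, full, a))
        else:
            anchors.append((short, full, to_panel(scalar_spots[b.element])))

    panel_h = TITLE_H + PANEL_CONTENT + 2 * PANEL_PAD
    bounds = (2.0, TITLE_H, PANEL_W - 2.0, panel_h - 2.0)
    labels, side = place_labels(anchors, bounds, font_size)
    if side:
        panel_h += (len(side)) * (font_size * 1.4) + 4.0
    return LegendPanel(obj.id, obj.name, panel_items, labels, side, panel_h)


def _element_markset(path, binding, seed, object_id):
    from .render import object_seed

    v = EXEMPLAR_VALUE
    el = binding.element
    if el == "fill_symbols":
        return enc.encode_fill_symbols(path, v, binding.static)
    if el == "mesh":
        return enc.encode_mesh(path, v, binding.static, seed=object_seed(seed, object_id))
    if el == "border_overlay":
        return enc.encode_border_overlay(path, v, binding.static)
    if el == "border_symbols":
        return enc.encode_border_symbols(path, v, binding.static)
    if el == "spikes":
        return enc.encode_spikes(path, v, binding.static)
    return enc.MarkSet()


def build_legend(template, font_size: float = _FONT) -> Scene:
    """Legend Scene: one panel per visible object with bindings, stacked vertically."""
    import warnings

    panels = []
    for obj in template.objects_in_z_order():
        if not obj.visible or not obj.bindings:
            continue
        panels.append(build_panel(template, obj, font_size))
    if not panels:
        warnings.warn("template has no bound visible objects; legend is empty", stacklevel=2)
        return Scene([], PANEL_W, 40.0, metadata={"legend": template.name})

    groups = []
    y = 0.0
    for p in panels:
        items = [TextItem(p.object_name, (PANEL_PAD / 2.0, TITLE_H - 5.0),
                          size=font_size + 1.0, bold=True)]
        items += p.exemplar_items
        for lb in p.labels:
            # leader line from the label toward its anchor when offset is large
            bx = lb.x + lb.w if lb.anchor[0] > lb.x + lb.w else lb.x
            by = lb.y + lb.h / 2.0
            dist = ((bx - lb.anchor[0]) ** 2 + (by - lb.anchor[1]) ** 2) ** 0.5
            if dist > 8.0:
                items.append(PathItem(np.array([[bx, by], list(lb.anchor)]), closed=False,
                                      fill=None, stroke=(120, 120, 120), stroke_width=0.5))
            items.append(TextItem(lb.text, (lb.x + 2.0, lb.y + lb.h - 3.0),
                                  size=font_size, title=lb.full))
        sy = TITLE_H + PANEL_CONTENT + 2 * PANEL_PAD
        for i, (short, full) in enumerate(p.side_list):
            items.append(TextItem(f"• {short}", (PANEL_PAD, sy + (i + 1) * font_size * 1.4),
                                  size=font_size, title=full))
        groups.append(MarkGroup(gid=f"legend-{p.object_id}", items=items,
                                translation=(0.0, y), scale=1.0))
        y += p.height + 6.0
    return Scene(groups, PANEL_W, y, metadata={"legend": template.name})
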