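"""Visual-element encoders: one operation per channel of a shape glyph.

Each encoder maps a normalized value ``v`` in [0, 1], plus the static
properties of the element, to either a scalar (dimensions, rotation, opacity,
colour) or a :class:`MarkSet` of concrete marks drawn on or in a
:class:`~glyphstack.geometry.ClosedPath`.

Count-based elements (fill symbols, border symbols, spikes, mesh) are exactly
empty at ``v = 0`` and monotone non-decreasing in ``v``. Dimension and opacity
encoders apply a small visibility floor so a zero-valued glyph part remains
identifiable rather than vanishing.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import DomainError
from .geometry import ClosedPath
from .palettes import get_palette

ELEMENTS = (
    "length", "width", "fill_gradient", "fill_symbols", "spikes",
    "border_overlay", "border_symbols", "mesh", "rotation", "opacity",
)

SYMBOLS = ("x_cross", "asterisk", "dash", "dot", "square", "wedge")

FILL_DIRECTIONS = ("left_to_right", "right_to_left", "top_to_bottom", "bottom_to_top")

MESH_ORIENTATIONS = ("vertical", "horizontal", "radial", "grid", "random")

#: visibility floor for the length/width channels
DIMENSION_FLOOR = 0.05
#: visibility floor for the opacity channel
OPACITY_FLOOR = 0.1
#: spike amplitude as a multiple of stroke size (static, so v means coverage)
SPIKE_AMPLITUDE = 3.0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _check_v(v: float) -> float:
    v = float(v)
    if not (0.0 <= v <= 1.0):
        raise DomainError(f"normalized value must lie in [0, 1], got {v}")
    return v


@dataclass(frozen=True)
class StaticProps:
    """Static styling consulted by the element an object binds.

    Only the fields relevant to the bound element are read; the rest are
    ignored. Colours are (r, g, b) byte triples; sizes are canvas units.
    """

    symbol: str = "dot"
    fill_direction: str = "left_to_right"
    mesh_orientation: str = "vertical"
    colour: tuple[int, int, int] = (0, 0, 0)
    colour_map: str = "Reds"
    stroke_size: float = 1.0
    symbol_size: float = 3.0
    density_max: int = 10

    def __post_init__(self):
        if self.symbol not in SYMBOLS:
            raise DomainError(f"unknown symbol '{self.symbol}'")
        if self.fill_direction not in FILL_DIRECTIONS:
            raise DomainError(f"unknown fill direction '{self.fill_direction}'")
        if self.mesh_orientation not in MESH_ORIENTATIONS:
            raise DomainError(f"unknown mesh orientation '{self.mesh_orientation}'")
        if self.density_max < 1:
            raise DomainError("density_max must be >= 1")
        if self.stroke_size <= 0 or self.symbol_size <= 0:
            raise DomainError("stroke_size and symbol_size must be positive")


@dataclass(frozen=True)
class ElementBinding:
    """Binds one data column to one visual element of an object."""

    element: str
    variable: str
    static: StaticProps = field(default_factory=StaticProps)

    def __post_init__(self):
        if self.element not in ELEMENTS:
            raise DomainError(f"unknown element '{self.element}'")


@dataclass(frozen=True)
class Mark:
    """One concrete mark: a placed symbol, a clipped segment, or a stroked subpath."""

    kind: str  # glyph_symbol | segment | subpath
    geometry: Any  # symbol: (x, y); segment: ((x1,y1),(x2,y2)); subpath: (m,2) array
    style: dict = field(default_factory=dict)


@dataclass
class MarkSet:
    marks: list[Mark] = field(default_factory=list)

    def __len__(self):
        return len(self.marks)

    def __iter__(self):
        return iter(self.marks)


# -- scalar channels -------------------------------------------------------

def encode_length(base_height: float, v: float) -> float:
    """Scaled dimension: ``base * (eps + (1 - eps) * v)`` with eps = 0.05."""
    if base_height <= 0:
        raise DomainError("base dimension must be positive")
    v = _check_v(v)
    return base_height * (DIMENSION_FLOOR + (1.0 - DIMENSION_FLOOR) * v)


#: width scales by the same affine law as length
encode_width = encode_length


def encode_rotation(v: float) -> float:
    """Rotation angle in degrees: the full turn [0, 360] mapped linearly."""
    return _check_v(v) * 360.0


def encode_opacity(v: float) -> float:
    """Alpha in [0.1, 1]: floor keeps fully transparent parts identifiable."""
    return OPACITY_FLOOR + (1.0 - OPACITY_FLOOR) * _check_v(v)


def encode_fill_gradient(v: float, colour_map) -> tuple[int, int, int]:
    """Colour at ``v`` along a sequential palette.

    ``colour_map`` is a palette name (see :mod:`glyphstack.palettes`) or an
    explicit anchor list of >= 2 RGB triples. Interpolation is piecewise
    linear in RGB between anchors with channels rounded to nearest integer.
    """
    v = _check_v(v)
    anchors = get_palette(colour_map) if isinstance(colour_map, str) else list(colour_map)
    if len(anchors) < 2:
        raise DomainError("colour map needs at least 2 anchor colours")
    pos = v * (len(anchors) - 1)
    i = min(int(math.floor(pos)), len(anchors) - 2)
    frac = pos - i
    a, b = anchors[i], anchors[i + 1]
    return tuple(_round_half_up(a[c] + (b[c] - a[c]) * frac) for c in range(3))


# -- area channels ---------------------------------------------------------

def fill_symbol_sites(path: ClosedPath, static: StaticProps) -> np.ndarray:
    """Candidate lattice sites for symbol filling, sorted by fill direction.

    A square lattice of pitch ``2 * symbol_size`` anchored half a pitch inside
    the bounding-box corner, clipped to the shape interior. Sites are ordered
    along the fill-direction axis, ties broken by the orthogonal axis, then by
    lattice index.
    """
    pitch = 2.0 * static.symbol_size
    xmin, ymin, xmax, ymax = path.bbox
    xs = np.arange(xmin + pitch / 2.0, xmax, pitch)
    ys = np.arange(ymin + pitch / 2.0, ymax, pitch)
    if len(xs) == 0 or len(ys) == 0:
        return np.empty((0, 2))
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel()])
    sites = sites[path.contains(sites)]
    if len(sites) == 0:
        return sites
    # y-down canvas: "top" is the minimum y
    axis, sign = {
        "left_to_right": (0, 1.0), "right_to_left": (0, -1.0),
        "top_to_bottom": (1, 1.0), "bottom_to_top": (1, -1.0),
    }[static.fill_direction]
    primary = sign * sites[:, axis]
    ortho = sites[:, 1 - axis]
    order = np.lexsort((np.arange(len(sites)), ortho, primary))
    return sites[order]


def encode_fill_symbols(path: ClosedPath, v: float, static: StaticProps) -> MarkSet:
    """Fill the interior with ``round(v * N)`` symbols along the fill direction."""
    v = _check_v(v)
    sites = fill_symbol_sites(path, static)
    n_sites = len(sites)
    if n_sites == 0:
        warnings.warn("symbol size leaves no lattice site inside the shape (degenerate fill)",
                      stacklevel=2)
        return MarkSet()
    k = _round_half_up(v * n_sites)
    style = {"symbol": static.symbol, "size": static.symbol_size, "colour": static.colour}
    return MarkSet([Mark("glyph_symbol", (float(x), float(y)), style) for x, y in sites[:k]])


def encode_mesh(path: ClosedPath, v: float, static: StaticProps, seed: int = 0) -> MarkSet:
    """Clipped guide lines; the line count ``round(v * density_max)`` encodes v.

    Orientations: ``vertical``/``horizontal`` lines equally spaced across the
    bounding box, ``grid`` both, ``radial`` rays through the centroid at equal
    angles, ``random`` lines through seeded-uniform interior points at
    seeded-uniform angles.
    """
    v = _check_v(v)
    n = _round_half_up(v * static.density_max)
    if n == 0:
        return MarkSet()
    xmin, ymin, xmax, ymax = path.bbox
    w, h = xmax - xmin, ymax - ymin
    pad = 0.05 * max(w, h) + 1.0
    style = {"colour": static.colour, "stroke_size": static.stroke_size}
    marks: list[Mark] = []

    def add_clipped(p1, p2):
        for a, b in path.clip_line(p1, p2):
            marks.append(Mark("segment", ((float(a[0]), float(a[1])),
                                          (float(b[0]), float(b[1]))), style))

    def verticals(count):
        for i in range(1, count + 1):
            x = xmin + i * w / (count + 1)
            add_clipped((x, ymin - pad), (x, ymax + pad))

    def horizontals(count):
        for i in range(1, count + 1):
            y = ymin + i * h / (count + 1)
            add_clipped((xmin - pad, y), (xmax + pad, y))

    orient = static.mesh_orientation
    if orient == "vertical":
        verticals(n)
    elif orient == "horizontal":
        horizontals(n)
    elif orient == "grid":
        verticals(n)
        horizontals(n)
    elif orient == "radial":
        c = path.centroid
        r = math.hypot(w, h) + pad
        for k in range(n):
            th = 2.0 * math.pi * k / n
            add_clipped(c, c + r * np.array([math.cos(th), math.sin(th)]))
    elif orient == "random":
        rng = np.random.default_rng(seed)
        r = math.hypot(w, h) + pad
        for _ in range(n):
            p = path.centroid
            for _try in range(100):
                cand = np.array([rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)])
                if path.contains(cand):
                    p = cand
                    break
            th = rng.uniform(0.0, math.pi)
            d = np.array([math.cos(th), math.sin(th)])
            add_clipped(p - r * d, p + r * d)
    return MarkSet(marks)


# -- outline channels ------------------------------------------------------

def encode_border_overlay(path: ClosedPath, v: float, static: StaticProps) -> MarkSet:
    """Stroke the first fraction ``v`` of the outline from t = 0."""
    v = _check_v(v)
    if v == 0.0:
        return MarkSet()
    pts = path.walk(0.0, v)
    style = {"colour": static.colour, "stroke_size": static.stroke_size}
    return MarkSet([Mark("subpath", pts, style)])


def encode_border_symbols(path: ClosedPath, v: float, static: StaticProps) -> MarkSet:
    """Symbols at arc-length spacing ``2 * symbol_size`` over the first fraction v.

    Emits ``floor(v * L / s)`` symbols at ``t = k * s / L``.
    """
    v = _check_v(v)
    s = 2.0 * static.symbol_size
    L = path.perimeter
    count = int(math.floor(v * L / s + 1e-9))
    style = {"symbol": static.symbol, "size": static.symbol_size, "colour": static.colour}
    marks = []
    for k in range(count):
        p, _ = path.point_at(min(k * s / L, 1.0))
        marks.append(Mark("glyph_symbol", (float(p[0]), float(p[1])), style))
    return MarkSet(marks)


def encode_spikes(path: ClosedPath, v: float, static: StaticProps) -> MarkSet:
    """Replace the first fraction v of the outline by a triangular zig-zag.

    ``round(v * density_max)`` spikes of fixed amplitude ``3 * stroke_size``
    point along the outward normal; each spike is one subpath mark.
    """
    v = _check_v(v)
    n = _round_half_up(v * static.density_max)
    if n == 0:
        return MarkSet()
    amp = SPIKE_AMPLITUDE * static.stroke_size
    style = {"colour": static.colour, "stroke_size": static.stroke_size}
    marks = []
    for k in range(n):
        t0 = k * v / n
        t1 = (k + 1) * v / n
        tm = 0.5 * (t0 + t1)
        p0, _ = path.point_at(t0)
        pm, nm = path.point_at(tm)
        p1, _ = path.point_at(min(t1, 1.0))
        apex = pm + amp * nm
        marks.append(Mark("subpath", np.array([p0, apex, p1]), style))
    return MarkSet(marks)
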