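"""Closed-shape primitives and geometric predicates.

Coordinates follow the screen/SVG convention: y grows downward, shapes are
defined centroid-centred in design units and placed on the canvas by a
:class:`Transform`. A :class:`ClosedPath` is an ordered polygon outline with
implicit closure; the arc-length parameter ``t`` in [0, 1] walks the outline
starting at vertex 0.

Containment uses the even-odd rule with boundary points counting as inside,
so self-intersecting one-stroke paths behave like they do in a graphics
editor, and symbol counts on lattice-aligned grids are stable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, InvalidDimensionError, InvalidShapeError

#: vertex budget used when polygonizing circles and ellipses
CIRCLE_VERTICES = 128

_EPS = 1e-9


@dataclass(frozen=True)
class ClosedPath:
    """An ordered closed polygon outline.

    ``vertices`` is an (n, 2) float array; the edge from the last vertex back
    to the first is implicit. ``smoothing`` records whether the vertex list
    was produced by Catmull-Rom subdivision of a hand-drawn stroke.
    """

    vertices: np.ndarray
    smoothing: str = "none"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidShapeError(f"a closed path needs at least 3 vertices, got shape {v.shape}")
        if np.allclose(v[0], v[-1], atol=_EPS):
            v = v[:-1]
            if v.shape[0] < 3:
                raise InvalidShapeError("fewer than 3 distinct vertices after closing the stroke")
        object.__setattr__(self, "vertices", v)
        if self.perimeter <= 0:
            raise InvalidShapeError("degenerate path: zero perimeter")
        # collinear vertex sets enclose nothing; self-intersecting outlines
        # (whose shoelace sum may cancel) are fine under even-odd semantics
        rel = v - v[0]
        d = rel[np.argmax(np.linalg.norm(rel, axis=1))]
        if np.abs(d[0] * rel[:, 1] - d[1] * rel[:, 0]).max() < _EPS * max(1.0, self.perimeter):
            raise InvalidShapeError("degenerate path: all vertices are collinear")

    # -- basic measures -------------------------------------------------

    @property
    def n(self) -> int:
        return self.vertices.shape[0]

    @property
    def edges(self) -> np.ndarray:
        """(n, 2, 2) array of [start, end] per edge, closing edge last."""
        v = self.vertices
        return np.stack([v, np.roll(v, -1, axis=0)], axis=1)

    @property
    def edge_lengths(self) -> np.ndarray:
        v = self.vertices
        return np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)

    @property
    def perimeter(self) -> float:
        return float(self.edge_lengths.sum())

    @property
    def signed_area(self) -> float:
        """Shoelace area; sign encodes vertex orientation (y-down axes)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area)

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid (falls back to vertex mean for near-degenerate rings)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * cross.sum()
        if abs(a) < _EPS:
            return self.vertices.mean(axis=0)
        cx = np.sum((x + xn) * cross) / (6.0 * a)
        cy = np.sum((y + yn) * cross) / (6.0 * a)
        return np.array([cx, cy])

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        v = self.vertices
        return (float(v[:, 0].min()), float(v[:, 1].min()),
                float(v[:, 0].max()), float(v[:, 1].max()))

    # -- arc-length walk ------------------------------------------------

    @property
    def _cumlen(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.edge_lengths)])

    def point_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Point on the outline at arc-length fraction ``t`` plus the outward unit normal.

        ``t`` = 0 is vertex 0; ``t`` = 1 wraps back to it.
        """
        if not (-_EPS <= t <= 1 + _EPS):
            raise DomainError(f"arc-length fraction must lie in [0, 1], got {t}")
        t = min(max(t, 0.0), 1.0)
        s = t * self.perimeter
        cum = self._cumlen
        if t >= 1.0:
            i, local = self.n - 1, self.edge_lengths[self.n - 1]
        else:
            i = int(np.searchsorted(cum, s, side="right") - 1)
            i = min(i, self.n - 1)
            local = s - cum[i]
        a = self.vertices[i]
        b = self.vertices[(i + 1) % self.n]
        d = b - a
        elen = self.edge_lengths[i]
        u = d / elen if elen > 0 else np.array([1.0, 0.0])
        point = a + u * local
        # outward normal: rotate the edge direction by 90 deg toward the
        # outside; orientation is read off the signed area (y-down axes).
        if self.signed_area > 0:
            normal = np.array([u[1], -u[0]])
        else:
            normal = np.array([-u[1], u[0]])
        return point, normal

    def walk(self, t0: float, t1: float) -> np.ndarray:
        """Polyline along the outline from fraction ``t0`` to ``t1`` (t0 <= t1 <= 1).

        Includes every intermediate vertex, so the polyline length is exactly
        ``(t1 - t0) * perimeter``.
        """
        if t1 < t0:
            raise DomainError("walk requires t0 <= t1")
        p0, _ = self.point_at(t0)
        pts = [p0]
        s0, s1 = t0 * self.perimeter, t1 * self.perimeter
        cum = self._cumlen
        for i in range(self.n):
            s = cum[i + 1]
            if s0 < s < s1:
                pts.append(self.vertices[(i + 1) % self.n])
        p1, _ = self.point_at(t1)
        pts.append(p1)
        return np.array(pts)

    # -- predicates ------------------------------------------------------

    def contains(self, points) -> np.ndarray | bool:
        """Even-odd containment test; boundary points count as inside.

        Accepts a single (x, y) point or an (m, 2) array; returns bool or a
        boolean array accordingly.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inside = _even_odd(self.vertices, pts)
        on_edge = _on_boundary(self.vertices, pts)
        result = inside | on_edge
        if np.asarray(points).ndim == 1:
            return bool(result[0])
        return result

    def clip_line(self, p1, p2, infinite: bool = False) -> list[tuple[np.ndarray, np.ndarray]]:
        """Interior portions of the segment (or infinite line through) p1-p2.

        Returns maximal segments ordered along the p1→p2 direction, consistent
        with the even-odd interior of :meth:`contains`.
        """
        p1 = np.asarray(p1, dtype=float)
        p2 = np.asarray(p2, dtype=float)
        d = p2 - p1
        dlen = np.linalg.norm(d)
        if dlen < _EPS:
            return []
        # candidate parameters along the line at every edge crossing
        params: list[float] = []
        if infinite:
            xmin, ymin, xmax, ymax = self.bbox
            corners = np.array([[xmin, ymin], [xmin, ymax], [xmax, ymin], [xmax, ymax]])
            proj = (corners - p1) @ d / (dlen * dlen)
            lo, hi = float(proj.min()) - 1.0, float(proj.max()) + 1.0
        else:
            lo, hi = 0.0, 1.0
        for a, b in self.edges:
            t = _line_edge_param(p1, d, a, b, infinite, lo, hi)
            params.extend(t)
        params = [t for t in params if lo - 1e-12 <= t <= hi + 1e-12]
        breaks = sorted({lo, hi} | set(params))
        # dedupe near-coincident breakpoints
        merged: list[float] = []
        for t in breaks:
            if not merged or t - merged[-1] > 1e-12 * max(1.0, abs(hi - lo)):
                merged.append(t)
        segments: list[tuple[np.ndarray, np.ndarray]] = []
        for t0, t1 in zip(merged[:-1], merged[1:]):
            tm = 0.5 * (t0 + t1)
            if self.contains(p1 + tm * d):
                a, b = p1 + t0 * d, p1 + t1 * d
                if segments and np.allclose(segments[-1][1], a, atol=1e-9):
                    segments[-1] = (segments[-1][0], b)  # merge contiguous
                else:
                    segments.append((a, b))
        return [s for s in segments if np.linalg.norm(s[1] - s[0]) > 1e-9]


def _even_odd(vertices: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Vectorized even-odd ray cast (horizontal ray toward +x)."""
    x, y = pts[:, 0], pts[:, 1]
    v1 = vertices
    v2 = np.roll(vertices, -1, axis=0)
    inside = np.zeros(len(pts), dtype=bool)
    for (x1, y1), (x2, y2) in zip(v1, v2):
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        hit = crosses & (x < xint)
        inside ^= hit
    return inside


def _on_boundary(vertices: np.ndarray, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    v1 = vertices
    v2 = np.roll(vertices, -1, axis=0)
    out = np.zeros(len(pts), dtype=bool)
    for a, b in zip(v1, v2):
        d = b - a
        ll = d @ d
        if ll < _EPS:
            continue
        t = np.clip(((pts - a) @ d) / ll, 0.0, 1.0)
        proj = a + t[:, None] * d
        out |= np.linalg.norm(pts - proj, axis=1) <= tol
    return out


def _line_edge_param(p, d, a, b, infinite, lo, hi) -> list[float]:
    """Intersection parameter(s) of line p + t*d with edge a-b."""
    e = b - a
    denom = d[0] * e[1] - d[1] * e[0]
    if abs(denom) < 1e-14:
        # parallel; collinear overlap contributes the projected endpoints
        cross = (a - p)[0] * d[1] - (a - p)[1] * d[0]
        if abs(cross) < 1e-12 * max(1.0, np.linalg.norm(d)):
            dd = d @ d
            return [float(((a - p) @ d) / dd), float(((b - p) @ d) / dd)]
        return []
    t = ((a - p)[0] * e[1] - (a - p)[1] * e[0]) / denom
    u = ((a - p)[0] * d[1] - (a - p)[1] * d[0]) / denom
    if -1e-12 <= u <= 1 + 1e-12:
        return [float(t)]
    return []


@dataclass(frozen=True)
class Transform:
    """Placement of a shape: scale about its centroid, rotate, then translate."""

    translation: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0
    scale_x: float = 1.0
    scale_y: float = 1.0

    def __post_init__(self):
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise InvalidDimensionError(
                f"scale factors must be strictly positive, got ({self.scale_x}, {self.scale_y})")

    def apply(self, path: ClosedPath) -> ClosedPath:
        c = path.centroid
        pts = (path.vertices - c) * np.array([self.scale_x, self.scale_y])
        r = math.radians(self.rotation_deg)
        rot = np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])
        pts = pts @ rot.T
        pts = pts + c + np.asarray(self.translation, dtype=float)
        return replace(path, vertices=pts)

    def inverse_apply(self, path: ClosedPath) -> ClosedPath:
        # centroid of the transformed path is c + translation (affine maps
        # move the area centroid with them)
        c = path.centroid - np.asarray(self.translation, dtype=float)
        pts = path.vertices - c - np.asarray(self.translation, dtype=float)
        r = math.radians(-self.rotation_deg)
        rot = np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])
        pts = pts @ rot.T
        pts = pts / np.array([self.scale_x, self.scale_y])
        return replace(path, vertices=pts + c)


# -- shape construction ---------------------------------------------------

def _regular_ellipse(rx: float, ry: float, n: int = CIRCLE_VERTICES) -> np.ndarray:
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([rx * np.cos(th), ry * np.sin(th)])


def catmull_rom(points: np.ndarray, samples_per_segment: int = 8) -> np.ndarray:
    """Closed uniform Catmull-Rom subdivision of a vertex loop."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    out = []
    for i in range(n):
        p0, p1, p2, p3 = pts[(i - 1) % n], pts[i], pts[(i + 1) % n], pts[(i + 2) % n]
        for j in range(samples_per_segment):
            t = j / samples_per_segment
            t2, t3 = t * t, t * t * t
            out.append(0.5 * ((2 * p1) + (-p0 + p2) * t
                              + (2 * p0 - 5 * p1 + 4 * p2 - p3) * t2
                              + (-p0 + 3 * p1 - 3 * p2 + p3) * t3))
    return np.array(out)


def make_shape(kind: str, **params) -> ClosedPath:
    """Build a centroid-centred closed path of the requested kind.

    Kinds and their parameters:

    - ``circle``: ``r``
    - ``ellipse``: ``rx``, ``ry``
    - ``square``: ``side``
    - ``rectangle``: ``width``, ``height``
    - ``custom``: ``vertices`` (>= 3 points, one-stroke outline, auto-closed),
      optional ``smooth`` (Catmull-Rom subdivision, default off)

    Circles and ellipses are polygonized at ``CIRCLE_VERTICES`` vertices.
    """
    def _dim(name):
        val = params.get(name)
        if val is None:
            raise InvalidDimensionError(f"{kind} requires dimension '{name}'")
        val = float(val)
        if val <= 0:
            raise InvalidDimensionError(f"dimension '{name}' must be positive, got {val}")
        return val

    if kind == "circle":
        r = _dim("r")
        return ClosedPath(_regular_ellipse(r, r))
    if kind == "ellipse":
        return ClosedPath(_regular_ellipse(_dim("rx"), _dim("ry")))
    if kind == "square":
        h = _dim("side") / 2.0
        return ClosedPath(np.array([[-h, -h], [h, -h], [h, h], [-h, h]]))
    if kind == "rectangle":
        w, h = _dim("width") / 2.0, _dim("height") / 2.0
        return ClosedPath(np.array([[-w, -h], [w, -h], [w, h], [-w, h]]))
    if kind == "custom":
        verts = params.get("vertices")
        if verts is None or len(verts) < 3:
            raise InvalidShapeError("custom shape needs at least 3 vertices")
        pts = np.asarray(verts, dtype=float)
        smoothing = "none"
        if params.get("smooth", False):
            pts = catmull_rom(pts)
            smoothing = "smoothed"
        path = ClosedPath(pts, smoothing=smoothing)
        return replace(path, vertices=path.vertices - path.centroid)
    raise InvalidShapeError(f"unknown shape kind '{kind}'")
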