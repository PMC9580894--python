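"""Visual-element encoders: scalar laws, mark counts, ordering, determinism."""
import numpy as np
import pytest

from glyphstack import encodings as enc
from glyphstack.errors import ConfigurationError, DomainError
from glyphstack.geometry import ClosedPath, make_shape


def seg_length(mark):
    a, b = np.asarray(mark.geometry[0]), np.asarray(mark.geometry[1])
    return float(np.linalg.norm(b - a))


def polyline_length(mark):
    pts = np.asarray(mark.geometry)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


class TestScalarChannels:
    @pytest.mark.parametrize("base,v,expected", [
        (100.0, 1.0, 100.0),
        (100.0, 0.0, 5.0),    # visibility floor eps = 0.05
        (80.0, 0.5, 42.0),    # 80 * (0.05 + 0.95 * 0.5)
    ])
    def test_length_affine_law(self, base, v, expected):
        assert enc.encode_length(base, v) == pytest.approx(expected)
        assert enc.encode_width(base, v) == pytest.approx(expected)

    @pytest.mark.parametrize("v,expected", [(1.0, 1.0), (0.0, 0.1), (0.5, 0.55)])
    def test_opacity_floor(self, v, expected):
        assert enc.encode_opacity(v) == pytest.approx(expected)

    @pytest.mark.parametrize("v,deg", [(0.0, 0.0), (0.5, 180.0), (1.0, 360.0)])
    def test_rotation_full_turn(self, v, deg):
        assert enc.encode_rotation(v) == pytest.approx(deg)

    @pytest.mark.parametrize("fn", [
        lambda v: enc.encode_length(10.0, v),
        enc.encode_opacity,
        enc.encode_rotation,
    ])
    @pytest.mark.parametrize("v", [-0.01, 1.01])
    def test_out_of_domain_rejected(self, fn, v):
        with pytest.raises(DomainError):
            fn(v)


class TestFillGradient:
    def test_endpoints_hit_anchors(self):
        from glyphstack.palettes import SEQUENTIAL
        for name, anchors in SEQUENTIAL.items():
            assert enc.encode_fill_gradient(0.0, name) == anchors[0]
            assert enc.encode_fill_gradient(1.0, name) == anchors[-1]

    def test_midpoint_of_two_anchor_map_is_mid_grey(self):
        mid = enc.encode_fill_gradient(0.5, [(0, 0, 0), (255, 255, 255)])
        assert mid == (128, 128, 128)  # 127.5 rounded up

    def test_unknown_palette_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            enc.encode_fill_gradient(0.5, "NotAPalette")

    def test_piecewise_linear_between_anchors(self):
        anchors = [(0, 0, 0), (100, 50, 200), (255, 255, 255)]
        # v=0.25 sits halfway along the first segment
        assert enc.encode_fill_gradient(0.25, anchors) == (50, 25, 100)


class TestFillSymbols:
    @pytest.fixture
    def square(self):
        # unit square with a 10x10 interior lattice at symbol_size 0.05
        return ClosedPath(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))

    @pytest.fixture
    def props(self):
        return enc.StaticProps(symbol="x_cross", symbol_size=0.05)

    def test_lattice_size(self, square, props):
        assert len(enc.fill_symbol_sites(square, props)) == 100

    def test_zero_and_full(self, square, props):
        assert len(enc.encode_fill_symbols(square, 0.0, props)) == 0
        assert len(enc.encode_fill_symbols(square, 1.0, props)) == 100

    def test_half_fill_left_to_right(self, square, props):
        ms = enc.encode_fill_symbols(square, 0.5, props)
        assert len(ms) == 50
        assert all(m.geometry[0] < 0.5 for m in ms)

    @pytest.mark.parametrize("direction,axis,sign", [
        ("left_to_right", 0, 1), ("right_to_left", 0, -1),
        ("top_to_bottom", 1, 1), ("bottom_to_top", 1, -1),
    ])
    def test_occupied_precede_unoccupied_along_direction(self, square, direction, axis, sign):
        props = enc.StaticProps(fill_direction=direction, symbol_size=0.05)
        sites = enc.fill_symbol_sites(square, props)
        ms = enc.encode_fill_symbols(square, 0.37, props)
        occupied = {tuple(m.geometry) for m in ms}
        values = [sign * s[axis] for s in sites]
        flags = [tuple(s) in occupied for s in sites]
        # along the declared direction, every occupied site precedes every empty one
        last_occupied = max((v for v, f in zip(values, flags) if f), default=-np.inf)
        first_empty = min((v for v, f in zip(values, flags) if not f), default=np.inf)
        assert last_occupied <= first_empty

    def test_occupancy_fraction_close_to_v(self, square, props):
        n = 100
        for v in np.linspace(0, 1, 23):
            k = len(enc.encode_fill_symbols(square, float(v), props))
            assert abs(k / n - v) <= 1 / (2 * n) + 1e-12

    def test_degenerate_fill_warns_and_is_empty(self):
        tiny = make_shape("square", side=0.01)
        props = enc.StaticProps(symbol_size=5.0)
        with pytest.warns(UserWarning, match="degenerate"):
            ms = enc.encode_fill_symbols(tiny, 0.8, props)
        assert len(ms) == 0


class TestBorderSymbols:
    def test_counts_on_unit_square(self, unit_square):
        props = enc.StaticProps(symbol_size=0.25)  # spacing s = 0.5, L = 4
        assert len(enc.encode_border_symbols(unit_square, 0.0, props)) == 0
        assert len(enc.encode_border_symbols(unit_square, 1.0, props)) == 8
        ms = enc.encode_border_symbols(unit_square, 0.25, props)
        assert len(ms) == 2
        # both symbols sit on the first edge (y = 0, x in [0, 1])
        for m in ms:
            assert m.geometry[1] == pytest.approx(0.0)
            assert 0.0 <= m.geometry[0] <= 1.0

    def test_symbols_lie_on_outline(self, circle_path):
        props = enc.StaticProps(symbol_size=0.1)
        for m in enc.encode_border_symbols(circle_path, 0.8, props):
            # every centre has |p| == r for a unit circle polygon (within facet sag)
            assert np.linalg.norm(m.geometry) == pytest.approx(1.0, abs=2e-3)


class TestBorderOverlay:
    def test_full_and_empty(self, unit_square):
        props = enc.StaticProps()
        assert len(enc.encode_border_overlay(unit_square, 0.0, props)) == 0
        full = enc.encode_border_overlay(unit_square, 1.0, props)
        assert polyline_length(full.marks[0]) == pytest.approx(4.0)

    def test_quarter_is_first_edge(self, unit_square):
        ms = enc.encode_border_overlay(unit_square, 0.25, props := enc.StaticProps())
        pts = np.asarray(ms.marks[0].geometry)
        assert pts[0] == pytest.approx([0.0, 0.0])
        assert pts[-1] == pytest.approx([1.0, 0.0])

    def test_length_proportional_to_v(self, fixture_shape):
        props = enc.StaticProps()
        for v in np.linspace(0.05, 1.0, 17):
            ms = enc.encode_border_overlay(fixture_shape, float(v), props)
            assert polyline_length(ms.marks[0]) == pytest.approx(
                v * fixture_shape.perimeter, rel=1e-6)


class TestSpikes:
    def test_counts(self, unit_square):
        props = enc.StaticProps(density_max=12)
        assert len(enc.encode_spikes(unit_square, 0.0, props)) == 0
        assert len(enc.encode_spikes(unit_square, 1.0, props)) == 12
        assert len(enc.encode_spikes(unit_square, 0.5, props)) == 6

    def test_half_coverage_confined_to_first_half(self, unit_square):
        props = enc.StaticProps(density_max=12, stroke_size=0.01)
        ms = enc.encode_spikes(unit_square, 0.5, props)
        # bases of all spikes lie within the first half of the perimeter:
        # edges (0,0)->(1,0)->(1,1), i.e. y=0 or x=1
        for m in ms:
            base0, apex, base1 = np.asarray(m.geometry)
            for p in (base0, base1):
                assert p[1] == pytest.approx(0.0, abs=1e-9) or p[0] == pytest.approx(1.0, abs=1e-9)

    def test_amplitude_is_three_strokes_along_normal(self, unit_square):
        props = enc.StaticProps(density_max=4, stroke_size=2.0)
        ms = enc.encode_spikes(unit_square, 1.0, props)
        base0, apex, base1 = np.asarray(ms.marks[0].geometry)
        mid = 0.5 * (base0 + base1)
        assert np.linalg.norm(apex - mid) == pytest.approx(6.0, rel=1e-6)


class TestMesh:
    def test_zero_is_empty(self, unit_square):
        assert len(enc.encode_mesh(unit_square, 0.0, enc.StaticProps())) == 0

    def test_vertical_full_density_on_square(self, unit_square):
        props = enc.StaticProps(mesh_orientation="vertical", density_max=10)
        ms = enc.encode_mesh(unit_square, 1.0, props)
        assert len(ms) == 10
        for m in ms:
            assert seg_length(m) == pytest.approx(1.0)

    def test_grid_half_density(self, unit_square):
        props = enc.StaticProps(mesh_orientation="grid", density_max=10)
        ms = enc.encode_mesh(unit_square, 0.5, props)
        assert len(ms) == 10  # 5 vertical + 5 horizontal
        horiz = sum(1 for m in ms if m.geometry[0][1] == pytest.approx(m.geometry[1][1]))
        assert horiz == 5

    def test_radial_count_on_convex_shape(self, circle_path):
        props = enc.StaticProps(mesh_orientation="radial", density_max=8)
        ms = enc.encode_mesh(circle_path, 1.0, props)
        assert len(ms) == 8

    def test_random_mesh_is_seed_deterministic(self, circle_path):
        props = enc.StaticProps(mesh_orientation="random", density_max=7)
        a = enc.encode_mesh(circle_path, 1.0, props, seed=42)
        b = enc.encode_mesh(circle_path, 1.0, props, seed=42)
        c = enc.encode_mesh(circle_path, 1.0, props, seed=43)
        assert [m.geometry for m in a] == [m.geometry for m in b]
        assert [m.geometry for m in a] != [m.geometry for m in c]

    def test_segments_lie_inside(self, l_polygon):
        props = enc.StaticProps(mesh_orientation="grid", density_max=9)
        for m in enc.encode_mesh(l_polygon, 1.0, props):
            a, b = np.asarray(m.geometry[0]), np.asarray(m.geometry[1])
            assert l_polygon.contains(0.5 * (a + b))


@pytest.mark.parametrize("encoder,counter", [
    (lambda p, v: enc.encode_fill_symbols(p, v, enc.StaticProps(symbol_size=0.05)), len),
    (lambda p, v: enc.encode_border_symbols(p, v, enc.StaticProps(symbol_size=0.1)), len),
    (lambda p, v: enc.encode_spikes(p, v, enc.StaticProps(density_max=15)), len),
    (lambda p, v: enc.encode_mesh(p, v, enc.StaticProps(density_max=15)), len),
])
def test_count_channels_monotone_and_zero_at_origin(unit_square, encoder, counter):
    counts = [counter(encoder(unit_square, float(v))) for v in np.linspace(0, 1, 41)]
    assert counts[0] == 0
    assert all(a <= b for a, b in zip(counts, counts[1:]))


def test_marks_stay_within_padded_bbox(fixture_shape):
    """Every emitted mark lies inside the owner's bbox grown by its reach."""
    props = enc.StaticProps(symbol_size=0.2, stroke_size=0.5, density_max=10,
                            mesh_orientation="grid")
    xmin, ymin, xmax, ymax = fixture_shape.bbox
    pad = max(props.symbol_size, enc.SPIKE_AMPLITUDE * props.stroke_size) + 1e-9

    def inside(p):
        return (xmin - pad <= p[0] <= xmax + pad) and (ymin - pad <= p[1] <= ymax + pad)

    for ms in (enc.encode_fill_symbols(fixture_shape, 0.8, props),
               enc.encode_border_symbols(fixture_shape, 0.8, props),
               enc.encode_mesh(fixture_shape, 0.8, props),
               enc.encode_spikes(fixture_shape, 0.8, props),
               enc.encode_border_overlay(fixture_shape, 0.8, props)):
        for m in ms:
            pts = np.atleast_2d(np.asarray(m.geometry, dtype=float))
            assert all(inside(p) for p in pts)
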