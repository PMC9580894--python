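# Methods

## Scope and model

`glyphstack` renders *composite shape glyphs*: one small figure per table row,
assembled from an ordered stack of closed shapes whose visual elements encode
normalized variables. The package is headless — templates are JSON documents
and figures are files — and deliberately deterministic: a (template, table,
page, seed) tuple always produces byte-identical SVG.

## Geometry

Shapes are closed polygons in a y-down canvas coordinate system (SVG/screen
convention), defined centroid-centred and placed by a transform
(scale-about-centroid, rotate, translate). Circles and ellipses are
polygonized at 128 vertices — the shoelace area of the 128-gon is within 0.05%
of the true disc, well under rendering resolution, while keeping all geometric
predicates exact polygon operations. Custom one-stroke outlines are
auto-closed (last vertex joins the first) and may optionally be smoothed by
closed uniform Catmull-Rom subdivision (8 samples per segment, off by
default; how a drawing canvas would smooth strokes is an open choice, so the
raw polygon is the default truth).

The arc-length parameter t ∈ [0, 1] walks the outline from vertex 0; walks
include intermediate vertices so a partial outline's polyline length is
exactly t·perimeter. Outward normals are read off edge orientation via the
signed area.

Containment uses the even-odd rule with boundary points counting as inside.
Even-odd was chosen because hand-drawn one-stroke outlines may self-intersect
and graphics editors fill them even-odd; boundary-inclusive makes symbol
counts stable when lattice sites fall exactly on edges of axis-aligned
shapes. Line clipping finds all edge-crossing parameters along the line,
splits at them, and keeps the sub-intervals whose midpoints are interior —
consistent with `contains` by construction, including for self-intersecting
outlines where a polygon-clipping library would reject the ring.

## Element encodings

All encoders take v ∈ [0, 1] (out-of-range raises; a missing value renders at
the v = 0 floor with a warning rather than dropping the row).

- **length/width**: dimension factor ε + (1 − ε)·v with ε = 0.05. The floor
  keeps zero-valued parts visible and identifiable in a figure.
- **opacity**: 0.1 + 0.9·v, same rationale.
- **rotation**: v·360° — the only parameter-free choice of range.
- **fill gradient**: piecewise-linear RGB interpolation between the 9 anchor
  colours of a named ColorBrewer sequential palette (channels rounded to
  nearest integer). Perceptually uniform interpolation is a non-goal.
- **fill symbols**: candidate sites are a square lattice of pitch
  2·symbol_size (preventing symbol overlap) anchored half a pitch inside the
  bounding-box corner and clipped to the interior; sites are ordered along the
  fill direction, ties broken by the orthogonal axis then lattice index, and
  round(v·N) sites are emitted. Occupied sites therefore always precede empty
  ones along the declared direction.
- **border symbols**: arc-length spacing s = 2·symbol_size; floor(v·L/s)
  symbols at t = k·s/L cover the first fraction v of the outline.
- **border overlay**: a stroked subpath from t = 0 to t = v.
- **spikes**: round(v·density_max) triangular spikes replace the first
  fraction v of the outline, with fixed amplitude 3·stroke_size along the
  outward normal. Amplitude is static so that v has a single meaning
  (coverage); spike count and extent grow together.
- **mesh**: n = round(v·density_max) guide lines per orientation (grid draws
  n vertical + n horizontal), each clipped to the shape interior. The random
  orientation draws lines through seeded-uniform interior points at
  seeded-uniform angles; the seed is derived stably from the template seed and
  the object id, because users are known to over-interpret random-looking
  marks — a saved project must re-render identically.

Counts use half-up rounding (floor(x + 0.5)): deterministic, monotone in v,
and matching the documented worked counts, unlike banker's rounding.

## Normalization

Min–max scaling per column; linked groups pool min/max over all members so
within-group ratios survive (exactly, whenever the pooled minimum is 0).
Detection in `auto` mode deems a column (or a whole linked group) already
normalized iff all its finite values lie in [0, 1]; `force` always rescales,
`skip` never does (values outside [0, 1] are clipped with a warning).
Constant columns map to 0.5 — min = max makes the scaling undefined and a
neutral mid-value renders an informative glyph where an error would lose the
whole row. Per-column (min, max, group) provenance is kept so original units
can be reconstructed (x = min + v·(max − min), exact to 1e-9) for legend
annotation. NaNs propagate with a warning and render at the element floor.

## Templates

The JSON project schema is this package's own (versioned via
`format_version`); no compatibility with any other tool's export format is
claimed. Validation is collect-all: a document with five problems reports all
five, each with a path to the field. Object ids are unique; z order is kept a
total order 0…n−1 (ties broken by id) so layer reordering is a
neighbour swap and rendering order is well defined. Duplication produces
`<id>-copy`, `<id>-copy2`, … deterministically, on top of the stack, with
bindings copied verbatim.

Two bundled designs double as integration fixtures: `wound` (well square:
colour ← cell area, grid mesh ← cell number; inner rectangle: height ← wound
area change) and `multiplexed-cell` (context square mesh ← local cell
density; three stacked cell outlines with border symbols ← pAKT, p4EBP1, pS6;
x-symbol cytosol filling ← CAV1; gradient-coloured Golgi and centrosome
circles ← GM130, PCNT; nucleus circle with colour ← YAP, border dots ← NUPS,
dot filling ← PCNA — ten bound variables in total, placed by positional
mapping on the embedding coordinates).

## Rendering and layout

Within an object, paint order is: base shape (gradient colour and opacity
applied), area marks (fill symbols, mesh), then outline marks (overlay,
border symbols, spikes) — outline marks are never buried. Objects paint in z
order. Each glyph group gets a single uniform scale so the template's
design-space bounding box (padded by the largest mark reach) fits the
configured glyph extent; aspect ratio is preserved.

Grid layout sorts stably by the optional sort variable, slices the page, and
tiles row-major on a near-square grid (the grid shape comes from page_size so
pitch is constant across pages). Positional layout scales both axis columns
linearly to the canvas with a half-glyph margin; both axes map
ascending-to-ascending in canvas coordinates, a constant axis maps to the
canvas midpoint, and overlapping glyphs draw in row order (scatter
semantics, no collision avoidance).

SVG output uses fixed attribute order and fixed 3-decimal float formatting so
identical inputs give identical bytes. PNG is rasterized from the same scene
tree with Pillow at the requested dpi (96 dpi = 1 px per canvas unit); text
metrics differ slightly from SVG renderers, which is cosmetic only.

## Legend

One panel per visible object with at least one binding, stacked vertically;
the object is drawn alone with every bound value at 0.7 — high enough that
count-based elements show several marks. Panel magnification is capped at 3×
so small objects do not balloon. Each binding gets one label anchored at a
representative mark (the middle mark of its mark set, or a characteristic
point of the shape for scalar channels), placed by a greedy search over 8
compass directions (east first) at increasing radii; the first candidate
whose box stays inside the panel and overlaps no placed box wins, with a
leader line when the offset is large. Labels that cannot be placed are listed
under the panel — never dropped. Greedy placement was chosen over global
optimization: deterministic, fast, and adequate at legend scale. Variable
names longer than 18 characters are truncated with an ellipsis; the full name
is emitted as an SVG `<title>` element (the static-file equivalent of a hover
tooltip).

## Synthetic fixtures

`generate_fixture` emulates the *shape* of two study designs, not their
measured values. `wound` draws per-gene scratch-assay summaries (wound-area
change as a fraction of the 0 h wound, uniform on [0.05, 1]; cells per well
uniform on [200, 2500]; mean cell area uniform on [300, 3200] µm²) with gene
labels from a small knockdown panel. `multiplexed` draws per-cluster means of
ten markers (uniform on [0.05, 2.5] in scaled-intensity units) plus 2-D
embedding coordinates uniform on [−6, 6]. Real data have correlated markers,
heavy-tailed intensities and non-uniform cluster geometry; passing tests
therefore demonstrate the *pipeline contracts* (normalization laws, mark
counts, determinism, layout monotonicity), not statistical properties of any
real screen. All generation is seeded and byte-reproducible.

## Numerical choices and limitations

- Tolerances: arc-length positions exact to 1e-9; overlay length to 1e-6
  relative; provenance inversion to 1e-9; circle-area tests use the analytic
  n-gon band rather than π itself.
- Geometry robustness: clip-line breakpoints are deduplicated at 1e-12
  relative; boundary containment tolerance is 1e-9. Degenerate inputs
  (collinear vertex sets, zero perimeter) are rejected at construction.
- Property-suite problem sizes: 1,000 random (shape, v) pairs across five
  fixture shapes; dense oracles use 2,000–10,000 sample points per shape.
- True Bézier/arc geometry, boolean shape algebra, collision-avoiding layout,
  PDF export and interactive (hover/zoom) output are out of scope. Very large
  tables are handled by pagination at display level only, not streamed I/O.
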