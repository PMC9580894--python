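# glyphstack

Composite shape glyphs for multivariate tables from quantitative microscopy
and other biomedical assays.

Bar charts, heat maps and embedding plots strip away the structural nature of
image-derived data: a well is a rectangle with a wound in it, a cell is an
outline with a nucleus, organelles and a signalling periphery. `glyphstack`
lets you describe a biological structure as a *template* — an ordered stack of
shaped objects — and bind each table column to a visual element of one object.
Rendering then draws one composite glyph per table row, so relationships
between variables can be read off the picture (a dense mesh *and* a pale well
colour means many small cells) instead of being reassembled mentally from a
heat map.

## The model

Every bound variable is first min–max normalized to v ∈ [0, 1],

    v = (x − min) / (max − min),

where the min/max are taken per column, or pooled over a *linked group* of
columns that share a physical scale. Linking preserves relative magnitude: if
the longest cell is 100 px and its width 60 px, a linked {length, width} group
scales them to 1.0 and 0.6, while independent scaling would map both to 1.0
and destroy the aspect ratio.

Each object of a template exposes ten visual elements; each can carry one
variable:

| element | encoding of v |
| --- | --- |
| length / width | dimension scaled by ε + (1 − ε)·v, ε = 0.05 |
| fill gradient | colour at v along a ColorBrewer sequential palette |
| fill symbols | round(v·N) of the N interior lattice sites occupied, filling along a chosen direction |
| border symbols | symbols covering the first fraction v of the outline at fixed arc-length spacing |
| border overlay | a stroke over the first fraction v of the outline |
| spikes | round(v·density) outward triangular spikes over the first fraction v of the outline |
| mesh | round(v·density) clipped guide lines (vertical, horizontal, grid, radial or seeded-random) |
| rotation | v·360° about the object centroid |
| opacity | 0.1 + 0.9·v |

Count-based elements are exactly empty at v = 0 and monotone in v; dimensions
and opacity keep small visibility floors so zero-valued parts remain
identifiable. Scenes are laid out on a grid with pagination and optional
sorting, or by *positional mapping* (two columns become canvas coordinates).
Output is deterministic SVG (byte-identical for identical inputs and seed,
including the random mesh) or PNG, plus an automatically generated legend
that draws each object separately and places non-overlapping element labels.

## Worked example

```python
from glyphstack import generate_fixture, normalize, render_page, export_svg
from glyphstack.template import bundled_templates

table = generate_fixture("wound", 4, seed=1)   # per-gene scratch-assay summaries
print(table.frame.to_string(index=False))
```

```
 gene  wound_area_change  cell_number  cell_area
 CTRL             0.5362        917.2     1893.8
 AKT2             0.9529       1173.7      379.9
PLCG1             0.1870       2103.7     2485.2
 CDH5             0.9512       1141.2     1860.6
```

```python
tpl = bundled_templates()["wound"]
nt = normalize(table, tpl.normalization)
print(nt.frame.round(3).to_string(index=False))
```

```
 gene  wound_area_change  cell_number  cell_area
 CTRL              0.536        0.000      0.719
 AKT2              0.953        0.216      0.000
PLCG1              0.187        1.000      1.000
 CDH5              0.951        0.189      0.703
```

`wound_area_change` was already within [0, 1] and is left untouched; the other
columns are min–max scaled (the provenance records `cell_number: (917.2,
2103.7)` so legend annotations can report original units). Rendering

```python
svg = export_svg(render_page(tpl, nt, page=0, seed=1))
```

produces one glyph per gene: the well square's red hue encodes mean cell area,
its grid-mesh density the cell count, and the height of the inner rectangle
the remaining wound area — AKT2 and CDH5 render tall inner rectangles (the
wound stayed open), PLCG1 a short one with a dense mesh (the wound closed and
the well is crowded).

The same pipeline is available from the shell:

```
glyphstack demo --kind multiplexed --n 6 --seed 1 --outdir demo/
glyphstack render --data demo/multiplexed_demo.csv \
    --template demo/multiplexed_template.json --out fig.svg --with-legend
glyphstack validate demo/multiplexed_template.json
```

The bundled `multiplexed-cell` template binds ten markers of a multiplexed
imaging panel to a cell-structure hierarchy (border symbols on three stacked
cell outlines for pAKT/p4EBP1/pS6, x-symbols filling the cytosol for CAV1,
colour gradients for Golgi/centrosome/nuclear proteins, dot filling and border
dots on the nucleus for PCNA and NUPS, grid mesh for local cell density) and
places each cluster glyph at its embedding-space centre.

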