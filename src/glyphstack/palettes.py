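"""ColorBrewer sequential palettes used by the fill-gradient element.

Each palette is its 9-class anchor list (light to dark). Values are
interpolated piecewise-linearly in RGB between anchors; see
:func:`glyphstack.encodings.encode_fill_gradient`.
"""
from __future__ import annotations

from .errors import ConfigurationError


def _hex(codes: str) -> tuple[tuple[int, int, int], ...]:
    out = []
    for c in codes.split():
        c = c.lstrip("#")
        out.append((int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16)))
    return tuple(out)


SEQUENTIAL: dict[str, tuple[tuple[int, int, int], ...]] = {
    "Reds": _hex("fff5f0 fee0d2 fcbba1 fc9272 fb6a4a ef3b2c cb181d a50f15 67000d"),
    "Blues": _hex("f7fbff deebf7 c6dbef 9ecae1 6baed6 4292c6 2171b5 08519c 08306b"),
    "Greens": _hex("f7fcf5 e5f5e0 c7e9c0 a1d99b 74c476 41ab5d 238b45 006d2c 00441b"),
    "Purples": _hex("fcfbfd efedf5 dadaeb bcbddc 9e9ac8 807dba 6a51a3 54278f 3f007d"),
    "Oranges": _hex("fff5eb fee6ce fdd0a2 fdae6b fd8d3c f16913 d94801 a63603 7f2704"),
    "Greys": _hex("ffffff f0f0f0 d9d9d9 bdbdbd 969696 737373 525252 252525 000000"),
    "YlGnBu": _hex("ffffd9 edf8b1 c7e9b4 7fcdbb 41b6c4 1d91c0 225ea8 253494 081d58"),
    "YlOrRd": _hex("ffffcc ffeda0 fed976 feb24c fd8d3c fc4e2a e31a1c bd0026 800026"),
    "BuPu": _hex("f7fcfd e0ecf4 bfd3e6 9ebcda 8c96c6 8c6bb1 88419d 810f7c 4d004b"),
    "GnBu": _hex("f7fcf0 e0f3db ccebc5 a8ddb5 7bccc4 4eb3d3 2b8cbe 0868ac 084081"),
    "OrRd": _hex("fff7ec fee8c8 fdd49e fdbb84 fc8d59 ef6548 d7301f b30000 7f0000"),
    "PuBu": _hex("fff7fb ece7f2 d0d1e6 a6bddb 74a9cf 3690c0 0570b0 045a8d 023858"),
}


def get_palette(name: str) -> tuple[tuple[int, int, int], ...]:
    try:
        return SEQUENTIAL[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown palette '{name}'; available: {', '.join(sorted(SEQUENTIAL))}") from None
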