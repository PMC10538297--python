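"""Built-in forensic Y-marker panel definitions.

Rosters follow the public locus lists of the commercial kits.  Multi-copy
loci (DYS385, DYF387S1, DYS527, DYF404S1) are listed once and counted as two
markers each (the a/b convention), so marker counts come out at the familiar
9 / 12 / 17 / 23 / 27.  The 44-marker panel models a 41 Y-STR + 3 Y-InDel
six-dye megaplex; its exact roster is user-editable via a panel config file.
"""

from __future__ import annotations

from .model import PanelDefinition

__all__ = [
    "MINIMAL",
    "POWERPLEX_Y",
    "YFILER",
    "POWERPLEX_Y23",
    "YFILER_PLUS",
    "YPLUS44",
    "BUILTIN_PANELS",
    "get_panel",
]

# Classic 9-marker minimal haplotype (DYS385a/b counted as two markers).
MINIMAL = PanelDefinition(
    name="minimal",
    loci=(
        "DYS19", "DYS385", "DYS389I", "DYS389II", "DYS390",
        "DYS391", "DYS392", "DYS393",
    ),
    multi_copy=frozenset({"DYS385"}),
)

POWERPLEX_Y = PanelDefinition(
    name="powerplex_y",
    loci=MINIMAL.loci + ("DYS437", "DYS438", "DYS439"),
    multi_copy=frozenset({"DYS385"}),
)

YFILER = PanelDefinition(
    name="yfiler",
    loci=POWERPLEX_Y.loci + ("DYS448", "DYS456", "DYS458", "DYS635", "YGATAH4"),
    multi_copy=frozenset({"DYS385"}),
)

POWERPLEX_Y23 = PanelDefinition(
    name="powerplex_y23",
    loci=YFILER.loci + ("DYS481", "DYS533", "DYS549", "DYS570", "DYS576", "DYS643"),
    multi_copy=frozenset({"DYS385"}),
)

YFILER_PLUS = PanelDefinition(
    name="yfiler_plus",
    loci=YFILER.loci
    + ("DYS449", "DYS460", "DYS481", "DYS518", "DYS533", "DYS570", "DYS576",
       "DYS627", "DYF387S1"),
    multi_copy=frozenset({"DYS385", "DYF387S1"}),
)

# 33 single-copy STRs + 4 double-copy STRs (counted twice) + 3 Y-InDels = 44.
YPLUS44 = PanelDefinition(
    name="yplus44",
    loci=POWERPLEX_Y23.loci
    + ("DYS388", "DYS444", "DYS447", "DYS449", "DYS460", "DYS518", "DYS522",
       "DYS557", "DYS593", "DYS596", "DYS627", "DYS645",
       "DYF387S1", "DYS527", "DYF404S1",
       "rs199815934", "rs759551978", "rs771783753"),
    multi_copy=frozenset({"DYS385", "DYF387S1", "DYS527", "DYF404S1"}),
    indel_loci=frozenset({"rs199815934", "rs759551978", "rs771783753"}),
)

BUILTIN_PANELS: dict[str, PanelDefinition] = {
    p.name: p
    for p in (MINIMAL, POWERPLEX_Y, YFILER, POWERPLEX_Y23, YFILER_PLUS, YPLUS44)
}


def get_panel(name: str) -> PanelDefinition:
    try:
        return BUILTIN_PANELS[name]
    except KeyError:
        raise KeyError(
            f"unknown panel {name!r}; built-ins: {', '.join(BUILTIN_PANELS)}"
        ) from None
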