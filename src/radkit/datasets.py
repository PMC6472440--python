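"""Published comparative-table inputs bundled for demos and reproduction.

Two small tables of island plant radiations, as printed in the published
comparisons this package reproduces: New Caledonian lineages (richness and
stem/crown ages) and rapid island radiations worldwide (richness, island
area, and the 95% HPD bounds of the crown age).  Only the *inputs* are
stored; diversification rates are always recomputed from them with
:func:`radkit.netdiv.ms_crown_rate`.
"""

from __future__ import annotations

from typing import List

from .netdiv import CladeRecord

__all__ = ["nc_radiations", "island_radiations", "NC_OXERA"]

# New Caledonian Oxera radiation: the focal clade of the worked examples.
NC_OXERA = CladeRecord(
    clade="NC Oxera", n=33, stem_age=5.39, crown_age=4.54,
    crown_low=2.7, crown_high=6.92, area_km2=18600.0,
)

# (clade, stem age Ma, crown age Ma, NC species richness)
_NC_ROWS = [
    ("Planchonella clade III", 18.0, 15.0, 3),
    ("Beauprea clade I", 78.2, 28.3, 7),
    ("Nothofagus", 26.1, 16.4, 5),
    ("Planchonella clade I", 15.3, 12.05, 4),
    ("Kermadecia-Sleumerodendron", 13.6, 12.3, 5),
    ("Metrosideros clade B", 21.25, 11.0, 5),
    ("Metrosideros clade A", 16.25, 13.6, 7),
    ("Clinosperma-Cyphokentia", 21.5, 10.5, 6),
    ("Metrosideros clade C", 29.1, 8.25, 5),
    ("Chambeyronia-Kentiopsis", 9.0, 4.5, 6),
    ("Pichonia", 19.0, 10.1, 7),
    ("Planchonella clade II", 33.0, 17.4, 18),
    ("Margaritopsis", 8.47, 5.21, 4),
    ("Psychotria clade NC1", 17.06, 4.78, 4),
    ("Oxanthera", 5.8, 5.8, 5),
    ("Pleioluma clade I", 10.0, 4.9, 5),
    ("Burretiokentia-Cyphophoenix", 11.5, 7.5, 9),
    ("Pycnandra", 29.8, 16.2, 57),
    ("Araucaria", 16.0, 8.0, 13),
    ("Geniostoma", 9.0, 6.5, 10),
    ("Dacrydium", 5.0, 3.05, 5),
    ("Podocarpus", 6.9, 4.2, 8),
    ("Pleioluma clade II", 7.5, 4.2, 8),
    ("Euroschinus", 11.85, 3.7, 7),
    ("Diospyros clade III", 9.1, 7.2, 25),
    ("NC Pandanus subgen. Lophostigma", 8.5, 6.5, 24),
    ("Dracophyllum", 5.2, 3.5, 8),
    ("Psychotria clade NC2", 7.63, 6.9, 78),
    ("NC Oxera", 5.39, 4.54, 33),
    ("Thiollierea", 6.5, 3.0, 13),
]

# (clade, n, area km^2, crown HPD low Ma, crown HPD high Ma); a None high
# bound marks clades published with a single crown age.
_ISLAND_ROWS = [
    ("NC Oxera", 33, 18600.0, 2.7, 6.92),
    ("Psychotria clade NC2", 78, 18600.0, 4.62, 9.82),
    ("Cheirolophus", 20, 10372.0, 5.98, 15.35),
    ("Euphorbia (Hawaii)", 16, 16644.0, 0.72, 3.97),
    ("Bidens (Hawaii)", 19, 16644.0, 1.3, 3.1),
    ("Echium (Macaronesia)", 19, 10372.0, 2.7, 3.9),
    ("Cyrtandra (Hawaii)", 58, 16644.0, 5.2, None),
    ("Lobeliads (Hawaii)", 126, 16644.0, 10.49, 16.71),
    ("Aeonium (Macaronesia)", 63, 10372.0, 13.25, 17.15),
    ("Veronica (New Zealand)", 120, 268680.0, 5.7, None),
]


def nc_radiations() -> List[CladeRecord]:
    """New Caledonian radiations: richness and stem/crown ages."""
    return [
        CladeRecord(clade=name, n=n, stem_age=stem, crown_age=crown)
        for name, stem, crown, n in _NC_ROWS
    ]


def island_radiations() -> List[CladeRecord]:
    """Rapid island radiations: richness, area and crown-age HPD bounds.

    Clades published with a single crown age get that age as
    ``crown_age`` and no HPD bounds.
    """
    out = []
    for name, n, area, low, high in _ISLAND_ROWS:
        if high is None:
            out.append(CladeRecord(clade=name, n=n, crown_age=low,
                                   area_km2=area))
        else:
            out.append(CladeRecord(clade=name, n=n, crown_low=low,
                                   crown_high=high, area_km2=area))
    return out
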