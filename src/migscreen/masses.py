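"""Static atomic- and isotope-mass tables (CODATA/IUPAC values).

Embedded so that mass arithmetic never depends on an external resource.
Monoisotopic masses refer to the lightest isotope of each supported element;
isotope distributions are (exact mass, natural abundance) pairs normalized to
sum to 1 per element.
"""

from __future__ import annotations

#: Elements supported throughout the toolkit (plastic-relevant organics plus
#: the alkali adduct carriers).
SUPPORTED_ELEMENTS: tuple[str, ...] = (
    "C", "H", "N", "O", "P", "S", "F", "Cl", "Na", "K",
)

#: Mass of the lightest (principal) isotope, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

PROTON_MASS = 1.007276466879
ELECTRON_MASS = 0.000548579909

#: Per-element isotope distributions: list of (exact mass Da, abundance).
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "H": [(1.00782503207, 0.999885), (2.0141017778, 0.000115)],
    "N": [(14.0030740048, 0.99636), (15.0001088982, 0.00364)],
    "O": [
        (15.9949146196, 0.99757),
        (16.9991317, 0.00038),
        (17.9991610, 0.00205),
    ],
    "P": [(30.97376163, 1.0)],
    "S": [
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ],
    "F": [(18.99840322, 1.0)],
    "Cl": [(34.96885268, 0.7576), (36.96590259, 0.2424)],
    "Na": [(22.9897692809, 1.0)],
    "K": [
        (38.96370668, 0.932581),
        (39.96399848, 0.000117),
        (40.96182576, 0.067302),
    ],
}

#: Standard bonding valences used for ring-plus-double-bond equivalents.
VALENCE: dict[str, int] = {
    "C": 4, "H": 1, "N": 3, "O": 2, "P": 3, "S": 2,
    "F": 1, "Cl": 1, "Na": 1, "K": 1,
}
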