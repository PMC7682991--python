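"""Static element data: IUPAC standard atomic weights and isotope table.

One versioned table, bundled with the package, so that every mass printed by
the pipeline is reproducible without a network lookup.  Values are the IUPAC
2021 standard atomic weights (conventional values for interval elements) and
the CIAAW isotopic masses/abundances.  Only the elements occurring in
unmodified peptides (plus phosphorus) are carried; anything else raises a
``KeyError`` at the point of use.
"""
from __future__ import annotations

#: IUPAC standard atomic weights (Da), conventional single values.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

#: Isotope table: element -> list of (isotopic mass in Da, relative abundance),
#: sorted by mass.  Abundances sum to 1 per element.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017780, 0.000115)],
    "C": [(12.0000000, 0.9893), (13.0033548378, 0.0107)],
    "N": [(14.0030740052, 0.99636), (15.0001088984, 0.00364)],
    "O": [
        (15.9949146221, 0.99757),
        (16.9991315, 0.00038),
        (17.9991604, 0.00205),
    ],
    "S": [
        (31.97207069, 0.9499),
        (32.97145850, 0.0075),
        (33.96786683, 0.0425),
        (35.96708088, 0.0001),
    ],
    "P": [(30.97376151, 1.0)],
}

#: Mass of the most abundant isotope (Da) -- the "monoisotopic" mass.
MONOISOTOPIC_MASSES: dict[str, float] = {
    el: max(isos, key=lambda p: p[1])[0] for el, isos in ISOTOPES.items()
}
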