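"""Elemental compositions, masses, isotope patterns and m/z arithmetic for
n-mer ions of a peptide.

This module underlies every m/z value in the pipeline.  The key physical
facts it encodes:

* a peptide of L residues is the sum of its residue formulas plus one water;
* an n-mer ion carrying z protons appears at m/z = (n*M + z*m_H+)/z, so
  species with equal n/z ratio are m/z-degenerate and can only be told apart
  by their isotopologue spacing of ~1.0034/z Th;
* the isotopologue envelope of a composition is the convolution of the
  per-element isotope distributions.

Isotopologues are aggregated by nominal mass shift and reported on an exact
neutron-spaced grid (monoisotopic mass + k * 1.0033548 Da).  This is the
convention used for charge reading throughout; true fine-structure centroids
deviate from that grid by well under typical TWIMS peak widths.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .elements import ATOMIC_WEIGHTS, ISOTOPES, MONOISOTOPIC_MASSES

#: Proton mass (Da) used for all charge arithmetic.
PROTON_MASS = 1.00728

#: Nominal isotopologue spacing (Da): the C13-C12 mass difference, the
#: dominant +1 channel in peptides; 1.0034/z Th is the charge-reading rule.
NEUTRON_SPACING = 1.0033548

#: Canonical 42-residue amyloid-beta peptide sequence.
ABETA42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

#: Residue (amino acid minus water) elemental formulas, one-letter codes.
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

WATER = {"H": 2, "O": 1}


class ElementalComposition(Mapping[str, int]):
    """Non-negative integer element counts (C, H, N, O, S, ...).

    Behaves as an immutable mapping; supports ``+`` (element-wise sum) and
    ``*`` int (n-mer scaling).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, c in src.items():
                merged[el] = merged.get(el, 0) + int(c)
        for el, c in merged.items():
            if c < 0:
                raise ValueError(f"negative count for element {el}: {c}")
        self._counts = {el: c for el, c in sorted(merged.items()) if c > 0}

    def __getitem__(self, el: str) -> int:
        return self._counts[el]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = dict(self._counts)
        for el, c in other.items():
            out[el] = out.get(el, 0) + c
        return ElementalComposition(out)

    def __mul__(self, n: int) -> "ElementalComposition":
        if not isinstance(n, int) or n < 0:
            raise ValueError("composition can only be scaled by a non-negative int")
        return ElementalComposition({el: c * n for el, c in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        body = "".join(f"{el}{c}" for el, c in self._counts.items())
        return f"ElementalComposition({body})"

    def total_atoms(self) -> int:
        return sum(self._counts.values())


def composition_from_sequence(sequence: str) -> ElementalComposition:
    """Elemental composition of a peptide: residue sum plus one water.

    Raises ``ValueError`` naming the offending character and its (1-based)
    position for anything outside the 20 canonical one-letter codes.
    """
    if not sequence:
        raise ValueError("empty sequence")
    counts: dict[str, int] = dict(WATER)
    for pos, aa in enumerate(sequence, start=1):
        try:
            formula = RESIDUE_FORMULAS[aa.upper()]
        except KeyError:
            raise ValueError(
                f"unknown residue code {aa!r} at position {pos}"
            ) from None
        for el, c in formula.items():
            counts[el] = counts.get(el, 0) + c
    return ElementalComposition(counts)


def average_mass(c: ElementalComposition) -> float:
    """Average mass (Da) from IUPAC standard atomic weights."""
    return float(sum(ATOMIC_WEIGHTS[el] * n for el, n in c.items()))


def monoisotopic_mass(c: ElementalComposition) -> float:
    """Monoisotopic mass (Da): most-abundant-isotope masses."""
    return float(sum(MONOISOTOPIC_MASSES[el] * n for el, n in c.items()))


@dataclass(frozen=True)
class IonSpecies:
    """An (oligomer order n, charge z) ion of a peptide.

    ``m_avg``/``m_mono`` are the *neutral monomer* masses; m/z arithmetic
    scales by n and protonates by z.
    """

    n: int
    z: int
    peptide: str = "Abeta42"
    m_avg: float = 0.0
    m_mono: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1 or self.z < 1:
            raise ValueError("oligomer order and charge must be positive")

    @classmethod
    def from_sequence(
        cls, sequence: str, n: int, z: int, peptide: str | None = None
    ) -> "IonSpecies":
        comp = composition_from_sequence(sequence)
        return cls(
            n=n,
            z=z,
            peptide=peptide or sequence,
            m_avg=average_mass(comp),
            m_mono=monoisotopic_mass(comp),
        )

    @property
    def label(self) -> str:
        return f"{self.n}-mer^{self.z}+ ({self.peptide})"


def mz_of_species(s: IonSpecies, convention: str = "average") -> float:
    """m/z = (n*M + z*m_proton)/z for the chosen mass convention."""
    if s.z == 0:
        raise ValueError("charge must be non-zero")
    if convention == "average":
        m = s.m_avg
    elif convention == "monoisotopic":
        m = s.m_mono
    else:
        raise ValueError(f"unknown mass convention {convention!r}")
    return (s.n * m + s.z * PROTON_MASS) / s.z


def nominal_mz(s: IonSpecies, convention: str = "average") -> int:
    """Integer peak label: floor of the computed m/z."""
    return math.floor(mz_of_species(s, convention))


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotopologue envelope of a (possibly multiply charged) ion.

    ``masses`` are neutral masses (Da) on the exact neutron-spaced grid;
    ``mz`` protonates and divides by charge.  Abundances are renormalized to
    sum to one after truncation.
    """

    masses: tuple[float, ...]
    abundances: tuple[float, ...]
    charge: int

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1 within 1e-9")
        diffs = np.diff(self.masses)
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError("masses must be strictly increasing")
        if len(diffs) and np.any(np.abs(diffs - NEUTRON_SPACING) > 1e-4 * self.charge):
            raise ValueError("isotopologue spacing violates the neutron grid")

    @property
    def mz(self) -> np.ndarray:
        m = np.asarray(self.masses)
        return (m + self.charge * PROTON_MASS) / self.charge

    @property
    def abundance_array(self) -> np.ndarray:
        return np.asarray(self.abundances)

    def to_table(self) -> "np.ndarray":
        return np.column_stack([self.masses, self.abundances])


def _truncated_convolve(a: np.ndarray, b: np.ndarray, limit: int) -> np.ndarray:
    return np.convolve(a, b)[:limit]


def _element_power_pattern(el: str, count: int, limit: int) -> np.ndarray:
    """Abundance polynomial of ``count`` atoms of ``el`` on the nominal grid,
    by exponentiation-by-squaring of the single-atom polynomial."""
    isos = ISOTOPES[el]
    m0 = isos[0][0]
    base = np.zeros(max(round(m - m0) for m, _ in isos) + 1)
    for m, a in isos:
        base[round(m - m0)] += a
    result = np.array([1.0])
    power = base
    k = count
    while k:
        if k & 1:
            result = _truncated_convolve(result, power, limit)
        k >>= 1
        if k:
            power = _truncated_convolve(power, power, limit)
    return result


def isotope_pattern(
    c: ElementalComposition,
    z: int = 1,
    n_peaks: int | None = None,
    truncate: bool = True,
) -> IsotopePattern:
    """Isotopologue pattern by element-wise abundance convolution.

    Peaks are kept (most abundant first) until their cumulative abundance
    reaches 0.9999, capped at ``n_peaks``; the surviving contiguous mass
    range is renormalized to sum to one.  ``truncate=False`` keeps the full
    computed support (for exact convolution identities).
    """
    if n_peaks is not None and n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if len(c) == 0:
        raise ValueError("empty composition has no isotope pattern")
    # internal grid length: mean nominal shift + generous tail
    mean = var = 0.0
    for el, count in c.items():
        isos = ISOTOPES[el]
        m0 = isos[0][0]
        mu = sum(a * round(m - m0) for m, a in isos)
        mean += count * mu
        var += count * sum(a * (round(m - m0) - mu) ** 2 for m, a in isos)
    limit = int(mean + 12.0 * math.sqrt(var)) + 8

    pattern = np.array([1.0])
    for el, count in c.items():
        pattern = _truncated_convolve(
            pattern, _element_power_pattern(el, count, limit), limit
        )

    if truncate:
        order = np.argsort(pattern)[::-1]
        cumulative = np.cumsum(pattern[order])
        keep_n = int(np.searchsorted(cumulative, 0.9999) + 1)
        if n_peaks is not None:
            keep_n = min(keep_n, n_peaks)
        kept = order[:keep_n]
        lo, hi = int(kept.min()), int(kept.max())
    else:
        nonzero = np.flatnonzero(pattern > 1e-15)
        lo, hi = int(nonzero.min()), int(nonzero.max())
    abundances = pattern[lo : hi + 1]
    abundances = abundances / abundances.sum()
    mono = monoisotopic_mass(c)
    masses = mono + NEUTRON_SPACING * np.arange(lo, hi + 1)
    return IsotopePattern(
        masses=tuple(masses.tolist()),
        abundances=tuple(abundances.tolist()),
        charge=z,
    )


def read_fasta(path) -> dict[str, str]:
    """Read sequences from a FASTA file: {record id: sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def pattern_to_text(p: IsotopePattern, path) -> None:
    """Write a pattern as two-column delimited text (mass, abundance)."""
    import pandas as pd

    pd.DataFrame({"mass": p.masses, "abundance": p.abundances}).to_csv(
        path, index=False
    )


def pattern_from_text(path, charge: int = 1) -> IsotopePattern:
    import pandas as pd

    df = pd.read_csv(path)
    return IsotopePattern(
        masses=tuple(df["mass"]), abundances=tuple(df["abundance"]), charge=charge
    )
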