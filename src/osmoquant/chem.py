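"""Exact-mass and isotope arithmetic for small polar metabolites.

This module is the package's single mass convention. Monoisotopic masses
and natural isotopic abundances are embedded below (IUPAC/NIST values,
>= 6 decimal places); every downstream stage — simulation, screening,
fragment annotation, quantification — derives its m/z values from here.

Two conventions worth stating explicitly:

* Protonation uses the *proton* mass (1.0072765 Da), i.e. the electron is
  accounted for.  [M+H]+ of cysteinolic acid (C3H9NO4S) then comes out at
  156.032505 Da.
* Isotope patterns are computed by full convolution of per-element isotope
  distributions and then merged by mass proximity (default 0.0025 Da,
  roughly what a 70k-resolution Orbitrap separates at m/z 150-200).  This
  keeps the diagnostic 34S peak at +1.995796 Da distinct from the 18O and
  13C2 isotopologues near +2.004 Da — the separation that makes the M+2
  sulfur signature usable as a screening filter in the first place.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ISOTOPES",
    "Formula",
    "AdductSpec",
    "IsotopePattern",
    "M_PLUS_H",
    "M_PLUS_NA",
    "M_MINUS_H",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "isotope_pattern",
    "mass_error_ppm",
    "SULFUR_M2_SHIFT",
    "SULFUR_M2_RATIO",
]

PROTON_MASS = 1.0072765  # m(1H) - m(e-), Da
ELECTRON_MASS = 0.00054858

#: element -> tuple of (isotope mass in Da, natural abundance fraction),
#: principal (most abundant) isotope first.
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.01410177785, 0.000115)),
    "C": ((12.0, 0.9893), (13.00335483507, 0.0107)),
    "N": ((14.0030740048, 0.99636), (15.00010889888, 0.00364)),
    "O": (
        (15.99491461956, 0.99757),
        (16.99913175650, 0.00038),
        (17.99915961286, 0.00205),
    ),
    "S": (
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ),
    "P": ((30.97376163, 1.0),),
    "Na": ((22.9897692809, 1.0),),
}

#: 34S - 32S mass difference: the M+2 spacing diagnostic for sulfur.
SULFUR_M2_SHIFT = ISOTOPES["S"][2][0] - ISOTOPES["S"][0][0]  # 1.995796 Da
#: 34S/32S natural abundance ratio (~0.0447 per sulfur atom).
SULFUR_M2_RATIO = ISOTOPES["S"][2][1] / ISOTOPES["S"][0][1]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible formulas."""


class Formula(Mapping[str, int]):
    """An elemental composition: immutable mapping element symbol -> count.

    Supports ``+`` and ``-`` for composition arithmetic (subtraction raises
    if any count would go negative, which is how neutral-loss feasibility
    is checked during MS/MS annotation).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int]):
        clean: dict[str, int] = {}
        for element, count in counts.items():
            if element not in ISOTOPES:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(count, int) or count < 0:
                raise FormulaError(
                    f"count for {element} must be a non-negative integer, got {count!r}"
                )
            if count > 0:
                clean[element] = count
        self._counts = clean

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == dict(other)
        return NotImplemented

    def __repr__(self) -> str:
        return f"Formula({self.to_string()!r})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for element, count in other.items():
            merged[element] = merged.get(element, 0) + count
        return Formula(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for element, count in other.items():
            remaining = merged.get(element, 0) - count
            if remaining < 0:
                raise FormulaError(
                    f"cannot subtract {other.to_string()} from {self.to_string()}: "
                    f"{element} count would be negative"
                )
            merged[element] = remaining
        return Formula(merged)

    def contains(self, other: "Formula") -> bool:
        """True if ``other`` is element-wise subtractable from this formula."""
        return all(self._counts.get(e, 0) >= c for e, c in other.items())

    # -- text form --------------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-notation formula string such as ``"C3H10NO4S"``."""
        if not text or not text.strip():
            raise FormulaError("empty formula string")
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        for match in _TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(
                    f"malformed formula {text!r} at position {pos}: "
                    f"unexpected {text[pos:match.start()]!r}"
                )
            element, digits = match.groups()
            if element not in ISOTOPES:
                raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
            count = int(digits) if digits else 1
            counts[element] = counts.get(element, 0) + count
            pos = match.end()
        if pos != len(text):
            raise FormulaError(f"malformed formula {text!r}: trailing {text[pos:]!r}")
        return cls(counts)

    def to_string(self) -> str:
        """Canonical Hill notation: C, H, then remaining elements A-Z."""
        parts = []
        order: list[str]
        if "C" in self._counts:
            order = ["C"] + (["H"] if "H" in self._counts else [])
            order += sorted(e for e in self._counts if e not in ("C", "H"))
        else:
            order = sorted(self._counts)
        for element in order:
            n = self._counts[element]
            parts.append(element if n == 1 else f"{element}{n}")
        return "".join(parts)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-notation formula string into a :class:`Formula`."""
    return Formula.parse(text)


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: name, mass delta in Da, and (positive) charge."""

    name: str
    mass_delta: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"adduct charge must be >= 1, got {self.charge}")


M_PLUS_H = AdductSpec("[M+H]+", PROTON_MASS, 1)
M_PLUS_NA = AdductSpec("[M+Na]+", ISOTOPES["Na"][0][0] - ELECTRON_MASS, 1)
M_MINUS_H = AdductSpec("[M-H]-", -PROTON_MASS, 1)

ADDUCTS = {a.name: a for a in (M_PLUS_H, M_PLUS_NA, M_MINUS_H)}


def monoisotopic_mass(comp: Formula | Mapping[str, int]) -> float:
    """Monoisotopic (principal-isotope) mass of a composition, in Da."""
    if not isinstance(comp, Formula):
        comp = Formula(comp)
    return sum(ISOTOPES[e][0][0] * n for e, n in comp.items())


def adduct_mz(comp: Formula | Mapping[str, int], adduct: AdductSpec) -> float:
    """m/z of a neutral composition under the given adduct."""
    return (monoisotopic_mass(comp) + adduct.mass_delta) / adduct.charge


def mass_error_ppm(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be > 0, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue envelope relative to the monoisotopic peak.

    ``peaks`` is a list of ``(mass shift in Da, relative abundance)`` with
    the monoisotopic peak first at shift 0.0 and abundance 1.0; shifts are
    strictly increasing.
    """

    peaks: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def abundance_at(self, shift: float, tol: float = 0.003) -> float:
        """Summed relative abundance of peaks within ``tol`` of ``shift``."""
        return sum(a for s, a in self.peaks if abs(s - shift) <= tol)


def _convolve(dist_a: dict[float, float], dist_b: dict[float, float],
              prune: float) -> dict[float, float]:
    out: dict[float, float] = {}
    for ma, pa in dist_a.items():
        for mb, pb in dist_b.items():
            p = pa * pb
            if p < prune:
                continue
            m = round(ma + mb, 7)
            out[m] = out.get(m, 0.0) + p
    return out


def isotope_pattern(
    comp: Formula | Mapping[str, int],
    abundance_threshold: float = 1e-4,
    merge_tol: float = 0.0025,
) -> IsotopePattern:
    """Predict the isotopologue pattern of a composition.

    Per-element isotope distributions are convolved atom by atom at full
    mass precision, then isotopologues closer than ``merge_tol`` Da are
    merged (mass = abundance-weighted mean).  Peaks below
    ``abundance_threshold`` relative to the monoisotopic peak are pruned;
    the monoisotopic peak itself is always kept.

    For any sulfur-containing formula the result contains a resolved peak
    at +1.995796 Da (34S) with relative abundance ~0.0447 per S atom.
    """
    if not 0 < abundance_threshold < 1:
        raise ValueError(
            f"abundance_threshold must be in (0, 1), got {abundance_threshold}"
        )
    if not isinstance(comp, Formula):
        comp = Formula(comp)
    prune = 1e-10
    dist: dict[float, float] = {0.0: 1.0}
    for element, n in comp.items():
        atom = {round(m - ISOTOPES[element][0][0], 7): p
                for m, p in ISOTOPES[element]}
        for _ in range(n):
            dist = _convolve(dist, atom, prune)
    # merge by mass proximity
    items = sorted(dist.items())
    clusters: list[list[tuple[float, float]]] = []
    for mass, prob in items:
        if clusters and mass - clusters[-1][-1][0] < merge_tol:
            clusters[-1].append((mass, prob))
        else:
            clusters.append([(mass, prob)])
    merged = []
    for cluster in clusters:
        total = sum(p for _, p in cluster)
        mean = sum(m * p for m, p in cluster) / total
        merged.append((mean, total))
    base = merged[0][1]  # monoisotopic cluster (lightest isotopes principal)
    peaks = [(0.0, 1.0)]
    for mean, total in merged[1:]:
        rel = total / base
        if rel >= abundance_threshold:
            peaks.append((mean - merged[0][0], rel))
    return IsotopePattern(tuple(peaks))
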