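"""Neutral-loss annotation of MS/MS fragment peaks.

Fragments of a protonated precursor are explained as combinations of
small neutral losses (water, ammonia, CO2, SO3, sulfurous acid) subtracted
from the precursor formula.  For cysteinolic acid [M+H]+ (156.0325) this
reproduces the diagnostic pair: loss of H2O at 138.0219 and the combined
loss of water plus the sulfonic group (H2O + H2SO3, leaving C3H6N+) at
56.0495.

The default fragment tolerance is 10 ppm — wider than the 5 ppm MS1
convention, because low-m/z fragment calibration on Orbitrap instruments
is routinely a few ppm worse (the published 56.04979 fragment itself sits
5.6 ppm above its exact mass).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .chem import (
    AdductSpec,
    Formula,
    FormulaError,
    M_PLUS_H,
    adduct_mz,
    mass_error_ppm,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "NeutralLoss",
    "FragmentAssignment",
    "DEFAULT_LOSSES",
    "DEFAULT_MSMS_TOL_PPM",
    "annotate_fragments",
]

DEFAULT_MSMS_TOL_PPM = 10.0


@dataclass(frozen=True)
class NeutralLoss:
    """A named neutral-loss moiety with its exact mass."""

    name: str
    formula: Formula

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"neutral loss {self.name} has non-positive mass")


DEFAULT_LOSSES: tuple[NeutralLoss, ...] = (
    NeutralLoss("H2O", parse_formula("H2O")),
    NeutralLoss("NH3", parse_formula("NH3")),
    NeutralLoss("CO2", parse_formula("CO2")),
    NeutralLoss("SO3", parse_formula("SO3")),
    NeutralLoss("H2SO3", parse_formula("H2SO3")),
)


@dataclass(frozen=True)
class FragmentAssignment:
    """One observed fragment peak and its best neutral-loss explanation.

    ``losses`` is the assigned loss combination (empty tuple = the intact
    precursor ion); ``None`` means no combination matched within
    tolerance, in which case ``theoretical_mz`` and ``error_ppm`` are
    ``None`` as well.
    """

    observed_mz: float
    losses: tuple[NeutralLoss, ...] | None
    theoretical_mz: float | None
    error_ppm: float | None

    @property
    def assigned(self) -> bool:
        return self.losses is not None

    @property
    def label(self) -> str:
        if self.losses is None:
            return "unassigned"
        if not self.losses:
            return "precursor"
        return "-(" + "+".join(l.name for l in self.losses) + ")"


def _loss_combinations(
    precursor: Formula,
    adduct: AdductSpec,
    losses: tuple[NeutralLoss, ...],
    max_combination: int,
) -> list[tuple[tuple[NeutralLoss, ...], float]]:
    """All subtractable loss multisets up to ``max_combination`` losses,
    with the theoretical m/z of the resulting fragment ion."""
    combos: list[tuple[tuple[NeutralLoss, ...], float]] = [
        ((), adduct_mz(precursor, adduct))
    ]
    for k in range(1, max_combination + 1):
        for combo in itertools.combinations_with_replacement(losses, k):
            total = combo[0].formula
            for loss in combo[1:]:
                total = total + loss.formula
            if not precursor.contains(total):
                continue
            remainder = precursor - total
            if not remainder:
                continue
            combos.append((combo, adduct_mz(remainder, adduct)))
    return combos


def annotate_fragments(
    precursor: Formula,
    adduct: AdductSpec = M_PLUS_H,
    peaks: list[float] | tuple[float, ...] = (),
    losses: tuple[NeutralLoss, ...] = DEFAULT_LOSSES,
    tol_ppm: float = DEFAULT_MSMS_TOL_PPM,
    max_combination: int = 2,
) -> list[FragmentAssignment]:
    """Assign each observed fragment m/z to a neutral-loss combination.

    All multisets of up to ``max_combination`` losses that are element-wise
    subtractable from the (neutral) precursor are enumerated; each peak is
    assigned to the combination minimizing |ppm error| within ``tol_ppm``,
    with exact ties broken toward fewer losses.  Peaks matching no
    combination are reported unassigned.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if max_combination < 1:
        raise ValueError("max_combination must be >= 1")
    combos = _loss_combinations(precursor, adduct, tuple(losses), max_combination)
    out: list[FragmentAssignment] = []
    for mz in peaks:
        best: tuple[float, int, tuple[NeutralLoss, ...], float] | None = None
        for combo, theo in combos:
            err = mass_error_ppm(mz, theo)
            if abs(err) > tol_ppm:
                continue
            if best is None or (abs(err), len(combo)) < (best[0], best[1]):
                best = (abs(err), len(combo), combo, theo)
        if best is None:
            out.append(FragmentAssignment(mz, None, None, None))
        else:
            _, _, combo, theo = best
            out.append(FragmentAssignment(
                observed_mz=mz,
                losses=combo,
                theoretical_mz=theo,
                error_ppm=mass_error_ppm(mz, theo),
            ))
    return out
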