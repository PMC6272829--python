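"""Exact-mass arithmetic for negative-mode small-molecule annotation.

Monoisotopic masses, ion m/z under the negative-ESI adduct set observed for
phenolic natural products ([M-H]-, [M+HCOO]-, [M+Cl]-, [2M-H]-), ppm mass
error, ring-and-double-bond equivalents (RDB), first-order M+1 isotope
fraction, and bounded elemental-formula enumeration from an accurate neutral
mass.

All atomic constants live in this module and nowhere else.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "Adduct",
    "ElementalFormula",
    "IonSpecies",
    "FormulaCandidate",
    "monoisotopic_mass",
    "ion_mz",
    "neutral_mass_from_mz",
    "ppm_error",
    "rdb",
    "isotope_m1_fraction",
    "enumerate_formulas",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "FORMATE_MASS",
    "DEFAULT_BOUNDS",
]

# IUPAC monoisotopic atomic masses (Da), most-abundant isotope.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "Cl": 34.96885271,
}

PROTON_MASS = 1.007276
ELECTRON_MASS = 0.000549
# HCOO- attachment: CHO2 plus the extra electron.
FORMATE_MASS = (
    MONOISOTOPIC_MASS["C"]
    + MONOISOTOPIC_MASS["H"]
    + 2 * MONOISOTOPIC_MASS["O"]
    + ELECTRON_MASS
)  # 44.998203

# Minor/major isotope abundance ratios contributing to the M+1 peak.
_M1_ABUNDANCE_RATIO: dict[str, float] = {
    "C": 0.010816,   # 13C/12C
    "H": 0.000156,   # 2H/1H
    "O": 0.000381,   # 17O/16O
    "N": 0.003613,   # 15N/14N
    "S": 0.007893,   # 33S/32S
    "Cl": 0.0,       # 37Cl contributes to M+2, not M+1
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Hill-like ordering: C, H, then remaining elements alphabetically.
_HILL_ORDER = ("C", "H", "Cl", "N", "O", "S")


class Adduct(str, Enum):
    """Negative-mode ion species observed for these compound classes."""

    M_MINUS_H = "M-H"
    M_PLUS_FORMATE = "M+HCOO"
    M_PLUS_CL = "M+Cl"
    DIMER_MINUS_H = "2M-H"


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map; immutable and hashable.

    Parsing ``"C7H6O5"`` and serializing round-trips losslessly.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = dict(counts)
        for el, n in items.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {el} must be a non-negative integer")
        ordered = tuple(
            (el, items[el]) for el in _HILL_ORDER if items.get(el, 0) > 0
        )
        object.__setattr__(self, "counts", ordered)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        if not text:
            return cls({})
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            el, num = match.group(1), match.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __str__(self) -> str:
        out = []
        for el, n in self.counts:
            out.append(el if n == 1 else f"{el}{n}")
        return "".join(out)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def add(self, other: "ElementalFormula | str") -> "ElementalFormula":
        if isinstance(other, str):
            other = ElementalFormula.parse(other)
        merged = dict(self.counts)
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def subtract(self, other: "ElementalFormula | str") -> "ElementalFormula":
        if isinstance(other, str):
            other = ElementalFormula.parse(other)
        merged = dict(self.counts)
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(f"subtraction would make {el} count negative")
        return ElementalFormula({el: n for el, n in merged.items() if n > 0})


@dataclass(frozen=True)
class IonSpecies:
    """A neutral molecule observed under one of the four negative adducts."""

    neutral_formula: ElementalFormula
    adduct: Adduct = Adduct.M_MINUS_H
    charge: int = -1

    def __post_init__(self):
        if self.charge != -1:
            raise ValueError("only singly charged negative ions are modelled")

    @property
    def mz(self) -> float:
        return ion_mz(self)


@dataclass(frozen=True)
class FormulaCandidate:
    """One elemental composition consistent with an accurate neutral mass."""

    formula: ElementalFormula
    theoretical_mass: float
    ppm_error: float
    rdb: float
    passes_golden_rules: bool

    @property
    def heteroatom_count(self) -> int:
        return sum(n for el, n in self.formula.counts if el not in ("C", "H"))


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass in Da; the empty formula sums to 0.0."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts)


def ion_mz(ion: IonSpecies) -> float:
    """m/z of a singly charged negative ion.

    [M-H]- and [2M-H]- are computed as M minus the proton mass; the electron
    mass is carried explicitly in the attachment adducts ([M+Cl]-, [M+HCOO]-),
    the standard negative-mode convention.
    """
    m = monoisotopic_mass(ion.neutral_formula)
    if ion.adduct is Adduct.M_MINUS_H:
        return m - PROTON_MASS
    if ion.adduct is Adduct.M_PLUS_FORMATE:
        return m + FORMATE_MASS
    if ion.adduct is Adduct.M_PLUS_CL:
        return m + MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS
    if ion.adduct is Adduct.DIMER_MINUS_H:
        return 2 * m - PROTON_MASS
    raise ValueError(f"unsupported adduct {ion.adduct}")


def neutral_mass_from_mz(mz: float, adduct: Adduct = Adduct.M_MINUS_H) -> float:
    """Invert :func:`ion_mz`: neutral monoisotopic mass from an observed m/z."""
    if adduct is Adduct.M_MINUS_H:
        return mz + PROTON_MASS
    if adduct is Adduct.M_PLUS_FORMATE:
        return mz - FORMATE_MASS
    if adduct is Adduct.M_PLUS_CL:
        return mz - MONOISOTOPIC_MASS["Cl"] - ELECTRON_MASS
    if adduct is Adduct.DIMER_MINUS_H:
        return (mz + PROTON_MASS) / 2.0
    raise ValueError(f"unsupported adduct {adduct}")


def ppm_error(observed: float, theoretical: float) -> float:
    """(observed - theoretical) / theoretical * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def rdb(formula: ElementalFormula | str) -> float:
    """Ring-and-double-bond equivalents: C - (H + halogens)/2 + N/2 + 1."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return (
        formula["C"]
        - (formula["H"] + formula["Cl"]) / 2.0
        + formula["N"] / 2.0
        + 1.0
    )


def isotope_m1_fraction(formula: ElementalFormula | str) -> float:
    """First-order M+1/M intensity ratio.

    Sum over elements of count times the minor/major abundance ratio; this
    linear approximation is what an isotope-abundance plausibility check on
    Orbitrap data uses, not a full isotopologue envelope.
    """
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return sum(_M1_ABUNDANCE_RATIO[el] * n for el, n in formula.counts)


DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (0, 60),
    "H": (0, 100),
    "O": (0, 30),
}


def _passes_golden_rules(c: int, h: int, o: int) -> bool:
    # Coarse published element-ratio heuristic for CHO(-rich) molecules.
    if c == 0:
        return True
    return 0.2 <= h / c <= 3.1 and o / c <= 3.0


def enumerate_formulas(
    neutral_mass: float,
    tol_ppm: float = 5.0,
    bounds: Mapping[str, tuple[int, int]] | None = None,
) -> list[FormulaCandidate]:
    """Exhaustive elemental-composition search within ``tol_ppm`` of a mass.

    Searches integer element counts inside ``bounds`` (default CHO,
    C 0-60 / H 0-100 / O 0-30; N, S, Cl may be added via ``bounds``), retains
    candidates with \\|ppm\\| <= tol_ppm and RDB >= 0, and flags the
    element-ratio heuristic (0.2 <= H/C <= 3.1, O/C <= 3) as a boolean;
    failing it demotes a candidate in the ordering but does not delete it.

    Ordering is deterministic: golden-rule passes first, then \\|ppm\\|
    ascending, then fewer heteroatoms, then lexicographic formula string.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    bounds = dict(bounds if bounds is not None else DEFAULT_BOUNDS)
    for el in bounds:
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol in bounds: {el!r}")
    if not bounds or all(hi < lo for lo, hi in bounds.values()):
        return []

    h_lo, h_hi = bounds.pop("H", (0, 0))
    heavy_elements = sorted(bounds)  # deterministic iteration order
    tol_da = neutral_mass * tol_ppm * 1e-6
    mass_h = MONOISOTOPIC_MASS["H"]

    out: list[FormulaCandidate] = []
    ranges = [range(bounds[el][0], bounds[el][1] + 1) for el in heavy_elements]
    for combo in itertools.product(*ranges):
        heavy_mass = sum(
            MONOISOTOPIC_MASS[el] * n for el, n in zip(heavy_elements, combo)
        )
        if heavy_mass > neutral_mass + tol_da:
            continue
        # H count window solving |heavy + n_H * m_H - mass| <= tol
        lo = max(h_lo, int(-(-(neutral_mass - tol_da - heavy_mass) // mass_h)))
        hi = min(h_hi, int((neutral_mass + tol_da - heavy_mass) // mass_h))
        for n_h in range(lo, hi + 1):
            counts = {el: n for el, n in zip(heavy_elements, combo) if n > 0}
            if n_h > 0:
                counts["H"] = n_h
            if not counts:
                continue
            formula = ElementalFormula(counts)
            theo = heavy_mass + n_h * mass_h
            err = ppm_error(neutral_mass, theo)
            # enumerate against the *observed* mass: candidate kept when the
            # observation sits within tol of the candidate's theoretical mass
            if abs(neutral_mass - theo) > tol_da:
                continue
            unsat = rdb(formula)
            if unsat < 0:
                continue
            out.append(
                FormulaCandidate(
                    formula=formula,
                    theoretical_mass=theo,
                    ppm_error=err,
                    rdb=unsat,
                    passes_golden_rules=_passes_golden_rules(
                        formula["C"], formula["H"], formula["O"]
                    ),
                )
            )
    out.sort(
        key=lambda c: (
            not c.passes_golden_rules,
            abs(c.ppm_error),
            c.heteroatom_count,
            str(c.formula),
        )
    )
    return out
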