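"""Elemental-composition arithmetic for 2'-deoxyribonucleoside adduct annotation.

Masses are monoisotopic (most abundant isotope, IUPAC values). Observed
precursor ions are even-electron protonated species [M+H]+, so theoretical
m/z at charge 1 is the neutral monoisotopic mass plus one proton.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ElementalComposition",
    "AnnotationResult",
    "EnumerationConstraints",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "DEOXYRIBOSE_LOSS",
    "monoisotopic_mass",
    "ppm_error",
    "rdb",
    "enumerate_compositions",
    "parse_formula",
]

# Most-abundant-isotope masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
}

PROTON_MASS = 1.0072765

#: Neutral loss of 2'-deoxyribose (C5H8O3) from a protonated deoxyribonucleoside.
DEOXYRIBOSE_LOSS = 116.0473

_HILL_ORDER = ("C", "H", "N", "O", "P", "S")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Element counts of a (neutral, unless stated) molecular formula."""

    counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}")
        if sum(self.counts.values()) == 0:
            raise ValueError("composition must contain at least one atom")

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def hill(self) -> str:
        """Formula string in Hill notation (C, H, then alphabetical)."""
        parts = []
        for el in _HILL_ORDER:
            n = self[el]
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(formula: str) -> ElementalComposition:
    """Parse a formula like ``"C22H44O12N2"`` (whitespace tolerated)."""
    counts: dict[str, int] = {}
    stripped = formula.replace(" ", "")
    pos = 0
    for m in _FORMULA_TOKEN.finditer(stripped):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        if not m.group(0):
            break
        el = m.group(1)
        counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    if pos != len(stripped) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return ElementalComposition(counts)


def monoisotopic_mass(
    comp: ElementalComposition | str, species: str = "neutral"
) -> float:
    """Monoisotopic mass of ``comp`` in Da.

    ``species="neutral"`` returns the neutral mass; ``species="protonated"``
    adds one proton and returns the m/z of the singly charged [M+H]+ ion.
    """
    if isinstance(comp, str):
        comp = parse_formula(comp)
    mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in comp.counts.items())
    if species == "neutral":
        return mass
    if species == "protonated":
        return mass + PROTON_MASS
    raise ValueError(f"species must be 'neutral' or 'protonated', got {species!r}")


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass deviation (observed − theoretical) in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def rdb(comp: ElementalComposition | str) -> float:
    """Rings-plus-double-bonds equivalent: C − H/2 + N/2 + 1.

    O and S contribute zero; trivalent P counts like N.
    """
    if isinstance(comp, str):
        comp = parse_formula(comp)
    return comp["C"] - comp["H"] / 2.0 + (comp["N"] + comp["P"]) / 2.0 + 1.0


@dataclass(frozen=True)
class EnumerationConstraints:
    """Search bounds for CHNO formula enumeration of protonated adduct ions.

    Minimum C/O/N counts reflect that a nucleoside adduct retains the sugar
    and base skeleton; defaults are min C 9, O 3, N 2 at charge 1 and 5 ppm.
    """

    min_c: int = 9
    min_o: int = 3
    min_n: int = 2
    min_h: int = 0
    max_c: int = 40
    max_h: int = 80
    max_n: int = 12
    max_o: int = 20
    charge: int = 1
    ppm_tol: float = 5.0
    require_integer_rdb: bool = True

    def __post_init__(self) -> None:
        if self.min_c > self.max_c or self.min_o > self.max_o or self.min_n > self.max_n:
            raise ValueError("min element count exceeds max")
        if self.charge != 1:
            raise ValueError("only singly protonated species are supported")
        if self.ppm_tol <= 0:
            raise ValueError("ppm_tol must be positive")


@dataclass(frozen=True)
class AnnotationResult:
    composition: ElementalComposition
    theoretical_mz: float
    delta_ppm: float
    rdb: float


def enumerate_compositions(
    target_mz: float,
    constraints: EnumerationConstraints = EnumerationConstraints(),
    species: str = "protonated",
) -> list[AnnotationResult]:
    """All CHNO neutral compositions whose [M+H]+ m/z falls within tolerance.

    The hydrogen count is solved directly from the residual mass for each
    (C, N, O) triple, so the search is O(#C x #N x #O). Candidates with
    negative rings-plus-double-bonds are discarded; with
    ``require_integer_rdb`` (default) half-integer RDB candidates — which for
    an even-electron protonated CHNO ion violate nitrogen-rule parity — are
    discarded as well. Results are ranked by absolute ppm deviation.
    """
    if species != "protonated":
        raise ValueError("only protonated species enumeration is supported")
    c = constraints
    neutral_target = target_mz - PROTON_MASS
    tol_da = c.ppm_tol * 1e-6 * target_mz
    m_c, m_h = MONOISOTOPIC_MASS["C"], MONOISOTOPIC_MASS["H"]
    m_n, m_o = MONOISOTOPIC_MASS["N"], MONOISOTOPIC_MASS["O"]

    results: list[AnnotationResult] = []
    for nc in range(c.min_c, c.max_c + 1):
        base_c = nc * m_c
        if base_c > neutral_target + tol_da:
            break
        for nn in range(c.min_n, c.max_n + 1):
            base_cn = base_c + nn * m_n
            if base_cn > neutral_target + tol_da:
                break
            for no in range(c.min_o, c.max_o + 1):
                residual = neutral_target - base_cn - no * m_o
                if residual < c.min_h * m_h - tol_da:
                    break
                # nearest hydrogen counts that could fall within tolerance
                nh0 = int(round(residual / m_h))
                for nh in (nh0 - 1, nh0, nh0 + 1):
                    if nh < c.min_h or nh > c.max_h:
                        continue
                    mass = base_cn + no * m_o + nh * m_h
                    if abs(mass - neutral_target) > tol_da:
                        continue
                    comp = ElementalComposition(
                        {"C": nc, "H": nh, "N": nn, "O": no}
                    )
                    r = rdb(comp)
                    if r < 0:
                        continue
                    if c.require_integer_rdb and abs(r - round(r)) > 1e-9:
                        continue
                    theo = mass + PROTON_MASS
                    results.append(
                        AnnotationResult(comp, theo, ppm_error(target_mz, theo), r)
                    )
    results.sort(key=lambda a: abs(a.delta_ppm))
    return results
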