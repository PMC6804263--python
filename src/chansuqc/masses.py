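"""Monoisotopic mass and m/z arithmetic for small-molecule annotation.

Every annotation decision downstream rests on accurate-mass comparisons
between theoretical ions and high-resolution Q-TOF measurements, so this
module owns the element mass table, molecular-formula parsing, adduct m/z
computation and the ppm error metric used throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "Formula",
    "parse_formula",
    "hill_string",
    "formula_add",
    "formula_sub",
    "monoisotopic_mass",
    "Adduct",
    "M_PLUS_H",
    "mz_of",
    "cation_mz",
    "ppm_error",
    "MatchTolerance",
]

#: Monoisotopic masses of the light elements (Da), CODATA/AME values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054857990943  # Da
PROTON_MASS = 1.00727646688  # Da

#: A molecular formula: element symbol -> non-negative integer count.
Formula = dict[str, int]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string such as ``"C24H34O4"``.

    A trailing charge suffix (``+``/``-``) is accepted and ignored; charge
    is carried by :class:`Adduct` or handled by :func:`cation_mz`.

    Raises
    ------
    ValueError
        On a malformed string or an element outside the mass table.
    """
    body = text.strip().rstrip("+-")
    if not body:
        raise ValueError(f"empty formula string: {text!r}")
    counts: Formula = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(body):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        if not m.group(0):
            break
        sym, digits = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {sym!r} in formula {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(body):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return counts


def hill_string(f: Formula) -> str:
    """Canonical Hill-order string: C, H, then remaining elements A-Z."""
    parts: list[str] = []
    for sym in ("C", "H"):
        n = f.get(sym, 0)
        if n:
            parts.append(sym if n == 1 else f"{sym}{n}")
    for sym in sorted(k for k in f if k not in ("C", "H")):
        n = f[sym]
        if n:
            parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def formula_add(a: Formula, b: Formula) -> Formula:
    out = dict(a)
    for sym, n in b.items():
        out[sym] = out.get(sym, 0) + n
    return {k: v for k, v in out.items() if v}


def formula_sub(a: Formula, b: Formula) -> Formula:
    """Element-wise subtraction; negative counts are a hard error."""
    out = dict(a)
    for sym, n in b.items():
        out[sym] = out.get(sym, 0) - n
        if out[sym] < 0:
            raise ValueError(
                f"subtraction gives negative {sym} count: {hill_string(a)} - {hill_string(b)}"
            )
    return {k: v for k, v in out.items() if v}


def monoisotopic_mass(f: Formula | str) -> float:
    """Neutral monoisotopic mass in Da (empty formula -> 0)."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(n * MONOISOTOPIC_MASS[sym] for sym, n in f.items())


@dataclass(frozen=True)
class Adduct:
    """An ionisation adduct: ``m/z = (M + delta - z * m_e) / |z|``."""

    label: str
    delta: float  # Da added to the neutral, as neutral atoms
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")


#: Protonation, the only adduct the positive-mode workflow uses.
M_PLUS_H = Adduct("[M+H]+", MONOISOTOPIC_MASS["H"], +1)


def mz_of(f: Formula | str, adduct: Adduct = M_PLUS_H) -> float:
    """Theoretical m/z of a neutral formula under an adduct.

    The electron mass is accounted once per unit charge, so
    ``mz_of("C24H34O4")`` gives 387.2530 for protonated bufalin.
    """
    neutral = monoisotopic_mass(f)
    return (neutral + adduct.delta - adduct.charge * ELECTRON_MASS) / abs(adduct.charge)


def cation_mz(f: Formula | str, charge: int = 1) -> float:
    """m/z of a formula that already denotes the cation (e.g. C10H10NO+)."""
    if charge <= 0:
        raise ValueError("cation charge must be positive")
    return (monoisotopic_mass(f) - charge * ELECTRON_MASS) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass accuracy in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class MatchTolerance:
    """ppm tolerance with an absolute floor for low-m/z ions.

    The floor matters below ~500 Da where a few-ppm window is tighter than
    the measured scatter of small diagnostic ions.
    """

    ppm: float = 10.0
    floor_da: float = 0.005

    def __post_init__(self) -> None:
        if self.ppm <= 0:
            raise ValueError("ppm tolerance must be > 0")
        if self.floor_da < 0:
            raise ValueError("absolute floor must be >= 0")

    def window(self, mz: float) -> float:
        """Half-width of the acceptance window at a given m/z, in Da."""
        return max(self.ppm * 1e-6 * mz, self.floor_da)

    def matches(self, observed: float, theoretical: float) -> bool:
        return abs(observed - theoretical) <= self.window(theoretical)


#: Precursor matching follows the instrument's calibration spec.
PRECURSOR_TOLERANCE = MatchTolerance(ppm=5.0, floor_da=0.0)
#: Product-ion matching is looser and floored for low-mass ions.
FRAGMENT_TOLERANCE = MatchTolerance(ppm=10.0, floor_da=0.005)
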