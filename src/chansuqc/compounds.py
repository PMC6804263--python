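"""Compound knowledge base for Chansu (toad venom) constituents.

The packaged database covers the compounds the venom workflow identifies in
the 296 nm fingerprint and by Q-TOF MS/MS: free amino acids and their
dicarboxylic-acid conjugates, indole alkaloids of the serotonin family,
free bufadienolides (bufogenins) and C-3 conjugated bufadienolides
(bufotoxins).  Conjugate mass arithmetic (argininyl diacid, oxalate,
sulfate) lives here because annotation and classification both depend on it.

Formulas for a few minor fingerprint constituents whose exact substitution
is not settled in the literature (hellebrigenol-9,11-ene, resibufaginol,
cinobufaginol) are derived from their parents by standard condensation /
oxidation arithmetic and are marked tentative in the CSV ordering only.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .masses import (
    Adduct,
    Formula,
    M_PLUS_H,
    MatchTolerance,
    formula_add,
    formula_sub,
    hill_string,
    monoisotopic_mass,
    mz_of,
    parse_formula,
    ppm_error,
)

__all__ = [
    "CompoundRecord",
    "CompoundClass",
    "load_compound_db",
    "conjugate_formula",
    "moiety_formula",
    "DIACID_NAMES",
    "lookup_by_mz",
    "MzMatch",
]

COMPOUND_CLASSES = ("amino_acid", "alkaloid", "bufogenin", "bufotoxin", "other")
CompoundClass = str

#: Dicarboxylic-acid homolog names indexed by the number of CH2 units
#: between the two carboxyls (C4..C11 diacids).
DIACID_NAMES = {
    2: "succinyl",
    3: "glutaryl",
    4: "adipyl",
    5: "pimeloyl",
    6: "suberoyl",
    7: "azelayl",
    8: "sebacyl",
    9: "undecanedioyl",
}

ARGININE = parse_formula("C6H14N4O2")
WATER = parse_formula("H2O")

_DIACID_TAG = re.compile(r"^argininyl_diacid\((\d+)\)$")

#: Substituent tags that count as steroid hydroxyls for the dehydration
#: ladder (the 14,15-epoxide contributes no water loss).
HYDROXYL_TAGS = frozenset({"3_OH", "5_OH", "11_OH", "12_OH", "14_OH", "16_OH"})


@dataclass(frozen=True)
class CompoundRecord:
    """One knowledge-base entry.

    ``substituents`` uses positional tags (``3_OH``, ``16_OAc``,
    ``14_15_epoxy``, ``19_CHO``, ``19_CH2OH``, ``indole_5_OH``,
    ``alkylamine_side_chain``, ``argininyl_diacid(n)``, ``oxalate``,
    ``sulfate``); ``parent_id`` links a bufotoxin to its aglycone.
    """

    id: str
    name: str
    cls: CompoundClass
    neutral_formula: Formula
    substituents: frozenset[str] = field(default_factory=frozenset)
    parent_id: Optional[str] = None
    fingerprint_peak: Optional[str] = None
    reference_rt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cls not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class {self.cls!r}")
        if self.cls == "bufotoxin":
            if self.parent_id is None:
                raise ValueError(f"bufotoxin {self.id!r} lacks a parent bufogenin")
            if not any(
                _DIACID_TAG.match(t) or t in ("oxalate", "sulfate")
                for t in self.substituents
            ):
                raise ValueError(f"bufotoxin {self.id!r} lacks a conjugate tag")

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.neutral_formula)

    @property
    def formula_string(self) -> str:
        return hill_string(self.neutral_formula)

    def hydroxyl_count(self) -> int:
        return len(self.substituents & HYDROXYL_TAGS)

    def conjugate_tag(self) -> Optional[str]:
        for t in self.substituents:
            if _DIACID_TAG.match(t) or t in ("oxalate", "sulfate"):
                return t
        return None


def moiety_formula(tag: str) -> Formula:
    """Neutral formula of a C-3 conjugation moiety before condensation.

    ``argininyl_diacid(n)`` is arginine amide-linked to the
    HOOC-(CH2)n-COOH homolog (one condensation already internal);
    ``oxalate`` and ``sulfate`` are the free acids.
    """
    m = _DIACID_TAG.match(tag)
    if m:
        n = int(m.group(1))
        if n not in DIACID_NAMES:
            raise ValueError(f"unsupported diacid homolog n={n}")
        diacid = {"C": n + 2, "H": 2 * n + 2, "O": 4}
        return formula_sub(formula_add(ARGININE, diacid), WATER)
    if tag == "oxalate":
        return parse_formula("C2H2O4")
    if tag == "sulfate":
        return parse_formula("H2SO4")
    raise ValueError(f"unsupported conjugation moiety {tag!r}")


def conjugate_formula(parent: CompoundRecord, moiety: str) -> Formula:
    """Neutral formula of the C-3 conjugate of a bufogenin.

    Condensation chemistry: parent + moiety - H2O, e.g. bufalin (C24H34O4)
    + argininyl_diacid(6) -> bufalitoxin (C38H58N4O8).
    """
    if parent.cls != "bufogenin":
        raise ValueError(
            f"conjugation parent must be a bufogenin, got {parent.cls!r} ({parent.id})"
        )
    return formula_sub(formula_add(parent.neutral_formula, moiety_formula(moiety)), WATER)


def _parse_rt(text: str) -> Optional[float]:
    return float(text) if text.strip() else None


def load_compound_db(path: Optional[str | Path] = None) -> list[CompoundRecord]:
    """Load the compound database (packaged fixture when ``path`` is None)."""
    if path is None:
        source = resources.files("chansuqc.data").joinpath("compounds.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    records: list[CompoundRecord] = []
    for row in csv.DictReader(text.splitlines()):
        tags = frozenset(t for t in row["substituents"].split(";") if t)
        records.append(
            CompoundRecord(
                id=row["id"],
                name=row["name"],
                cls=row["class"],
                neutral_formula=parse_formula(row["formula"]),
                substituents=tags,
                parent_id=row["parent_id"] or None,
                fingerprint_peak=row.get("fingerprint_peak") or None,
                reference_rt=_parse_rt(row.get("reference_rt", "")),
            )
        )
    if not records:
        raise ValueError("empty compound database")
    return records


@dataclass(frozen=True)
class MzMatch:
    record: CompoundRecord
    adduct: Adduct
    theoretical_mz: float
    ppm: float


def lookup_by_mz(
    db: Iterable[CompoundRecord],
    observed_mz: float,
    adducts: Iterable[Adduct] = (M_PLUS_H,),
    tol: MatchTolerance = MatchTolerance(ppm=5.0, floor_da=0.0),
) -> list[MzMatch]:
    """All records whose theoretical adduct m/z falls within tolerance.

    Sorted by |ppm error|, ties broken by record id then adduct label, so
    the result is invariant under database record order.
    """
    adducts = tuple(adducts)
    out: list[MzMatch] = []
    for rec in db:
        for adduct in adducts:
            theo = mz_of(rec.neutral_formula, adduct)
            if tol.matches(observed_mz, theo):
                out.append(MzMatch(rec, adduct, theo, ppm_error(observed_mz, theo)))
    out.sort(key=lambda m: (abs(m.ppm), m.record.id, m.adduct.label))
    return out
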