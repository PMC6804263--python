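"""Rule-based MS/MS annotation of toad-venom chemotypes.

The four venom chemotypes fragment in characteristic ways under positive
ESI-CID, and those regularities are encoded here as a small rule grammar
instead of a combinatorial bond-breaking fragmenter:

* bufogenins — a dehydration ladder (one water per steroid hydroxyl),
  substituent-specific neutral losses (CO for a 19-formyl, HCHO for a
  19-hydroxymethyl, acetic acid for a 16-acetoxyl) and elimination of the
  C-17 alpha-pyrone ring (C5H4O2) once at least two waters are gone;
* bufotoxins — loss of the C-3 conjugate moiety regenerating the protonated
  aglycone and its ladder, plus the protonated-moiety diagnostic (e.g.
  suberoyl arginine at m/z 331.198) and the arginine ion series;
* acyl arginines — diacid loss to protonated arginine and the arginine
  series (175.119 / 158.092 / 112.087 / 70.065);
* indole alkaloids — alpha-cleavage loss of the alkylamine side chain to
  the common C10H10NO+ ion at m/z 160.0757 (or its 5-O-sulfate analog).

Fragment intensities are carried for reporting but never scored: the
workflow reasons on accurate m/z only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .compounds import (
    CompoundRecord,
    DIACID_NAMES,
    MzMatch,
    lookup_by_mz,
    moiety_formula,
)
from .masses import (
    Adduct,
    FRAGMENT_TOLERANCE,
    M_PLUS_H,
    MatchTolerance,
    PRECURSOR_TOLERANCE,
    cation_mz,
    monoisotopic_mass,
    mz_of,
    parse_formula,
    ppm_error,
)

__all__ = [
    "ProductIonSpectrum",
    "PredictedFragment",
    "predict_fragments",
    "match_fragments",
    "FragmentMatch",
    "AnnotationResult",
    "ScoreWeights",
    "annotate_spectrum",
    "classify_spectrum",
    "ClassEvidence",
    "PolarityModel",
    "rank_isomers",
    "IsomerAssignment",
    "SCAN_RANGE",
]

#: Q-TOF product-ion scan range (Da).
SCAN_RANGE = (50.0, 1500.0)

_WATER = monoisotopic_mass("H2O")
_CO = monoisotopic_mass("CO")
_HCHO = monoisotopic_mass("CH2O")
_HOAC = monoisotopic_mass("C2H4O2")
_PYRONE = monoisotopic_mass("C5H4O2")
_NH3 = monoisotopic_mass("NH3")

#: Arginine immonium/related ion series (cation m/z), seen for free and
#: conjugated arginine alike.
ARGININE_SERIES = {
    "ArgH+": mz_of("C6H14N4O2"),
    "ArgH+-NH3": cation_mz("C6H12N3O2"),
    "C5H10N3+": cation_mz("C5H10N3"),
    "C4H8N+": cation_mz("C4H8N"),
}

#: Indole side-chain-loss diagnostic cations.
INDOLE_ION = cation_mz("C10H10NO")
INDOLE_SULFATE_ION = cation_mz("C10H10NO4S")

_DIACID_TAG = re.compile(r"^argininyl_diacid\((\d+)\)$")


@dataclass
class ProductIonSpectrum:
    """A product-ion (MS/MS) spectrum with its chromatographic context."""

    precursor_mz: float
    charge: int = 1
    rt_min: Optional[float] = None
    peaks: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    title: str = ""

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if len(self.peaks):
            order = np.argsort(self.peaks[:, 0])
            self.peaks = self.peaks[order]
            if np.any(self.peaks[:, 1] < 0):
                raise ValueError("negative fragment intensity")

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


@dataclass(frozen=True)
class PredictedFragment:
    mz: float
    label: str
    rule: str  # provenance: which rule produced it


def _dedupe(frags: list[PredictedFragment]) -> list[PredictedFragment]:
    out: list[PredictedFragment] = []
    for f in sorted(frags, key=lambda f: (f.mz, f.label)):
        if out and abs(f.mz - out[-1].mz) < 1e-6:
            continue
        if SCAN_RANGE[0] <= f.mz <= SCAN_RANGE[1]:
            out.append(f)
    return out


def _bufogenin_fragments(rec: CompoundRecord, prec: float) -> list[PredictedFragment]:
    n_oh = rec.hydroxyl_count()
    losses: list[tuple[float, str]] = [(0.0, "")]
    if "19_CHO" in rec.substituents:
        losses.append((_CO, "-CO"))
    if "19_CH2OH" in rec.substituents:
        losses.append((_HCHO, "-HCHO"))
    if "16_OAc" in rec.substituents:
        losses.append((_HOAC, "-HOAc"))
    frags = [PredictedFragment(prec, "[M+H]+", "precursor")]
    for sub_loss, sub_label in losses:
        for k in range(0, n_oh + 1):
            if k == 0 and not sub_label:
                continue
            label = f"[M+H{'-%dH2O' % k if k else ''}{sub_label}]+"
            rule = "substituent_loss" if sub_label else "dehydration"
            frags.append(PredictedFragment(prec - k * _WATER - sub_loss, label, rule))
        for k in range(2, n_oh + 1):
            frags.append(
                PredictedFragment(
                    prec - k * _WATER - sub_loss - _PYRONE,
                    f"[M+H-{k}H2O{sub_label}-C5H4O2]+",
                    "pyrone_elimination",
                )
            )
    return frags


def _acyl_arginine_fragments(rec: CompoundRecord, prec: float) -> list[PredictedFragment]:
    frags = [
        PredictedFragment(prec, "[M+H]+", "precursor"),
        PredictedFragment(prec - _NH3, "[M+H-NH3]+", "amine_loss"),
        PredictedFragment(prec - _NH3 - _WATER, "[M+H-NH3-H2O]+", "amine_loss"),
    ]
    for label, mz in ARGININE_SERIES.items():
        frags.append(PredictedFragment(mz, label, "arginine_series"))
    return frags


def _alkaloid_fragments(rec: CompoundRecord, prec: float) -> list[PredictedFragment]:
    frags = [PredictedFragment(prec, "[M+H]+", "precursor")]
    ion = INDOLE_SULFATE_ION if "indole_5_OSO3" in rec.substituents else INDOLE_ION
    frags.append(PredictedFragment(ion, "indole_core+", "side_chain_loss"))
    return frags


def _bufotoxin_fragments(
    rec: CompoundRecord, prec: float, db_by_id: Optional[dict[str, CompoundRecord]]
) -> list[PredictedFragment]:
    tag = rec.conjugate_tag()
    assert tag is not None
    moiety = moiety_formula(tag)
    moiety_mass = monoisotopic_mass(moiety)
    aglycone_prec = prec - (moiety_mass - _WATER)  # neutral loss of condensed moiety
    frags = [
        PredictedFragment(prec, "[M+H]+", "precursor"),
        PredictedFragment(prec - _WATER, "[M+H-H2O]+", "dehydration"),
        PredictedFragment(aglycone_prec, "[aglycone+H]+", "moiety_loss"),
    ]
    if _DIACID_TAG.match(tag):
        frags.append(PredictedFragment(mz_of(moiety), "[moiety+H]+", "moiety_ion"))
        for label, mz in ARGININE_SERIES.items():
            frags.append(PredictedFragment(mz, label, "arginine_series"))
    # the regenerated aglycone fragments like the free bufogenin
    parent = db_by_id.get(rec.parent_id) if db_by_id and rec.parent_id else None
    if parent is not None:
        for f in _bufogenin_fragments(parent, aglycone_prec):
            if f.rule != "precursor":
                frags.append(PredictedFragment(f.mz, "aglycone:" + f.label, f.rule))
    return frags


def predict_fragments(
    rec: CompoundRecord,
    adduct: Adduct = M_PLUS_H,
    db: Optional[Sequence[CompoundRecord]] = None,
) -> list[PredictedFragment]:
    """Forward-predict the product-ion set of a compound under the grammar.

    ``db`` is only needed for bufotoxins, whose regenerated aglycone
    fragments according to its own (parent) record.
    """
    prec = mz_of(rec.neutral_formula, adduct)
    if rec.cls == "bufogenin":
        frags = _bufogenin_fragments(rec, prec)
    elif rec.cls == "bufotoxin":
        db_by_id = {r.id: r for r in db} if db else None
        frags = _bufotoxin_fragments(rec, prec, db_by_id)
    elif rec.cls == "amino_acid":
        if rec.conjugate_tag() is None and rec.id != "arginine":
            frags = [PredictedFragment(prec, "[M+H]+", "precursor")]
        else:
            frags = _acyl_arginine_fragments(rec, prec)
    elif rec.cls == "alkaloid":
        frags = _alkaloid_fragments(rec, prec)
    else:
        raise ValueError(f"no fragmentation rules for class {rec.cls!r}")
    return _dedupe(frags)


@dataclass(frozen=True)
class FragmentMatch:
    predicted: PredictedFragment
    observed_mz: float
    observed_intensity: float
    delta_mda: float


def match_fragments(
    predicted: Sequence[PredictedFragment],
    spectrum: ProductIonSpectrum,
    tol: MatchTolerance = FRAGMENT_TOLERANCE,
) -> list[FragmentMatch]:
    """Greedy nearest-m/z matching; each observed peak is used at most once."""
    if not len(spectrum.peaks):
        return []
    used: set[int] = set()
    matches: list[FragmentMatch] = []
    mzs = spectrum.mz
    for pred in sorted(predicted, key=lambda p: p.mz):
        window = tol.window(pred.mz)
        idx = np.searchsorted(mzs, pred.mz)
        best, best_d = -1, np.inf
        for j in (idx - 1, idx):
            if 0 <= j < len(mzs) and j not in used:
                d = abs(mzs[j] - pred.mz)
                if d <= window and d < best_d:
                    best, best_d = j, d
        # scan outward for nearest unused within window
        j = idx - 2
        while j >= 0 and pred.mz - mzs[j] <= window:
            if j not in used and abs(mzs[j] - pred.mz) < best_d:
                best, best_d = j, abs(mzs[j] - pred.mz)
            j -= 1
        j = idx + 1
        while j < len(mzs) and mzs[j] - pred.mz <= window:
            if j not in used and abs(mzs[j] - pred.mz) < best_d:
                best, best_d = j, abs(mzs[j] - pred.mz)
            j += 1
        if best >= 0:
            used.add(best)
            matches.append(
                FragmentMatch(pred, mzs[best], spectrum.intensity[best], (mzs[best] - pred.mz) * 1e3)
            )
    return matches


@dataclass(frozen=True)
class ScoreWeights:
    precursor: float = 0.3
    fragments: float = 0.5
    diagnostics: float = 0.2


@dataclass
class AnnotationResult:
    record: CompoundRecord
    score: float
    precursor_ppm: float
    precursor_score: float
    fragment_score: float
    diagnostic_score: Optional[float]
    matches: list[FragmentMatch]
    diagnostic_matches: list[FragmentMatch]
    assigned_class: str


def _class_diagnostics(rec: CompoundRecord) -> list[PredictedFragment]:
    """Class-indicating ions the candidate's spectrum is expected to show."""
    if rec.cls == "alkaloid":
        ion = INDOLE_SULFATE_ION if "indole_5_OSO3" in rec.substituents else INDOLE_ION
        return [PredictedFragment(ion, "indole_core+", "diagnostic")]
    if rec.cls == "amino_acid" and (rec.conjugate_tag() or rec.id == "arginine"):
        return [PredictedFragment(ARGININE_SERIES["ArgH+"], "ArgH+", "diagnostic")]
    if rec.cls == "bufotoxin":
        tag = rec.conjugate_tag()
        if tag and _DIACID_TAG.match(tag):
            return [PredictedFragment(mz_of(moiety_formula(tag)), "[moiety+H]+", "diagnostic")]
    return []


def annotate_spectrum(
    spectrum: ProductIonSpectrum,
    db: Sequence[CompoundRecord],
    precursor_tol: MatchTolerance = PRECURSOR_TOLERANCE,
    fragment_tol: MatchTolerance = FRAGMENT_TOLERANCE,
    weights: ScoreWeights = ScoreWeights(),
    polarity: Optional["PolarityModel"] = None,
) -> list[AnnotationResult]:
    """Score every database candidate within precursor tolerance.

    score = w_p (1 - |ppm|/tol) + w_f (matched / predicted) + w_d
    (matched diagnostics / expected); when a class has no diagnostics the
    diagnostic weight is folded into the fragment term.  Ties are broken
    by polarity/RT consistency (more polar candidates earlier) and then
    record id, so output order is deterministic.
    """
    candidates = lookup_by_mz(db, spectrum.precursor_mz, (M_PLUS_H,), precursor_tol)
    polarity = polarity or PolarityModel()
    results: list[AnnotationResult] = []
    for cand in candidates:
        preds = predict_fragments(cand.record, M_PLUS_H, db)
        matches = match_fragments(preds, spectrum, fragment_tol)
        frag_score = len(matches) / len(preds) if preds else 0.0
        diags = _class_diagnostics(cand.record)
        diag_matches = match_fragments(diags, spectrum, fragment_tol)
        prec_score = max(0.0, 1.0 - abs(cand.ppm) / precursor_tol.ppm)
        if diags:
            diag_score: Optional[float] = len(diag_matches) / len(diags)
            total = (
                weights.precursor * prec_score
                + weights.fragments * frag_score
                + weights.diagnostics * diag_score
            )
        else:
            diag_score = None
            total = (
                weights.precursor * prec_score
                + (weights.fragments + weights.diagnostics) * frag_score
            )
        results.append(
            AnnotationResult(
                record=cand.record,
                score=total,
                precursor_ppm=cand.ppm,
                precursor_score=prec_score,
                fragment_score=frag_score,
                diagnostic_score=diag_score,
                matches=matches,
                diagnostic_matches=diag_matches,
                assigned_class=cand.record.cls,
            )
        )

    def _tiebreak(r: AnnotationResult) -> tuple:
        # polarity/RT consistency: when the spectrum has an RT and the
        # candidate a reference RT, smaller |deltaRT| wins
        if spectrum.rt_min is not None and r.record.reference_rt is not None:
            rt_pen = abs(spectrum.rt_min - r.record.reference_rt)
        else:
            rt_pen = np.inf
        return (-r.score, rt_pen, r.record.id)

    results.sort(key=_tiebreak)
    return results


# ---------------------------------------------------------------------------
# chemotype classification


@dataclass
class ClassEvidence:
    assigned: str
    evidence: list[str]


def _has_peak(spectrum: ProductIonSpectrum, mz: float, tol: MatchTolerance) -> bool:
    if not len(spectrum.peaks):
        return False
    i = np.searchsorted(spectrum.mz, mz)
    for j in (i - 1, i):
        if 0 <= j < len(spectrum.mz) and abs(spectrum.mz[j] - mz) <= tol.window(mz):
            return True
    return False


#: Condensed-moiety neutral losses that flag a C-3 conjugate.
_CONJUGATE_LOSSES = {
    f"argininyl_diacid({n})": monoisotopic_mass(moiety_formula(f"argininyl_diacid({n})")) - _WATER
    for n in DIACID_NAMES
}
_CONJUGATE_LOSSES["oxalate"] = monoisotopic_mass(parse_formula("C2H2O4")) - _WATER
_CONJUGATE_LOSSES["sulfate"] = monoisotopic_mass(parse_formula("H2SO4")) - _WATER


def classify_spectrum(
    spectrum: ProductIonSpectrum,
    tol: MatchTolerance = FRAGMENT_TOLERANCE,
) -> ClassEvidence:
    """Assign a chemotype from diagnostic evidence alone (no database).

    Decision order: conjugate loss (bufotoxin) > indole core ion
    (alkaloid) > arginine series below the steroid mass range
    (amino acid) > dehydration ladder, with the pyrone elimination as
    supporting evidence (bufogenin) > unknown.
    """
    prec = spectrum.precursor_mz
    evidence: list[str] = []
    # bufotoxin: precursor loses a condensed conjugation moiety to a
    # steroid-range aglycone ion
    for tag, loss in _CONJUGATE_LOSSES.items():
        aglycone = prec - loss
        if aglycone > 300 and _has_peak(spectrum, aglycone, tol):
            evidence.append(f"neutral loss of {tag} moiety -> m/z {aglycone:.4f}")
            return ClassEvidence("bufotoxin", evidence)
    for name, ion in (("C10H10NO+", INDOLE_ION), ("C10H10NO4S+", INDOLE_SULFATE_ION)):
        if _has_peak(spectrum, ion, tol):
            evidence.append(f"indole core ion {name} at m/z {ion:.4f}")
            return ClassEvidence("alkaloid", evidence)
    if prec < 400 and _has_peak(spectrum, ARGININE_SERIES["ArgH+"], tol):
        evidence.append("arginine series without steroid-range precursor")
        return ClassEvidence("amino_acid", evidence)
    n_waters = 0
    while _has_peak(spectrum, prec - (n_waters + 1) * _WATER, tol):
        n_waters += 1
    pyrone = any(
        _has_peak(spectrum, prec - k * _WATER - _PYRONE, tol) for k in range(2, n_waters + 1)
    )
    if n_waters >= 1 and prec > 350:
        evidence.append(f"dehydration ladder ({n_waters} waters)")
        if pyrone:
            evidence.append("alpha-pyrone elimination")
        return ClassEvidence("bufogenin", evidence)
    return ClassEvidence("unknown", evidence)


# ---------------------------------------------------------------------------
# isomer ranking by the polarity-retention heuristic


@dataclass(frozen=True)
class PolarityModel:
    """Substituent polarity weights for reversed-phase elution order.

    Only the 5-OH > 16-OH ordering is established for these compounds;
    the 5 > 11 > 12 > 16 position order with unit gaps is a documented
    heuristic default and fully configurable.
    """

    weights: tuple[tuple[str, float], ...] = (
        ("5_OH", 4.0),
        ("11_OH", 3.0),
        ("12_OH", 2.0),
        ("16_OH", 1.0),
    )

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if "5_OH" in w and "16_OH" in w and not w["5_OH"] > w["16_OH"]:
            raise ValueError("polarity model must keep 5-OH more polar than 16-OH")

    def score(self, rec: CompoundRecord) -> float:
        w = dict(self.weights)
        return sum(w.get(tag, 0.0) for tag in rec.substituents)


@dataclass
class IsomerAssignment:
    assignments: list[tuple[CompoundRecord, float]]  # (record, assigned RT)
    resolved: bool
    note: str = ""


def rank_isomers(
    candidates: Sequence[CompoundRecord],
    peak_rts: Sequence[float],
    model: PolarityModel = PolarityModel(),
) -> IsomerAssignment:
    """Assign isomeric candidates to RT-ordered peaks.

    Reversed-phase convention: the most polar candidate elutes first.
    Equal polarity scores are flagged unresolved rather than silently
    ordered.
    """
    if len(candidates) != len(peak_rts):
        raise ValueError("candidate and peak counts differ")
    scores = [model.score(c) for c in candidates]
    order = sorted(range(len(candidates)), key=lambda i: (-scores[i], candidates[i].id))
    rts = sorted(peak_rts)
    assignments = [(candidates[i], rt) for i, rt in zip(order, rts)]
    resolved = len(set(scores)) == len(scores)
    note = "" if resolved else "tied polarity scores; assignment not resolved"
    return IsomerAssignment(assignments, resolved, note)
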