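"""Calibration, LOD/LOQ, content computation and method-validation statistics.

Contents are expressed in mg analyte per g dried venom.  The default
sample preparation (60 mg powder refluxed into 20 mL methanol) makes the
back-calculated concentration in ug/mL convert to mg/g by a factor of
volume/mass = 1/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "load_calibration_table",
    "lod_loq",
    "SamplePrep",
    "quantify",
    "BatchContentTable",
    "load_batch_contents",
    "ContentSummary",
    "summarize_contents",
    "ValidationReport",
    "validation_stats",
]


@dataclass
class CalibrationCurve:
    """A linear response curve (peak area vs concentration in ug/mL)."""

    analyte: str
    slope: float
    intercept: float
    r2: float
    range_ug_ml: tuple[float, float]
    lod_ug_ml: Optional[float] = None
    loq_ug_ml: Optional[float] = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if self.range_ug_ml[0] <= 0 or self.range_ug_ml[1] <= self.range_ug_ml[0]:
            raise ValueError("invalid linear range")
        if self.lod_ug_ml is not None and self.loq_ug_ml is not None:
            if not (self.loq_ug_ml >= self.lod_ug_ml > 0):
                raise ValueError("need LOQ >= LOD > 0")

    def predict_area(self, conc: float | np.ndarray) -> float | np.ndarray:
        return self.slope * conc + self.intercept

    def back_calculate(self, area: float | np.ndarray) -> float | np.ndarray:
        return (area - self.intercept) / self.slope


def fit_calibration(
    conc_ug_ml: Sequence[float], area: Sequence[float], analyte: str = ""
) -> CalibrationCurve:
    """Ordinary least-squares calibration; R^2 is the squared Pearson r."""
    x = np.asarray(conc_ug_ml, float)
    y = np.asarray(area, float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in concentrations")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        range_ug_ml=(float(x.min()), float(x.max())),
    )


def load_calibration_table(path: Optional[str | Path] = None) -> dict[str, CalibrationCurve]:
    """Validated response curves for the seven quantitation markers.

    The packaged table carries the slope/intercept/R^2, linear range and
    LOD/LOQ of each marker bufogenin as established on the HPLC-DAD method.
    """
    if path is None:
        text = resources.files("chansuqc.data").joinpath("calibration_curves.csv").read_text()
    else:
        text = Path(path).read_text()
    df = pd.read_csv(StringIO(text))
    out: dict[str, CalibrationCurve] = {}
    for _, r in df.iterrows():
        out[r["analyte"]] = CalibrationCurve(
            analyte=r["analyte"],
            slope=r["slope"],
            intercept=r["intercept"],
            r2=r["r2"],
            range_ug_ml=(r["range_low_ug_ml"], r["range_high_ug_ml"]),
            lod_ug_ml=r["lod_ug_ml"],
            loq_ug_ml=r["loq_ug_ml"],
        )
    return out


def lod_loq(
    conc_ug_ml: Sequence[float], snr: Sequence[float]
) -> tuple[float, float]:
    """Concentrations at S/N = 3 (LOD) and S/N = 10 (LOQ).

    Linear interpolation between the bracketing dilution levels; S/N is
    peak height over baseline noise SD and must be non-decreasing in
    concentration.
    """
    c = np.asarray(conc_ug_ml, float)
    s = np.asarray(snr, float)
    order = np.argsort(c)
    c, s = c[order], s[order]
    if np.any(np.diff(s) < 0):
        raise ValueError("S/N must be non-decreasing in concentration")
    if not (s.min() <= 3 <= s.max()) or not (s.min() <= 10 <= s.max()):
        raise ValueError("S/N series does not bracket 3 and 10")
    lod = float(np.interp(3.0, s, c))
    loq = float(np.interp(10.0, s, c))
    return lod, loq


@dataclass(frozen=True)
class SamplePrep:
    """Extraction geometry converting solution concentration to content."""

    mass_mg: float = 60.0
    volume_ml: float = 20.0

    def __post_init__(self) -> None:
        if self.mass_mg <= 0 or self.volume_ml <= 0:
            raise ValueError("sample mass and volume must be positive")


def quantify(
    area: float,
    curve: CalibrationCurve,
    prep: SamplePrep = SamplePrep(),
    dilution: float = 1.0,
) -> float:
    """Content in mg/g from a peak area via the calibration line.

    content = c * V * dilution / m with c in ug/mL, V in mL, m in mg
    (ug/mg = mg/g).  A non-positive back-calculation is floored at zero
    with a warning; an out-of-range concentration is flagged but kept.
    """
    c = curve.back_calculate(area)
    if c <= 0:
        warnings.warn(
            f"{curve.analyte or 'analyte'}: area {area:.3g} back-calculates to "
            f"{c:.3g} ug/mL; floored to 0",
            stacklevel=2,
        )
        return 0.0
    lo, hi = curve.range_ug_ml
    if not (lo <= c <= hi):
        warnings.warn(
            f"{curve.analyte or 'analyte'}: back-calculated {c:.4g} ug/mL outside "
            f"linear range [{lo}, {hi}]",
            stacklevel=2,
        )
    return float(c * prep.volume_ml * dilution / prep.mass_mg)


@dataclass
class BatchContentTable:
    """samples x analytes content matrix (mg/g) with origin labels."""

    contents: pd.DataFrame  # index: batch id, columns: analytes
    origins: pd.Series  # index: batch id
    sds: Optional[pd.DataFrame] = None  # replicate SDs where known
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if (self.contents.values < 0).any():
            raise ValueError("negative contents")
        if self.sds is not None and (self.sds.values < 0).any():
            raise ValueError("negative SDs")


def load_batch_contents(path: Optional[str | Path] = None) -> BatchContentTable:
    """The packaged 20-batch, 5-origin, 7-analyte content table (mg/g)."""
    if path is None:
        text = resources.files("chansuqc.data").joinpath("batch_contents.csv").read_text()
    else:
        text = Path(path).read_text()
    df = pd.read_csv(StringIO(text), index_col="batch")
    analytes = [c for c in df.columns if c != "origin" and not c.endswith("_sd")]
    return BatchContentTable(
        contents=df[analytes].astype(float),
        origins=df["origin"],
        sds=df[[f"{a}_sd" for a in analytes]].rename(
            columns={f"{a}_sd": a for a in analytes}
        ).astype(float),
    )


@dataclass
class ContentSummary:
    per_analyte_rsd_pct: pd.Series
    batch_totals: pd.Series
    min_total: float
    max_total: float


def summarize_contents(t: BatchContentTable) -> ContentSummary:
    """Across-batch RSD% per analyte and per-batch totals (mg/g).

    RSD uses the sample SD (n-1) over batch means; totals sum analyte
    means per batch.  Both are permutation-invariant in analyte order.
    """
    if len(t.contents) < 2:
        raise ValueError("need at least 2 batches for an across-batch RSD")
    rsd = t.contents.std(axis=0, ddof=1) / t.contents.mean(axis=0) * 100
    totals = t.contents.sum(axis=1)
    return ContentSummary(
        per_analyte_rsd_pct=rsd,
        batch_totals=totals,
        min_total=float(totals.min()),
        max_total=float(totals.max()),
    )


@dataclass
class ValidationReport:
    intraday_rsd_pct: pd.Series
    interday_rsd_pct: pd.Series
    repeatability_rsd_pct: pd.Series
    recovery_mean_pct: pd.Series
    recovery_rsd_pct: pd.Series
    stability_rsd_pct: pd.Series


def _rsd(df: pd.DataFrame) -> pd.Series:
    if df.shape[0] < 2:
        raise ValueError("need >= 2 replicates")
    return df.std(axis=0, ddof=1) / df.mean(axis=0) * 100


def validation_stats(
    intraday: pd.DataFrame,
    interday: pd.DataFrame,
    repeatability: pd.DataFrame,
    stability: pd.DataFrame,
    recovery_base: pd.Series,
    recovery_added: pd.Series,
    recovery_measured: pd.DataFrame,
) -> ValidationReport:
    """Method-validation statistics from replicate designs.

    Each DataFrame is replicates x analytes of measured contents/areas;
    recovery% = (measured spiked - base) / added * 100 per replicate.
    """
    rec_pct = (recovery_measured - recovery_base) / recovery_added * 100
    return ValidationReport(
        intraday_rsd_pct=_rsd(intraday),
        interday_rsd_pct=_rsd(interday),
        repeatability_rsd_pct=_rsd(repeatability),
        recovery_mean_pct=rec_pct.mean(axis=0),
        recovery_rsd_pct=_rsd(rec_pct),
        stability_rsd_pct=_rsd(stability),
    )
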