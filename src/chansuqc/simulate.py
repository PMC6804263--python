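"""Seeded generators for every input the QC pipeline consumes.

The generators emulate the structure of a 20-batch, five-origin venom
study: per-batch analyte contents follow the packaged origin profiles
(group means and between-batch CVs of the seven marker bufogenins);
296 nm chromatograms are sums of Gaussian peaks on the synthetic P1-P33
retention ladder whose quantitation-marker areas follow the validated
response lines applied to the contents; MS/MS spectra are forward
applications of the fragmentation grammar with ppm-scale mass jitter and
uniform low-intensity decoy peaks.

Everything is driven by one :class:`SimulationConfig`; an identical
config yields bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import ProductIonSpectrum, predict_fragments
from .compounds import CompoundRecord, load_compound_db
from .fingerprint import Chromatogram
from .masses import M_PLUS_H, mz_of
from .quant import (
    BatchContentTable,
    CalibrationCurve,
    SamplePrep,
    load_batch_contents,
    load_calibration_table,
)

__all__ = [
    "SimulationConfig",
    "OriginProfile",
    "default_origin_profiles",
    "generate_content_table",
    "rt_ladder",
    "BACKGROUND_AREAS",
    "generate_chromatogram",
    "sample_chromatogram",
    "simulate_spectrum",
    "generate_calibration",
    "separable_two_class",
    "SyntheticDataset",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the study-scale defaults."""

    seed: int = 0
    batches_per_origin: int = 4
    replicates: int = 3
    #: chromatography
    run_minutes: float = 90.0
    grid_step_min: float = 0.01
    peak_sigma_min: float = 0.2
    baseline_noise_sd: float = 0.05  # absorbance units
    rt_jitter_sd_min: float = 0.02
    area_cv: float = 0.0  # extra multiplicative area noise on top of contents
    background_cv: float = 0.03
    #: spectra
    ppm_jitter: float = 3.0
    decoy_peaks: int = 5
    decoy_intensity: float = 2.0
    #: calibration
    calibration_levels: int = 6
    calibration_noise_cv: float = 0.005

    def __post_init__(self) -> None:
        for name in (
            "baseline_noise_sd",
            "rt_jitter_sd_min",
            "ppm_jitter",
            "area_cv",
            "background_cv",
            "calibration_noise_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class OriginProfile:
    """Per-origin content level and between-batch variability."""

    origin: str
    means_mg_g: pd.Series  # per analyte
    cvs: pd.Series  # per analyte, between-batch CV

    def __post_init__(self) -> None:
        if (self.means_mg_g < 0).any() or (self.cvs < 0).any():
            raise ValueError("means and CVs must be non-negative")


def default_origin_profiles() -> list[OriginProfile]:
    """Origin profiles derived from the packaged 20-batch content table."""
    table = load_batch_contents()
    out = []
    for origin, idx in table.contents.groupby(table.origins).groups.items():
        block = table.contents.loc[idx]
        means = block.mean(axis=0)
        out.append(
            OriginProfile(
                origin=str(origin),
                means_mg_g=means,
                cvs=(block.std(axis=0, ddof=1) / means).fillna(0.0),
            )
        )
    out.sort(key=lambda p: p.origin)
    return out


def generate_content_table(
    cfg: SimulationConfig,
    profiles: Optional[Sequence[OriginProfile]] = None,
    rng: Optional[np.random.Generator] = None,
) -> BatchContentTable:
    """Batch contents = origin mean x mean-1 lognormal noise at the origin CV."""
    profiles = list(profiles) if profiles is not None else default_origin_profiles()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    rows, origins, ids = [], [], []
    for prof in profiles:
        s = np.sqrt(np.log1p(prof.cvs.to_numpy(float) ** 2))
        for b in range(cfg.batches_per_origin):
            noise = np.exp(rng.normal(-0.5 * s**2, s))
            rows.append(prof.means_mg_g.to_numpy(float) * noise)
            origins.append(prof.origin)
            ids.append(f"{prof.origin[:2].upper()}-S{b + 1}")
    contents = pd.DataFrame(rows, index=ids, columns=profiles[0].means_mg_g.index)
    return BatchContentTable(
        contents=contents, origins=pd.Series(origins, index=ids), n_replicates=cfg.replicates
    )


def rt_ladder(db: Optional[Sequence[CompoundRecord]] = None) -> pd.Series:
    """Retention ladder: fingerprint peak label -> apex RT (min)."""
    db = db if db is not None else load_compound_db()
    pairs = {
        r.fingerprint_peak: r.reference_rt
        for r in db
        if r.fingerprint_peak and r.reference_rt is not None
    }
    return pd.Series(pairs).sort_values()


#: Areas (AU*min) of fingerprint peaks not driven by the content table.
#: The reference peak P16 is large and stable by design; the early
#: amino-acid/alkaloid region carries moderate peaks; the rest are minor.
BACKGROUND_AREAS: dict[str, float] = {
    "P1": 180.0, "P2": 120.0, "P3": 150.0, "P6": 35.0, "P7": 45.0,
    "P8": 30.0, "P9": 60.0, "P10": 70.0, "P11": 25.0, "P13": 40.0,
    "P14": 30.0, "P15": 28.0, "P16": 500.0, "P17": 65.0, "P18": 42.0,
    "P19": 24.0, "P20": 22.0, "P21": 26.0, "P22": 32.0, "P24": 55.0,
    "P26": 38.0, "P27": 30.0, "P29": 80.0, "P33": 20.0,
}

#: Quantitation markers and their fingerprint peaks.
ANALYTE_PEAKS = {
    "GB": "P12", "TBG": "P23", "BFL": "P25", "CFL": "P28",
    "BL": "P30", "CBG": "P31", "RBG": "P32",
}


def generate_chromatogram(
    peak_areas: dict[str, float],
    ladder: pd.Series,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    batch_id: str = "",
    origin: str = "",
) -> Chromatogram:
    """Sum of Gaussian peaks plus baseline noise on the synthetic ladder."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.run_minutes + cfg.grid_step_min / 2, cfg.grid_step_min)
    y = np.zeros_like(t)
    rts = sorted(float(ladder[p]) for p in peak_areas if p in ladder.index)
    if any(b - a < 4 * cfg.peak_sigma_min for a, b in zip(rts, rts[1:])):
        warnings.warn("adjacent peaks closer than 4 sigma; areas may merge", stacklevel=2)
    sigma = cfg.peak_sigma_min
    for label, area in peak_areas.items():
        if label not in ladder.index:
            raise KeyError(f"no ladder RT for peak {label!r}")
        if area <= 0:
            continue
        rt = float(ladder[label]) + rng.normal(0.0, cfg.rt_jitter_sd_min)
        y += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
    if cfg.baseline_noise_sd > 0:
        y = y + rng.normal(0.0, cfg.baseline_noise_sd, size=t.shape)
    return Chromatogram(time_min=t, signal=y, batch_id=batch_id, origin=origin)


def sample_chromatogram(
    contents: pd.Series,
    cfg: SimulationConfig,
    curves: Optional[dict[str, CalibrationCurve]] = None,
    ladder: Optional[pd.Series] = None,
    rng: Optional[np.random.Generator] = None,
    prep: SamplePrep = SamplePrep(),
    batch_id: str = "",
    origin: str = "",
) -> Chromatogram:
    """Chromatogram of one batch from its analyte contents (mg/g).

    Marker peak areas follow the validated response lines applied to the
    extract concentration implied by the sample preparation; the other
    ladder peaks carry background areas with a small multiplicative CV.
    """
    curves = curves if curves is not None else load_calibration_table()
    ladder = ladder if ladder is not None else rt_ladder()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    areas: dict[str, float] = {}
    for analyte, peak in ANALYTE_PEAKS.items():
        if analyte not in contents.index:
            continue
        conc = float(contents[analyte]) * prep.mass_mg / prep.volume_ml  # ug/mL
        area = float(curves[analyte].predict_area(conc))
        if cfg.area_cv > 0:
            area *= 1.0 + rng.normal(0.0, cfg.area_cv)
        areas[peak] = max(area, 0.0)
    for peak, base in BACKGROUND_AREAS.items():
        if peak not in ladder.index:
            continue
        mult = 1.0 + rng.normal(0.0, cfg.background_cv) if cfg.background_cv > 0 else 1.0
        areas[peak] = max(base * mult, 0.0)
    return generate_chromatogram(
        areas, ladder, cfg, rng=rng, batch_id=batch_id, origin=origin
    )


def simulate_spectrum(
    rec: CompoundRecord,
    cfg: SimulationConfig,
    db: Optional[Sequence[CompoundRecord]] = None,
    rng: Optional[np.random.Generator] = None,
) -> ProductIonSpectrum:
    """Forward-simulated product-ion spectrum of one database compound."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    preds = predict_fragments(rec, M_PLUS_H, db)
    intensity_by_rule = {
        "precursor": 55.0,
        "dehydration": 100.0,
        "pyrone_elimination": 45.0,
        "substituent_loss": 60.0,
        "moiety_loss": 80.0,
        "moiety_ion": 70.0,
        "arginine_series": 65.0,
        "side_chain_loss": 100.0,
        "amine_loss": 50.0,
    }
    mzs, ints = [], []
    for p in preds:
        jit = rng.uniform(-cfg.ppm_jitter, cfg.ppm_jitter) * 1e-6
        mzs.append(p.mz * (1.0 + jit))
        ints.append(intensity_by_rule.get(p.rule, 30.0))
    prec = mz_of(rec.neutral_formula, M_PLUS_H)
    prec_obs = prec * (1.0 + rng.uniform(-cfg.ppm_jitter, cfg.ppm_jitter) * 1e-6)
    for _ in range(cfg.decoy_peaks):
        mzs.append(rng.uniform(50.0, prec + 30.0))
        ints.append(cfg.decoy_intensity)
    return ProductIonSpectrum(
        precursor_mz=prec_obs,
        charge=1,
        rt_min=rec.reference_rt,
        peaks=np.column_stack([mzs, ints]),
        title=rec.id,
    )


def generate_calibration(
    curve: CalibrationCurve,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Triplicate areas at geometric levels over the curve's linear range.

    Levels that fall below the curve's LOD are flagged in the
    ``below_lod`` column (none do over a validated range).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lo, hi = curve.range_ug_ml
    if cfg.calibration_levels < 3:
        raise ValueError("need at least 3 levels")
    levels = np.geomspace(lo, hi, cfg.calibration_levels)
    rows = []
    for conc in levels:
        for rep in range(cfg.replicates):
            area = curve.predict_area(conc)
            if cfg.calibration_noise_cv > 0:
                area *= 1.0 + rng.normal(0.0, cfg.calibration_noise_cv)
            rows.append(
                {
                    "analyte": curve.analyte,
                    "conc_ug_ml": float(conc),
                    "area": float(area),
                    "replicate": rep + 1,
                    "below_lod": bool(
                        curve.lod_ug_ml is not None and conc < curve.lod_ug_ml
                    ),
                }
            )
    return pd.DataFrame(rows)


def separable_two_class(
    rng: np.random.Generator,
    n_per_class: int = 10,
    n_features: int = 8,
    n_informative: int = 3,
    shift: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two linearly separable classes for discriminant-model checks.

    Unit-variance noise on every feature; the second class is shifted by
    ``shift`` standard deviations on the informative features, far beyond
    the overlap region.
    """
    X = rng.normal(size=(2 * n_per_class, n_features))
    X[n_per_class:, :n_informative] += shift
    labels = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    return X, labels


@dataclass
class SyntheticDataset:
    """A complete seeded study: contents, chromatograms, spectra, calibration."""

    config: SimulationConfig
    contents: BatchContentTable
    chromatograms: list[Chromatogram]
    spectra: list[ProductIonSpectrum]
    calibration: pd.DataFrame
    ladder: pd.Series = field(default_factory=rt_ladder)


def generate_dataset(
    cfg: SimulationConfig,
    profiles: Optional[Sequence[OriginProfile]] = None,
    db: Optional[Sequence[CompoundRecord]] = None,
) -> SyntheticDataset:
    """Generate every pipeline input from one seed."""
    rng = np.random.default_rng(cfg.seed)
    db = list(db) if db is not None else load_compound_db()
    curves = load_calibration_table()
    ladder = rt_ladder(db)
    contents = generate_content_table(cfg, profiles, rng=rng)
    chroms = [
        sample_chromatogram(
            contents.contents.loc[b],
            cfg,
            curves=curves,
            ladder=ladder,
            rng=rng,
            batch_id=str(b),
            origin=str(contents.origins[b]),
        )
        for b in contents.contents.index
    ]
    spectra = [
        simulate_spectrum(rec, cfg, db=db, rng=rng)
        for rec in db
        if rec.cls in ("amino_acid", "alkaloid", "bufogenin", "bufotoxin")
    ]
    calibration = pd.concat(
        [generate_calibration(curves[a], cfg, rng=rng) for a in sorted(curves)],
        ignore_index=True,
    )
    return SyntheticDataset(
        config=cfg,
        contents=contents,
        chromatograms=chroms,
        spectra=spectra,
        calibration=calibration,
        ladder=ladder,
    )
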