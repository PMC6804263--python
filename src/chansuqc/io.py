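"""Readers/writers for the workflow's file formats and the pipeline config.

Spectra travel as MGF (Mascot generic format, via pyteomics), chromatograms
and matrices as CSV, reports as JSON with stable key order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .annotate import ProductIonSpectrum
from .fingerprint import Chromatogram

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_chromatogram",
    "write_chromatogram",
    "PipelineConfig",
    "write_json",
]


def read_spectra(path: str | Path) -> list[ProductIonSpectrum]:
    """Read product-ion spectra from an MGF file.

    RTINSECONDS is converted to minutes; a block without PEPMASS is a
    hard error naming the offending block.
    """
    out: list[ProductIonSpectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"block {i + 1}"))
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise ValueError(f"MGF block {title!r} is missing PEPMASS")
            charge = int(params["charge"][0]) if params.get("charge") else 1
            rt = params.get("rtinseconds")
            rt_min = float(rt) / 60.0 if rt is not None else None
            peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
            out.append(
                ProductIonSpectrum(
                    precursor_mz=float(params["pepmass"][0]),
                    charge=charge,
                    rt_min=rt_min,
                    peaks=peaks,
                    title=title,
                )
            )
    return out


def write_spectra(spectra: Sequence[ProductIonSpectrum], path: str | Path) -> None:
    """Write spectra as MGF (PEPMASS, CHARGE, RTINSECONDS, TITLE)."""
    entries = []
    for s in spectra:
        params = {"title": s.title, "pepmass": s.precursor_mz, "charge": s.charge}
        if s.rt_min is not None:
            params["rtinseconds"] = s.rt_min * 60.0
        entries.append(
            {
                "params": params,
                "m/z array": s.mz,
                "intensity array": s.intensity,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_chromatogram(path: str | Path, batch_id: str = "", origin: str = "") -> Chromatogram:
    """Two-column time_min,intensity CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns time_min,intensity")
    return Chromatogram(
        time_min=df.iloc[:, 0].to_numpy(float),
        signal=df.iloc[:, 1].to_numpy(float),
        batch_id=batch_id or Path(path).stem,
        origin=origin,
    )


def write_chromatogram(c: Chromatogram, path: str | Path) -> None:
    pd.DataFrame({"time_min": c.time_min, "intensity": c.signal}).to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Declarative configuration of a full workflow run."""

    seed: int = 0
    out_dir: str = "chansuqc_out"
    precursor_ppm: float = 5.0
    fragment_ppm: float = 10.0
    fragment_floor_da: float = 0.005
    reference_peak: str = "P16"
    area_fraction: float = 0.90
    similarity_method: str = "cosine"
    scaling: str = "autoscale"
    rt_tol_min: float = 0.5
    n_orthogonal: int = 1
    cv_folds: int = 7
    batches_per_origin: int = 4

    def __post_init__(self) -> None:
        for name in ("precursor_ppm", "fragment_ppm", "rt_tol_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def write_json(obj, path: str | Path) -> None:
    """JSON report writer with stable key order and numpy coercion."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="index")
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))
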