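"""HPLC fingerprint construction and similarity scoring.

A 296 nm chromatogram per batch is reduced to a peak table, peak tables
are aligned across batches on retention time, the shared peaks carrying
>= 90% of the mean total area become the characteristic set, and each
sample is summarised as relative peak areas (RPA) against a designated
reference peak.  The batch-consensus fingerprint is the component-wise
median, and each sample's similarity value (SV) to it is the cosine of
the two RPA vectors (Pearson correlation is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Chromatogram",
    "Peak",
    "PeakTable",
    "detect_peaks",
    "AlignedPeakMatrix",
    "align_peaks",
    "select_characteristic_peaks",
    "rrt_rpa",
    "FingerprintVector",
    "reference_fingerprint",
    "similarity",
    "similarity_report",
    "SimilarityReport",
    "validation_rsd",
]


@dataclass
class Chromatogram:
    """A single-wavelength detector trace on a strictly increasing time grid."""

    time_min: np.ndarray
    signal: np.ndarray
    batch_id: str = ""
    origin: str = ""

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_min.shape != self.signal.shape:
            raise ValueError("time grid and signal lengths differ")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.time_min < 0):
            raise ValueError("negative retention times")


@dataclass(frozen=True)
class Peak:
    rt: float
    area: float
    height: float


@dataclass
class PeakTable:
    """Detected peaks of one chromatogram, apexes strictly increasing."""

    peaks: list[Peak]
    batch_id: str = ""
    origin: str = ""

    def __post_init__(self) -> None:
        rts = [p.rt for p in self.peaks]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("peak apexes must be strictly increasing")
        if any(p.area <= 0 for p in self.peaks):
            raise ValueError("peak areas must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rt": [p.rt for p in self.peaks],
             "area": [p.area for p in self.peaks],
             "height": [p.height for p in self.peaks]}
        )


def detect_peaks(
    c: Chromatogram,
    min_height: Optional[float] = None,
    min_prominence: Optional[float] = None,
    noise_k: float = 10.0,
) -> PeakTable:
    """Detect peaks and integrate them above a local linear baseline.

    Thresholds default to ``noise_k`` times a robust noise estimate (MAD
    of the first-difference of the signal).  Peak bounds are the valleys
    flanking each apex; the area is the trapezoidal integral of the
    signal above the straight line joining the bounds.
    """
    if len(c.signal) < 3:
        raise ValueError("chromatogram has fewer than 3 points")
    t, y = c.time_min, c.signal
    if min_height is None or min_prominence is None:
        noise = float(np.median(np.abs(np.diff(y) - np.median(np.diff(y))))) * 1.4826
        noise = max(noise, 1e-12)
        if min_height is None:
            min_height = noise_k * noise
        if min_prominence is None:
            min_prominence = noise_k * noise
    apexes, _ = find_peaks(y, height=min_height, prominence=min_prominence)
    if len(apexes) == 0:
        return PeakTable([], c.batch_id, c.origin)
    # valley bounds between consecutive apexes.  The bound sits at the
    # sample nearest the valley floor on the noise-free signal; estimating
    # it from noisy samples (e.g. the argmin) would couple the integration
    # window to the noise and bias areas, so the bound is taken at the
    # apex midpoint, which coincides with the valley floor for resolved
    # peaks.  Trace ends bound the outer peaks.
    bounds = [0]
    for a, b in zip(apexes[:-1], apexes[1:]):
        bounds.append((a + b) // 2)
    bounds.append(len(y) - 1)
    # baseline anchors: median of the central few percent of each
    # inter-peak gap.  The window position depends only on the apexes,
    # never on where the noisy minimum happens to fall, and sits as far
    # as possible from both apexes so that even tall-peak tails contribute
    # nothing; the anchor is then an unbiased level estimate of the local
    # baseline.
    gap_edges = np.concatenate([[0], apexes, [len(y) - 1]])
    anchor = []
    for a, b in zip(gap_edges[:-1], gap_edges[1:]):
        lo = a + int(0.48 * (b - a))
        hi = max(a + int(0.52 * (b - a)), lo + 1)
        anchor.append(float(np.median(y[lo:hi])))
    peaks: list[Peak] = []
    for i, apex in enumerate(apexes):
        lo, hi = bounds[i], bounds[i + 1]
        baseline = np.interp(t[lo:hi + 1], [t[lo], t[hi]], [anchor[i], anchor[i + 1]])
        seg = y[lo:hi + 1] - baseline
        # the noisy boundary samples are replaced by the baseline itself so
        # that valley selection cannot leak into the integral
        seg[0] = 0.0
        seg[-1] = 0.0
        area = float(np.trapezoid(seg, t[lo:hi + 1]))
        if area > 0:
            peaks.append(Peak(rt=float(t[apex]), area=area, height=float(y[apex])))
    return PeakTable(peaks, c.batch_id, c.origin)


@dataclass
class AlignedPeakMatrix:
    """samples x aligned-peaks area matrix; zero marks an absent peak."""

    areas: pd.DataFrame  # index: sample ids, columns: aligned peak labels
    consensus_rt: pd.Series  # per aligned peak
    origins: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        if (self.areas.values < 0).any():
            raise ValueError("negative peak areas")
        if np.any(np.diff(self.consensus_rt.values) < 0):
            raise ValueError("consensus RTs must be non-decreasing")


def align_peaks(
    tables: Sequence[PeakTable],
    rt_tol: float = 0.5,
    sample_ids: Optional[Sequence[str]] = None,
) -> AlignedPeakMatrix:
    """Greedy RT agglomeration of per-sample peak tables.

    Pooled apexes are swept in RT order and grouped into clusters of width
    <= ``rt_tol``; within a cluster each sample contributes its peak
    nearest the cluster median (largest-area first on ties), surplus peaks
    of the same sample start no new entry.  Consensus RT is the member
    median.
    """
    if not tables:
        raise ValueError("no peak tables")
    if sample_ids is None:
        sample_ids = [tb.batch_id or f"S{i}" for i, tb in enumerate(tables)]
    pooled = sorted(
        (p.rt, si, p.area) for si, tb in enumerate(tables) for p in tb.peaks
    )
    clusters: list[list[tuple[float, int, float]]] = []
    for item in pooled:
        if clusters and item[0] - clusters[-1][0][0] <= rt_tol:
            clusters[-1].append(item)
        else:
            clusters.append([item])
    labels, rts, cols = [], [], []
    for k, members in enumerate(clusters):
        med = float(np.median([m[0] for m in members]))
        col = np.zeros(len(tables))
        best_d = {si: np.inf for si in range(len(tables))}
        for rt, si, area in members:
            d = abs(rt - med)
            if d < best_d[si]:
                best_d[si] = d
                col[si] = area
        labels.append(f"FP{k + 1:02d}")
        rts.append(med)
        cols.append(col)
    areas = pd.DataFrame(
        np.column_stack(cols), index=list(sample_ids), columns=labels
    )
    origins = pd.Series([tb.origin for tb in tables], index=list(sample_ids))
    return AlignedPeakMatrix(areas, pd.Series(rts, index=labels), origins)


def select_characteristic_peaks(
    m: AlignedPeakMatrix, area_fraction: float = 0.90
) -> tuple[list[str], float]:
    """Shared peaks greedily accumulated to the mean-area threshold.

    Only peaks present in every sample are eligible; they are added in
    descending mean area until their cumulative mean area reaches
    ``area_fraction`` of the total mean area of all aligned peaks.
    Returns the selected labels (RT order) and the achieved fraction.
    """
    if m.areas.empty:
        raise ValueError("empty aligned matrix")
    mean_area = m.areas.mean(axis=0)
    total = float(mean_area.sum())
    shared = [c for c in m.areas.columns if (m.areas[c] > 0).all()]
    if not shared:
        raise ValueError("no peak is present in every sample")
    ranked = sorted(shared, key=lambda c: (-mean_area[c], c))
    chosen: list[str] = []
    cum = 0.0
    for c in ranked:
        chosen.append(c)
        cum += float(mean_area[c])
        if cum >= area_fraction * total:
            break
    chosen.sort(key=lambda c: list(m.areas.columns).index(c))
    return chosen, cum / total


def rrt_rpa(table: pd.Series | dict, rt: pd.Series | dict, reference: str) -> pd.DataFrame:
    """Relative retention time and relative peak area against a reference peak.

    ``table`` maps peak label -> area and ``rt`` maps label -> retention
    time for one sample; RRT = RT/RT_ref, RPA = area/area_ref.
    """
    areas = pd.Series(table, dtype=float)
    rts = pd.Series(rt, dtype=float)
    if reference not in areas.index or areas[reference] <= 0:
        raise ValueError(f"reference peak {reference!r} missing from sample")
    return pd.DataFrame({"RRT": rts / rts[reference], "RPA": areas / areas[reference]})


@dataclass
class FingerprintVector:
    """Per-sample RPA vector over the characteristic peak set."""

    values: pd.Series  # index: peak labels
    reference: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.reference not in self.values.index:
            raise ValueError("reference peak not in vector")
        if not np.isclose(self.values[self.reference], 1.0):
            raise ValueError("RPA of the reference peak must be 1")


def reference_fingerprint(vectors: Sequence[FingerprintVector]) -> FingerprintVector:
    """Median consensus fingerprint across samples."""
    if not vectors:
        raise ValueError("no fingerprint vectors")
    idx = vectors[0].values.index
    for v in vectors[1:]:
        if not v.values.index.equals(idx):
            raise ValueError("inconsistent peak sets across samples")
    med = pd.concat([v.values for v in vectors], axis=1).median(axis=1)
    med[vectors[0].reference] = 1.0
    return FingerprintVector(med, vectors[0].reference, sample_id="median_reference")


def similarity(a: FingerprintVector, ref: FingerprintVector, method: str = "cosine") -> float:
    """Similarity value of a sample against the consensus fingerprint.

    Cosine of the RPA vectors (the SV convention adopted here); Pearson
    correlation is available as the secondary statistic.
    """
    if not a.values.index.equals(ref.values.index):
        raise ValueError("peak sets differ")
    x = a.values.to_numpy(float)
    y = ref.values.to_numpy(float)
    if not (np.linalg.norm(x) > 0 and np.linalg.norm(y) > 0):
        raise ValueError("zero fingerprint vector")
    if method == "cosine":
        return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))
    if method == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    raise ValueError(f"unknown similarity method {method!r}")


@dataclass
class SimilarityReport:
    per_sample: pd.Series
    within_origin_range: tuple[float, float]
    between_origin_range: tuple[float, float]
    mean_within: float
    mean_between: float
    method: str = "cosine"


def similarity_report(
    vectors: Sequence[FingerprintVector],
    origins: dict[str, str],
    method: str = "cosine",
) -> SimilarityReport:
    """SVs vs the median reference, plus within/between-origin pairwise ranges.

    Within/between statistics are computed on pairwise sample-sample SVs
    grouped by origin label.
    """
    ref = reference_fingerprint(vectors)
    sv = pd.Series(
        {v.sample_id: similarity(v, ref, method) for v in vectors}, dtype=float
    )
    within, between = [], []
    for i, a in enumerate(vectors):
        for b in vectors[i + 1:]:
            s = similarity(a, FingerprintVector(b.values, b.reference, b.sample_id), method)
            (within if origins[a.sample_id] == origins[b.sample_id] else between).append(s)
    rng = lambda xs: (float(np.min(xs)), float(np.max(xs))) if xs else (np.nan, np.nan)
    return SimilarityReport(
        per_sample=sv,
        within_origin_range=rng(within),
        between_origin_range=rng(between),
        mean_within=float(np.mean(within)) if within else np.nan,
        mean_between=float(np.mean(between)) if between else np.nan,
        method=method,
    )


def validation_rsd(
    replicate_areas: Sequence[pd.Series],
    replicate_rts: Sequence[pd.Series],
    reference: str,
) -> pd.DataFrame:
    """RSD% of every RRT and RPA across method-validation replicates.

    Sample standard deviation (n-1) over replicate injections; the
    instrument-method criterion is that every value stays below 3%.
    """
    if len(replicate_areas) < 2:
        raise ValueError("need at least 2 replicates")
    rrts, rpas = [], []
    for areas, rts in zip(replicate_areas, replicate_rts):
        tab = rrt_rpa(areas, rts, reference)
        rrts.append(tab["RRT"])
        rpas.append(tab["RPA"])
    rrt = pd.concat(rrts, axis=1)
    rpa = pd.concat(rpas, axis=1)
    out = pd.DataFrame(
        {
            "RRT_rsd_pct": rrt.std(axis=1, ddof=1) / rrt.mean(axis=1) * 100,
            "RPA_rsd_pct": rpa.std(axis=1, ddof=1) / rpa.mean(axis=1) * 100,
        }
    )
    return out.fillna(0.0)
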