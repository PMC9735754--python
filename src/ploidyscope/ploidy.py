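"""DNA ploidy analysis of per-nucleus IOD measurements.

The pipeline for one specimen:

1. ``normalize`` — rescale every IOD so the mean of the operator-designated
   reference cells (normal squamous epithelial cells or lymphocytes) sits at
   2c: ``c = 2 * iod / mean(reference iods)``.  Reference-cell quality is
   summarized in a :class:`QCReport` (>=30 reference cells expected, their
   coefficient of variation must stay below 5%, and >=300 analysis cells are
   recommended).
2. ``build_histogram`` — DNA histogram in c-units for display.
3. ``detect_stemlines`` — modal G0/G1 peaks via a Gaussian kernel density
   estimate (fixed bandwidth in c-units) with local-maximum extraction.
   Peaks near twice the position of a larger stemline are annotated as G2/M
   doubling peaks.
4. ``count_exceeding_events`` / ``classify_ploidy`` — ESACP aneuploidy
   criteria: a specimen is DNA-aneuploid if some stemline mode deviates more
   than 10% from the diploid (2c) or tetraploid (4c) region, i.e. lies
   strictly outside [1.8, 2.2] and [3.6, 4.4] c, or if at least one cell
   exceeds 9c (single-cell aneuploidy).  Cells above 5c are counted and
   reported but never trigger by themselves.

Boundary semantics are strict ("more than 10%"): a stemline exactly at 2.2c
is euploid.  A doubling peak of a euploid stemline (e.g. 8c over a 4c line)
does not trigger stemline aneuploidy; a doubling peak of an aneuploid
stemline adds nothing — the primary stemline already triggers.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import NormalizationError, ParameterError, StateError

__all__ = [
    "NucleusMeasurement",
    "Specimen",
    "QCReport",
    "DNAHistogram",
    "Stemline",
    "ClassificationThresholds",
    "PloidyResult",
    "normalize",
    "build_histogram",
    "detect_stemlines",
    "count_exceeding_events",
    "classify_ploidy",
    "analyze_specimen",
    "read_cells_csv",
    "write_cells_csv",
    "result_to_dict",
    "write_results_json",
]

MIN_REFERENCE_CELLS = 30
MIN_ANALYSIS_CELLS = 300
MAX_REFERENCE_CV = 0.05


@dataclass
class NucleusMeasurement:
    """One cell's densitometric measurement and (after normalization) c-value."""

    cell_id: str
    role: Literal["reference", "analysis"]
    iod: float
    c_value: Optional[float] = None

    def __post_init__(self):
        if self.iod <= 0:
            raise ParameterError(f"cell {self.cell_id}: IOD must be positive")


@dataclass
class Specimen:
    """A brush-biopsy sample: nucleus measurements plus optional cytology category.

    Cytology categories: 1 negative, 2 doubtful, 3 suspicious, 4 positive.
    """

    specimen_id: str
    measurements: list[NucleusMeasurement]
    cytology_category: Optional[int] = None

    @property
    def reference_iods(self) -> np.ndarray:
        return np.array([m.iod for m in self.measurements if m.role == "reference"])

    @property
    def analysis_cells(self) -> list[NucleusMeasurement]:
        return [m for m in self.measurements if m.role == "analysis"]

    @property
    def analysis_c_values(self) -> np.ndarray:
        cs = [m.c_value for m in self.analysis_cells]
        if any(c is None for c in cs):
            raise StateError(
                f"specimen {self.specimen_id} has unnormalized analysis cells"
            )
        return np.array(cs, dtype=float)

    @property
    def is_normalized(self) -> bool:
        return all(m.c_value is not None for m in self.measurements)


@dataclass
class QCReport:
    n_reference: int
    n_analysis: int
    reference_cv: float
    flags: list[str] = field(default_factory=list)
    saturation_warnings: int = 0


@dataclass
class DNAHistogram:
    """DNA histogram: uniform half-open bins [edge, edge + width) starting at 0."""

    bin_edges: np.ndarray
    counts: np.ndarray
    c_values: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class Stemline:
    """A modal G0/G1 subpopulation in the DNA histogram.

    ``doubling_of`` indexes another stemline in the same detection result
    whose position is approximately half of this one (a G2/M doubling peak).
    """

    position: float
    n_cells: int
    fraction: float
    doubling_of: Optional[int] = None


@dataclass
class ClassificationThresholds:
    """ESACP decision constants, all in c-units unless relative."""

    diploid_center: float = 2.0
    tetraploid_center: float = 4.0
    relative_tolerance: float = 0.10  # -> euploid intervals [1.8,2.2], [3.6,4.4]
    rare_event_cutoff: float = 9.0
    secondary_event_cutoff: float = 5.0
    doubling_tolerance: float = 0.10  # relative, for doubling-peak annotation

    def __post_init__(self):
        if not 0 < self.relative_tolerance < 1 or not 0 < self.doubling_tolerance < 1:
            raise ParameterError("tolerances must lie in (0, 1)")
        if self.rare_event_cutoff <= 0 or self.secondary_event_cutoff <= 0:
            raise ParameterError("event cutoffs must be positive")

    @property
    def diploid_interval(self) -> tuple[float, float]:
        t = self.relative_tolerance * self.diploid_center
        return (self.diploid_center - t, self.diploid_center + t)

    @property
    def tetraploid_interval(self) -> tuple[float, float]:
        t = self.relative_tolerance * self.tetraploid_center
        return (self.tetraploid_center - t, self.tetraploid_center + t)

    def in_euploid_region(self, position: float) -> bool:
        """True if a stemline at this position is euploid (closed intervals)."""
        lo, hi = self.diploid_interval
        if lo <= position <= hi:
            return True
        lo, hi = self.tetraploid_interval
        return lo <= position <= hi


@dataclass
class PloidyResult:
    classification: Literal["aneuploid", "non_aneuploid"]
    reasons: list[str]
    stemlines: list[Stemline]
    n_cells_gt_5c: int
    n_cells_gt_9c: int
    qc: QCReport


def _qc_report(specimen: Specimen, saturation_warnings: int = 0) -> QCReport:
    ref = specimen.reference_iods
    n_ref = len(ref)
    n_ana = len(specimen.analysis_cells)
    cv = float(np.std(ref) / np.mean(ref)) if n_ref > 0 else float("nan")
    flags = []
    if n_ref < MIN_REFERENCE_CELLS:
        flags.append("insufficient_reference")
    if n_ref > 0 and cv >= MAX_REFERENCE_CV:
        flags.append("high_reference_cv")
    if n_ana < MIN_ANALYSIS_CELLS:
        flags.append("low_analysis_count")
    if saturation_warnings:
        flags.append("saturation_warnings")
    return QCReport(n_ref, n_ana, cv, flags, saturation_warnings)


def normalize(specimen: Specimen) -> tuple[Specimen, QCReport]:
    """Normalize IODs to c-units against the specimen's reference cells.

    Every cell gets ``c_value = 2 * iod / mean(reference iods)``, anchoring
    the reference mean at 2c.  QC failures (high reference CV, low counts)
    flag the specimen but do not veto downstream classification.
    """
    ref = specimen.reference_iods
    if len(ref) == 0:
        raise NormalizationError(
            f"specimen {specimen.specimen_id}: no reference cells to normalize against"
        )
    mean_ref = float(ref.mean())
    new_measurements = [
        replace(m, c_value=2.0 * m.iod / mean_ref) for m in specimen.measurements
    ]
    normalized = replace(specimen, measurements=new_measurements)
    return normalized, _qc_report(normalized)


def build_histogram(specimen: Specimen, bin_width: float = 0.1) -> DNAHistogram:
    """DNA histogram of the analysis cells' c-values (display only)."""
    if bin_width <= 0:
        raise ParameterError("bin width must be positive")
    c = specimen.analysis_c_values
    top = float(c.max()) if len(c) else 0.0
    n_bins = max(1, int(np.floor(top / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width
    # np.histogram closes the last bin on the right; add a bin so every value
    # lands in a genuinely half-open [edge, edge+width) bin.
    counts, _ = np.histogram(c, bins=np.append(edges, edges[-1] + bin_width))
    return DNAHistogram(bin_edges=edges, counts=counts[: len(edges) - 1] + 0, c_values=c)


def _kde(grid: np.ndarray, values: np.ndarray, bandwidth: float) -> np.ndarray:
    z = (grid[:, None] - values[None, :]) / bandwidth
    return np.exp(-0.5 * z * z).sum(axis=1) / (bandwidth * np.sqrt(2 * np.pi) * len(values))


def detect_stemlines(
    specimen: Specimen,
    thresholds: Optional[ClassificationThresholds] = None,
    min_stemline_fraction: float = 0.05,
    min_stemline_cells: int = 5,
    bandwidth: float = 0.1,
    grid_step: float = 0.01,
) -> list[Stemline]:
    """Detect modal stemlines in the c-value distribution.

    A Gaussian KDE (fixed bandwidth in c-units) is evaluated on a uniform
    grid; local maxima with topographic prominence of at least 0.4x the peak
    height of a minimal admissible stemline (``min_stemline_fraction`` of
    cells concentrated at one point) are candidate modes.  The cells
    attributed to a candidate are those within 2.5 bandwidths of its
    position — a stemline is a *narrow* modal subpopulation.  A candidate
    becomes a stemline only if its attributed cells *in excess of the local
    continuum* (estimated from equal-width flanking bands, 2.5-5 bandwidths
    on either side, which capture the S-phase plateau and scattered
    background cells) reach both ``min_stemline_fraction`` of the analysis
    cells and ``min_stemline_cells`` cells; chance clusters of background
    cells and single rare events therefore do not masquerade as stemlines.
    Stemlines are ordered by (raw) cell count descending, ties broken by
    lower c-value.  A stemline whose position is within
    ``doubling_tolerance`` (relative) of twice the position of a stemline
    with more attributed cells is annotated as that stemline's G2/M doubling
    peak.
    """
    from scipy.signal import find_peaks

    thresholds = thresholds or ClassificationThresholds()
    c = specimen.analysis_c_values
    n = len(c)
    if n == 0:
        return []

    grid = np.arange(0.0, c.max() + 4 * bandwidth + grid_step, grid_step)
    density = _kde(grid, c, bandwidth)
    min_prominence = 0.4 * min_stemline_fraction / (bandwidth * np.sqrt(2 * np.pi))
    peak_idx, _ = find_peaks(density, prominence=min_prominence)
    # a single tight cluster can put its mode at the grid interior only; if no
    # interior peak exists (monotone density), use the global maximum
    if len(peak_idx) == 0:
        peak_idx = np.array([int(np.argmax(density))])
    candidates = grid[peak_idx]

    window = 2.5 * bandwidth  # a modal subpopulation's half-width
    stems: list[Stemline] = []
    for pos in candidates:
        dist = np.abs(c - pos)
        members = c[dist <= window]
        n_k = len(members)
        # local continuum under the peak, from flanking bands of equal
        # combined width (the S-phase plateau / scattered cells)
        n_flank = int(np.sum((dist > window) & (dist <= 2 * window)))
        n_excess = n_k - n_flank
        if n_excess < min_stemline_cells or n_excess / n < min_stemline_fraction:
            continue
        # refine the mode on the attributed cells: fine local grid plus the
        # member values themselves (exact for a cluster of identical cells)
        local = np.concatenate(
            [
                np.arange(members.min() - bandwidth, members.max() + bandwidth, grid_step / 10),
                members,
            ]
        )
        pos_refined = float(local[np.argmax(_kde(local, members, bandwidth))])
        stems.append(Stemline(position=pos_refined, n_cells=n_k, fraction=n_k / n))

    stems.sort(key=lambda s: (-s.n_cells, s.position))

    # annotate doubling peaks: position ~ 2x a larger (earlier-ordered) stemline
    for i, s in enumerate(stems):
        best, best_err = None, np.inf
        for j in range(i):
            target = 2.0 * stems[j].position
            err = abs(s.position - target) / target
            if err <= thresholds.doubling_tolerance and err < best_err:
                best, best_err = j, err
        s.doubling_of = best
    return stems


def count_exceeding_events(
    specimen: Specimen, thresholds: Optional[ClassificationThresholds] = None
) -> tuple[int, int]:
    """Counts of analysis cells strictly above 5c and above 9c."""
    thresholds = thresholds or ClassificationThresholds()
    c = specimen.analysis_c_values
    return (
        int(np.sum(c > thresholds.secondary_event_cutoff)),
        int(np.sum(c > thresholds.rare_event_cutoff)),
    )


def classify_ploidy(
    specimen: Specimen,
    thresholds: Optional[ClassificationThresholds] = None,
    min_stemline_fraction: float = 0.05,
    min_stemline_cells: int = 5,
    bandwidth: float = 0.1,
    qc: Optional[QCReport] = None,
) -> PloidyResult:
    """Classify a normalized specimen as DNA-aneuploid or not (ESACP rules).

    Reasons:

    - ``stemline_aneuploidy`` — some stemline mode lies strictly outside both
      the diploid interval [1.8, 2.2] and the tetraploid interval [3.6, 4.4],
      and is not the doubling peak of a stemline already judged euploid.
    - ``single_cell_aneuploidy`` — at least one analysis cell exceeds 9c.

    Cells above 5c are reported but never a reason by themselves.
    """
    if not specimen.is_normalized:
        raise StateError(
            f"specimen {specimen.specimen_id} must be normalized before classification"
        )
    thresholds = thresholds or ClassificationThresholds()
    stems = detect_stemlines(
        specimen,
        thresholds,
        min_stemline_fraction=min_stemline_fraction,
        min_stemline_cells=min_stemline_cells,
        bandwidth=bandwidth,
    )
    n_gt5, n_gt9 = count_exceeding_events(specimen, thresholds)

    # euploid status resolved in detection order so a doubling peak can
    # inherit euploidy from its (larger) primary stemline
    euploid = [False] * len(stems)
    triggers = []
    for i, s in enumerate(stems):
        if thresholds.in_euploid_region(s.position):
            euploid[i] = True
        elif s.doubling_of is not None and euploid[s.doubling_of]:
            euploid[i] = True  # G2/M of a euploid line, e.g. 8c over 4c
        else:
            triggers.append(i)

    reasons = []
    if triggers:
        reasons.append("stemline_aneuploidy")
    if n_gt9 >= 1:
        reasons.append("single_cell_aneuploidy")

    return PloidyResult(
        classification="aneuploid" if reasons else "non_aneuploid",
        reasons=reasons,
        stemlines=stems,
        n_cells_gt_5c=n_gt5,
        n_cells_gt_9c=n_gt9,
        qc=qc if qc is not None else _qc_report(specimen),
    )


def analyze_specimen(
    specimen: Specimen,
    thresholds: Optional[ClassificationThresholds] = None,
    **detect_kwargs,
) -> PloidyResult:
    """Normalize then classify one raw-IOD specimen."""
    normalized, qc = normalize(specimen)
    return classify_ploidy(normalized, thresholds, qc=qc, **detect_kwargs)


# ---------------------------------------------------------------------------
# CSV / JSON plumbing (per-cell CSV dialect: specimen_id, cell_id, role, iod)

def read_cells_csv(path) -> list[Specimen]:
    df = pd.read_csv(path)
    required = {"specimen_id", "cell_id", "role", "iod"}
    if not required.issubset(df.columns):
        raise ParameterError(f"per-cell CSV must have columns {sorted(required)}")
    specimens = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        ms = [
            NucleusMeasurement(cell_id=str(r.cell_id), role=r.role, iod=float(r.iod))
            for r in grp.itertuples()
        ]
        specimens.append(Specimen(specimen_id=str(sid), measurements=ms))
    return specimens


def write_cells_csv(path, specimens: Sequence[Specimen]) -> None:
    rows = [
        {"specimen_id": s.specimen_id, "cell_id": m.cell_id, "role": m.role, "iod": m.iod}
        for s in specimens
        for m in s.measurements
    ]
    pd.DataFrame(rows, columns=["specimen_id", "cell_id", "role", "iod"]).to_csv(
        path, index=False
    )


def result_to_dict(specimen_id: str, result: PloidyResult) -> dict:
    return {
        "specimen_id": specimen_id,
        "classification": result.classification,
        "reasons": result.reasons,
        "stemlines": [
            {
                "position": round(s.position, 4),
                "n_cells": s.n_cells,
                "fraction": round(s.fraction, 6),
                "doubling_of": s.doubling_of,
            }
            for s in result.stemlines
        ],
        "n_gt_5c": result.n_cells_gt_5c,
        "n_gt_9c": result.n_cells_gt_9c,
        "qc": {
            "n_reference": result.qc.n_reference,
            "n_analysis": result.qc.n_analysis,
            "reference_cv": round(result.qc.reference_cv, 6)
            if np.isfinite(result.qc.reference_cv)
            else None,
            "flags": result.qc.flags,
        },
    }


def write_results_json(path, results: dict[str, PloidyResult]) -> None:
    payload = [result_to_dict(sid, res) for sid, res in results.items()]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
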