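"""Synthetic cell populations, cohorts and nucleus images.

Everything downstream of the microscope is testable without a slide:

- ``generate_population`` draws per-nucleus IODs for a specimen from a
  mixture of G0/G1 stemlines, their G2/M doubling peaks, S-phase plateaus,
  a scattered background, and an exact number of rare events above 9c, with
  multiplicative Gaussian measurement noise (sd = CV x mean, truncated at 0).
- ``generate_cohort`` expands grouped study counts (cytology category x
  ploidy result x follow-up outcome) into labelled case rows, exactly
  count-preserving.
- ``generate_nucleus_image`` renders a disc nucleus whose integrated optical
  density encodes a chosen c-value, for end-to-end densitometry round trips.

All randomness flows through explicit seeds; there is no global RNG state.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .densitometry import ImagePatch
from .errors import FixtureIntegrityError, ParameterError
from .ploidy import ClassificationThresholds, NucleusMeasurement, Specimen

__all__ = [
    "StemlineSpec",
    "PopulationSpec",
    "SyntheticSpecimen",
    "CohortSpec",
    "CohortRow",
    "generate_population",
    "generate_cohort",
    "generate_nucleus_image",
    "load_study_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "IOD_PER_C",
]

#: calibration constant of the synthetic imager: IOD units per 1c of DNA
IOD_PER_C = 50.0

# scattered background cells (the <=1 remainder of the stemline fractions) are
# drawn away from the >9c rare-event region so generator truth stays exact
_SCATTER_RANGE = (1.5, 5.0)


class StemlineSpec(BaseModel):
    """One G0/G1 stemline and its cell-cycle companions.

    ``fraction`` of the analysis cells sit at ``position`` (the G0/G1 mode),
    ``doubling_fraction`` at twice that position (G2/M), and
    ``s_phase_fraction`` spread uniformly between the two (S phase).
    """

    position: float = Field(gt=0, description="DNA content in c-units")
    fraction: float = Field(ge=0, le=1)
    doubling_fraction: float = Field(default=0.0, ge=0, le=1)
    s_phase_fraction: float = Field(default=0.0, ge=0, le=1)

    @property
    def total_fraction(self) -> float:
        return self.fraction + self.doubling_fraction + self.s_phase_fraction


class PopulationSpec(BaseModel):
    """Full recipe for one synthetic specimen's cell population."""

    stemlines: list[StemlineSpec]
    rare_event_count: int = Field(default=0, ge=0)
    n_analysis: int = Field(default=300, ge=0)
    n_reference: int = Field(default=30, ge=0)
    measurement_cv: float = Field(default=0.03, ge=0)
    reference_cv: float = Field(default=0.03, ge=0)
    iod_scale: float = Field(default=IOD_PER_C, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_fractions(self):
        total = sum(s.total_fraction for s in self.stemlines)
        if total > 1 + 1e-9:
            raise ParameterError(
                f"stemline fractions sum to {total:.3f} > 1"
            )
        return self


@dataclass
class SyntheticSpecimen:
    """A generated specimen plus the ground truth it was drawn from."""

    spec: PopulationSpec
    specimen: Specimen
    truth_classification: Literal["aneuploid", "non_aneuploid"]
    truth_stemline_positions: list[float]


def _expected_classification(
    spec: PopulationSpec, thresholds: Optional[ClassificationThresholds] = None
) -> str:
    """Apply the ESACP rules to the *intended* population parameters."""
    thresholds = thresholds or ClassificationThresholds()
    if spec.rare_event_count >= 1:
        return "aneuploid"
    for s in spec.stemlines:
        if s.fraction > 0 and not thresholds.in_euploid_region(s.position):
            return "aneuploid"
        # a doubling peak only matters when its primary line is euploid and
        # the doubled position is not: then it is an annotated G2/M peak,
        # never a trigger — so doubling peaks never change the verdict
    return "non_aneuploid"


def _largest_remainder(targets: np.ndarray) -> np.ndarray:
    """Round fractional cell targets to integers preserving their sum."""
    base = np.floor(targets).astype(int)
    shortfall = int(round(targets.sum())) - int(base.sum())
    if shortfall > 0:
        order = np.argsort(-(targets - base))
        base[order[:shortfall]] += 1
    return base


def generate_population(spec: PopulationSpec) -> SyntheticSpecimen:
    """Draw one specimen's reference and analysis IODs from the recipe.

    Reference cells center on 2c x iod_scale with CV ``reference_cv``;
    analysis cells follow the stemline mixture with CV ``measurement_cv``.
    Exactly ``rare_event_count`` cells are drawn uniformly in (9c, 12c]
    before noise.  Identical specs (including seed) give identical output.
    """
    rng = np.random.default_rng(spec.seed)

    targets = []
    kinds = []
    for s in spec.stemlines:
        for frac, kind in (
            (s.fraction, ("point", s.position)),
            (s.doubling_fraction, ("point", 2.0 * s.position)),
            (s.s_phase_fraction, ("uniform", (s.position, 2.0 * s.position))),
        ):
            targets.append(frac * spec.n_analysis)
            kinds.append(kind)

    n_mixture = spec.n_analysis - spec.rare_event_count
    if n_mixture < 0:
        raise ParameterError("rare_event_count exceeds n_analysis")
    counts = _largest_remainder(np.array(targets or [0.0]))
    if counts.sum() > n_mixture:
        raise ParameterError(
            "stemline fractions plus rare events exceed the analysis cell count"
        )

    c_values = []
    for (kind, param), n_k in zip(kinds, counts):
        if n_k == 0:
            continue
        if kind == "point":
            c_values.append(np.full(n_k, param))
        else:
            lo, hi = param
            c_values.append(rng.uniform(lo, hi, size=n_k))
    n_scatter = n_mixture - counts.sum()
    if n_scatter > 0:
        c_values.append(rng.uniform(*_SCATTER_RANGE, size=n_scatter))
    if spec.rare_event_count > 0:
        # uniform on (9, 12]
        c_values.append(12.0 - rng.uniform(0.0, 3.0, size=spec.rare_event_count))
    c = np.concatenate(c_values) if c_values else np.array([])

    # iod_scale is the imager calibration: arbitrary IOD units per 1c
    iods = _multiplicative_noise(c * spec.iod_scale, spec.measurement_cv, rng)

    ref = np.full(spec.n_reference, 2.0 * spec.iod_scale)
    ref = _multiplicative_noise(ref, spec.reference_cv, rng)

    measurements = [
        NucleusMeasurement(cell_id=f"ref{i:04d}", role="reference", iod=float(v))
        for i, v in enumerate(ref)
    ] + [
        NucleusMeasurement(cell_id=f"ana{i:04d}", role="analysis", iod=float(v))
        for i, v in enumerate(iods)
    ]
    truth_positions = [s.position for s in spec.stemlines if s.fraction > 0] + [
        2.0 * s.position for s in spec.stemlines if s.doubling_fraction > 0
    ]
    return SyntheticSpecimen(
        spec=spec,
        specimen=Specimen(specimen_id=f"synthetic-{spec.seed}", measurements=measurements),
        truth_classification=_expected_classification(spec),
        truth_stemline_positions=truth_positions,
    )


def _multiplicative_noise(values: np.ndarray, cv: float, rng) -> np.ndarray:
    """Gaussian multiplicative error, sd = cv x mean, truncated at zero."""
    if cv == 0 or len(values) == 0:
        return values
    factors = rng.normal(1.0, cv, size=len(values))
    bad = factors <= 0
    while bad.any():  # truncation: resample nonpositive factors
        factors[bad] = rng.normal(1.0, cv, size=int(bad.sum()))
        bad = factors <= 0
    return values * factors


# ---------------------------------------------------------------------------
# Cohorts

@dataclass(frozen=True)
class CohortRow:
    """One labelled case: cytology category, ploidy verdict, follow-up outcome."""

    specimen_id: str
    cytology: int  # 1 negative, 2 doubtful, 3 suspicious, 4 positive
    icm: Literal["aneuploid", "non_aneuploid"]
    followup: Literal["positive", "negative"]


class CohortSpec(BaseModel):
    """Grouped cohort counts keyed by (cytology, icm, followup)."""

    counts: dict[tuple[int, str, str], int]

    @model_validator(mode="after")
    def _validate(self):
        for (cyt, icm, fup), n in self.counts.items():
            if cyt not in (1, 2, 3, 4):
                raise ParameterError(f"cytology category {cyt} out of range 1..4")
            if icm not in ("aneuploid", "non_aneuploid"):
                raise ParameterError(f"bad icm label {icm!r}")
            if fup not in ("positive", "negative"):
                raise ParameterError(f"bad follow-up label {fup!r}")
            if n < 0:
                raise ParameterError("counts must be nonnegative")
        return self

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def generate_cohort(cohort: CohortSpec, seed: int = 0) -> list[CohortRow]:
    """Expand grouped counts into one row per case (exactly count-preserving).

    The seed only shuffles row order; no count is sampled.
    """
    rows = []
    i = 0
    for (cyt, icm, fup), n in sorted(cohort.counts.items()):
        for _ in range(n):
            rows.append(
                CohortRow(specimen_id=f"case{i:04d}", cytology=cyt, icm=icm, followup=fup)
            )
            i += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    return [rows[j] for j in order]


def cohort_to_frame(rows: list[CohortRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"specimen_id": r.specimen_id, "cytology": r.cytology, "icm": r.icm,
             "followup": r.followup}
            for r in rows
        ],
        columns=["specimen_id", "cytology", "icm", "followup"],
    )


def write_cohort_csv(path, rows: list[CohortRow]) -> None:
    cohort_to_frame(rows).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cytology", "icm", "followup"}
    if not required.issubset(df.columns):
        raise ParameterError(f"cohort CSV must have columns {sorted(required)}")
    return df


def _counts_checksum(counts: list[dict]) -> str:
    canon = json.dumps(
        sorted(counts, key=lambda r: (r["cytology"], r["icm"], r["followup"])),
        sort_keys=True,
    )
    return hashlib.sha256(canon.encode()).hexdigest()


def load_study_cohort(verify: bool = True, path=None) -> tuple[CohortSpec, dict]:
    """Load the packaged 602-case study cohort fixture.

    Returns the :class:`CohortSpec` plus the raw fixture payload (derivation
    notes, benign-side criteria split, checksum).  With ``verify`` the counts
    are checked against the recorded checksum and margin totals; a mismatch
    raises :class:`FixtureIntegrityError` naming expected vs found values.
    ``path`` overrides the packaged file (for externally edited fixtures).
    """
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = fh.read()
    else:
        raw = resources.files("ploidyscope.data").joinpath("study_cohort.json").read_text()
    payload = json.loads(raw)
    counts = payload["counts"]
    if verify:
        found = _counts_checksum(counts)
        if found != payload["sha256"]:
            raise FixtureIntegrityError(
                "study fixture checksum mismatch",
                expected=payload["sha256"],
                found=found,
            )
        total = sum(r["n"] for r in counts)
        if total != payload["expected_total"]:
            raise FixtureIntegrityError(
                f"study fixture total {total} != expected {payload['expected_total']}",
                expected=payload["expected_total"],
                found=total,
            )
    spec = CohortSpec(
        counts={(r["cytology"], r["icm"], r["followup"]): r["n"] for r in counts}
    )
    # study-design invariant: every cytologically negative case was non-aneuploid
    for (cyt, icm, _), n in spec.counts.items():
        if cyt == 1 and icm == "aneuploid" and n > 0:
            raise FixtureIntegrityError(
                "study fixture contains cytology-negative aneuploid cases",
                expected=0,
                found=n,
            )
    return spec, payload


# ---------------------------------------------------------------------------
# Nucleus images

def generate_nucleus_image(
    c_value: float,
    radius: int = 12,
    patch_size: int = 40,
    background_intensity: float = 4096.0,
    noise: float = 0.0,
    seed: int = 0,
    iod_per_c: float = IOD_PER_C,
) -> tuple[ImagePatch, np.ndarray]:
    """Render a disc nucleus whose IOD encodes ``c_value``.

    The disc's per-pixel optical density is ``c_value * iod_per_c / area`` so
    the integrated optical density over the mask equals ``c_value * iod_per_c``
    exactly at zero noise.  ``noise`` is the CV of multiplicative Gaussian
    noise on the per-pixel OD.  Returns the patch and its boolean mask.
    """
    if c_value <= 0:
        raise ParameterError("c_value must be positive")
    if background_intensity <= 0:
        raise ParameterError("background intensity must be positive")
    yy, xx = np.mgrid[0:patch_size, 0:patch_size]
    center = (patch_size - 1) / 2.0
    mask = (yy - center) ** 2 + (xx - center) ** 2 <= radius**2
    area = int(mask.sum())
    if area == 0:
        raise ParameterError("nucleus radius too small for the patch")

    od = np.zeros((patch_size, patch_size))
    od[mask] = c_value * iod_per_c / area
    if noise > 0:
        rng = np.random.default_rng(seed)
        od[mask] = np.abs(od[mask] * rng.normal(1.0, noise, size=area))
    pixels = background_intensity * np.power(10.0, -od)
    return ImagePatch(pixels=pixels, background_intensity=background_intensity), mask
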