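"""Shared domain types for the IHC tumor-microenvironment pipeline.

The pipeline moves brightfield field images (RGB, known physical pixel
size) through positive-cell detection, hotspot aggregation, semi-
quantitative tumor-cell scoring and cohort statistics.  The dataclasses
here are the contracts between those stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# Stain models ----------------------------------------------------------------

#: Nickel-enhanced DAB without counterstain (FoxP3 protocol): positive
#: nuclei are near-black on a light background.
DAB_NI = "dab_ni_no_counterstain"
#: Plain DAB over a Mayer's hematoxylin counterstain (IDO protocol):
#: brown positive signal, blue negative nuclei.
DAB_HEMA = "dab_with_hematoxylin"

STAIN_MODELS = (DAB_NI, DAB_HEMA)

# Histological groups, ordered by malignancy ----------------------------------

GROUPS = ("benign", "dysplastic", "in_situ", "pT1", "pT4", "pN1")
INVASIVE_GROUPS = ("pT1", "pT4", "pN1")

# Detection verdicts -----------------------------------------------------------

ACCEPTED = "accepted"
REJECTED_SIZE = "rejected_size"
REJECTED_ASPECT = "rejected_aspect"
REJECTED_EDGE = "rejected_edge"
REJECTED_INTENSITY = "rejected_intensity"
REJECTED_MELANIN = "rejected_melanin"

VERDICTS = (
    ACCEPTED,
    REJECTED_SIZE,
    REJECTED_ASPECT,
    REJECTED_EDGE,
    REJECTED_INTENSITY,
    REJECTED_MELANIN,
)

# Ground-truth object classes (synthetic fields) -------------------------------

CLASS_POSITIVE = "positive"
CLASS_TOO_LARGE = "too_large"
CLASS_ELONGATED = "elongated"
CLASS_FAINT = "faint"
CLASS_EDGE = "edge_touching"
CLASS_MELANIN = "melanin"

OBJECT_CLASSES = (
    CLASS_POSITIVE,
    CLASS_TOO_LARGE,
    CLASS_ELONGATED,
    CLASS_FAINT,
    CLASS_EDGE,
    CLASS_MELANIN,
)

#: The verdict each distractor class is expected to receive from the
#: detector; positives are expected to be accepted.
EXPECTED_VERDICT = {
    CLASS_POSITIVE: ACCEPTED,
    CLASS_TOO_LARGE: REJECTED_SIZE,
    CLASS_ELONGATED: REJECTED_ASPECT,
    CLASS_FAINT: REJECTED_INTENSITY,
    CLASS_EDGE: REJECTED_EDGE,
    CLASS_MELANIN: REJECTED_MELANIN,
}


@dataclass
class FieldImage:
    """One microscope field: RGB pixels plus the physical pixel size."""

    pixels: np.ndarray  # (H, W, 3) uint8
    pixel_size_um: float = 0.11
    stain_model: str = DAB_NI
    image_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("FieldImage requires an (H, W, 3) RGB array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.stain_model not in STAIN_MODELS:
            raise ValueError(f"unknown stain model {self.stain_model!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class GroundTruthObject:
    """One planted object in a synthetic field."""

    centroid_xy_px: tuple[float, float]
    object_class: str
    major_axis_px: float
    minor_axis_px: float
    mean_stain_od: float
    label: int


@dataclass
class GroundTruth:
    """Sidecar annotation for a synthetic field.

    ``label_mask`` holds one distinct positive integer per planted
    object; 0 is background.
    """

    objects: list[GroundTruthObject]
    label_mask: np.ndarray  # (H, W) int

    def objects_of_class(self, object_class: str) -> list[GroundTruthObject]:
        return [o for o in self.objects if o.object_class == object_class]

    @property
    def n_positive(self) -> int:
        return len(self.objects_of_class(CLASS_POSITIVE))


@dataclass
class DetectedCell:
    """One candidate object measured from a field image.

    Measurements are in physical units (µm, µm²); the centroid is in
    pixel coordinates (x, y).  ``verdict`` is None until the exclusion
    rules have run.
    """

    centroid_xy_px: tuple[float, float]
    area_um2: float
    major_axis_um: float
    minor_axis_um: float
    mean_stain_od: float
    touches_edge: bool
    solidity: float = 1.0
    orientation_rad: float = 0.0
    label: int = 0
    verdict: Optional[str] = None

    @property
    def aspect_ratio(self) -> float:
        if self.minor_axis_um <= 0:
            return float("inf")
        return self.major_axis_um / self.minor_axis_um


@dataclass
class FieldCount:
    """Per-field counting outcome: accepted count plus rejection tallies."""

    image_id: Optional[str]
    n_accepted: int
    n_rejected_by_reason: dict[str, int]
    qc_flag: str  # "auto_ok" | "needs_manual_review"
    cells: list[DetectedCell] = field(default_factory=list)

    @property
    def n_candidates(self) -> int:
        return self.n_accepted + sum(self.n_rejected_by_reason.values())


@dataclass
class HotspotResult:
    """Hotspot selection for one lesion."""

    sample_id: str
    selected_field_ids: list
    per_field_counts: list[float]
    aggregate_count: float
    k_requested: int
    short_of_fields: bool = False


@dataclass
class IdoTumorScore:
    """Semi-quantitative IDO tumor-cell score.

    Coverage of IDO-positive tumor cells is binned into categories 0-4;
    staining intensity (1 weak, 2 moderate, 3 strong) is only defined
    for tumors with more than 1 % positive cells.
    """

    coverage_fraction: float
    coverage_category: int
    intensity_category: Optional[int]
    ido_status: str  # "negative" | "positive"
    intensity_group: Optional[str]  # "weak" | "moderate_or_strong"


@dataclass
class DichotomizedMarker:
    """Median split of a continuous marker into low/high."""

    threshold: float
    labels: list  # "low" | "high" (None for missing inputs)


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    method: str
    statistic: float
    p_value: float
    n: int
    df: Optional[int] = None
    adjustment: Optional[str] = None
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n": int(self.n),
        }
        if self.df is not None:
            out["df"] = int(self.df)
        if self.adjustment is not None:
            out["adjustment"] = self.adjustment
        if self.detail:
            out["detail"] = {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.detail.items()
            }
        return out


class OvercrowdedFieldError(RuntimeError):
    """Requested non-overlapping objects cannot be placed in the field."""


class CoxConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed (e.g. complete separation)."""
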