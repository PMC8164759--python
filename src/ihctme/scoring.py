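"""Semi-quantitative IDO tumor-cell scoring and marker dichotomization.

Coverage of IDO-positive tumor cells (fraction of all tumor cells) is
binned into five ordinal categories; staining intensity is scored 1
(weak) to 3 (strong) for tumors with more than 1 % positive cells.
Continuous hotspot marker values are split at the cohort median into
low/high groups for contingency and survival analyses.

The published coverage labels are integer-percent ranges (< 1 %,
1–5 %, 6–10 %, 11–20 %, > 20 %); continuous fractions are assigned by
the half-open partition below so every fraction in [0, 1] maps to
exactly one category:

    [0, 1%) → 0   [1%, 5%] → 1   (5%, 10%] → 2   (10%, 20%] → 3   (20%, 1] → 4
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .datatypes import DichotomizedMarker, IdoTumorScore

IDO_NEGATIVE = "negative"
IDO_POSITIVE = "positive"
INTENSITY_WEAK = "weak"
INTENSITY_MODERATE_OR_STRONG = "moderate_or_strong"


def score_ido_coverage(fraction: float) -> int:
    """Coverage category 0-4 from the fraction of IDO+ tumor cells."""
    if not (isinstance(fraction, (int, float)) and 0.0 <= fraction <= 1.0) or math.isnan(fraction):
        raise ValueError("coverage fraction must lie in [0, 1]")
    if fraction < 0.01:
        return 0
    if fraction <= 0.05:
        return 1
    if fraction <= 0.10:
        return 2
    if fraction <= 0.20:
        return 3
    return 4


def score_ido_intensity(per_cell_intensities: Sequence[int]) -> int:
    """Predominant (modal) intensity category; ties go to the lower category."""
    cats = list(per_cell_intensities)
    if not cats:
        raise ValueError("intensity scoring needs at least one category")
    if any(c not in (1, 2, 3) for c in cats):
        raise ValueError("intensity categories must be 1, 2 or 3")
    counts = {c: cats.count(c) for c in (1, 2, 3)}
    best = max(counts.values())
    return min(c for c, n in counts.items() if n == best)


def dichotomize_ido_status(coverage_category: int) -> str:
    """Category 0 → negative tumor; categories 1-4 → positive."""
    if coverage_category not in (0, 1, 2, 3, 4):
        raise ValueError("coverage category must be 0-4")
    return IDO_NEGATIVE if coverage_category == 0 else IDO_POSITIVE


def group_intensity(intensity_category: int) -> str:
    """Collapse intensity 1 → weak; 2 and 3 → moderate_or_strong."""
    if intensity_category not in (1, 2, 3):
        raise ValueError("intensity category must be 1-3")
    return INTENSITY_WEAK if intensity_category == 1 else INTENSITY_MODERATE_OR_STRONG


def score_tumor(
    coverage_fraction: float,
    per_cell_intensities: Optional[Sequence[int]] = None,
    intensity_category: Optional[int] = None,
) -> IdoTumorScore:
    """Full score for one tumor from its coverage fraction.

    Intensity may be given either as per-cell categories (aggregated by
    the predominant deposit) or directly as a category; it is recorded
    only for IDO-positive tumors (> 1 % coverage).
    """
    cat = score_ido_coverage(coverage_fraction)
    status = dichotomize_ido_status(cat)
    intensity: Optional[int] = None
    if status == IDO_POSITIVE:
        if intensity_category is not None:
            if intensity_category not in (1, 2, 3):
                raise ValueError("intensity category must be 1-3")
            intensity = intensity_category
        elif per_cell_intensities:
            intensity = score_ido_intensity(per_cell_intensities)
    return IdoTumorScore(
        coverage_fraction=float(coverage_fraction),
        coverage_category=cat,
        intensity_category=intensity,
        ido_status=status,
        intensity_group=group_intensity(intensity) if intensity is not None else None,
    )


def dichotomize_by_median(values: Sequence[float], ties: str = "low") -> DichotomizedMarker:
    """Split marker values at their median into low/high groups.

    The threshold is the sample median of the non-missing values.
    Values strictly above the median are "high"; values at or below it
    are "low" (``ties="high"`` flips values equal to the median).
    Missing values keep a ``None`` label.
    """
    if ties not in ("low", "high"):
        raise ValueError("ties must be 'low' or 'high'")
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("need at least two non-missing values to dichotomize")
    threshold = float(np.median(finite))
    labels: list[Optional[str]] = []
    for v in arr:
        if not np.isfinite(v):
            labels.append(None)
        elif v > threshold or (ties == "high" and v == threshold):
            labels.append("high")
        else:
            labels.append("low")
    return DichotomizedMarker(threshold=threshold, labels=labels)
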