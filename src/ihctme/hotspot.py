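"""Hotspot field selection and per-sample aggregation.

A lesion is quantified from the few microscope fields with the highest
positive-cell density ("hot spots"): depending on lesion size, the 3
or 5 densest tumor-containing fields are selected and their accepted
counts averaged into one value per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .datatypes import HotspotResult


@dataclass
class LesionImageSet:
    """Candidate fields of one lesion with their accepted counts."""

    sample_id: str
    field_ids: list
    counts: list[float]
    tumor_presence: list[bool]
    lesion_area_mm2: float

    def __post_init__(self) -> None:
        if not self.field_ids:
            raise ValueError("a lesion needs at least one field")
        if not (len(self.field_ids) == len(self.counts) == len(self.tumor_presence)):
            raise ValueError("field_ids, counts and tumor_presence must align")
        if self.lesion_area_mm2 <= 0:
            raise ValueError("lesion_area_mm2 must be positive")


def choose_field_number(lesion_area_mm2: float, threshold_mm2: float = 2.0) -> int:
    """3 fields for small lesions, 5 for lesions at or above the area threshold."""
    if lesion_area_mm2 <= 0:
        raise ValueError("lesion area must be positive")
    return 5 if lesion_area_mm2 >= threshold_mm2 else 3


def aggregate_sample_count(per_field_counts: Sequence[float]) -> float:
    """Arithmetic mean of the selected fields' counts.

    The mean is the per-sample marker value; means of integer counts
    naturally produce half-integer values (e.g. [56, 57] → 56.5).
    """
    counts = list(per_field_counts)
    if not counts:
        raise ValueError("cannot aggregate an empty list of counts")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    return float(sum(counts)) / len(counts)


def select_hotspots(lesion: LesionImageSet, k: int) -> HotspotResult:
    """Pick the k tumor-containing fields with the largest counts.

    Ties are broken by ascending field index, so the selection is
    deterministic.  If fewer than k tumor-containing fields exist, all
    eligible fields are used and the result is flagged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    eligible = [
        (i, fid, c)
        for i, (fid, c, tp) in enumerate(
            zip(lesion.field_ids, lesion.counts, lesion.tumor_presence)
        )
        if tp
    ]
    if not eligible:
        raise ValueError(f"lesion {lesion.sample_id}: no tumor-containing field")
    ranked = sorted(eligible, key=lambda t: (-t[2], t[0]))
    chosen = ranked[: min(k, len(ranked))]
    chosen.sort(key=lambda t: t[0])  # report in field order
    counts = [c for _, _, c in chosen]
    return HotspotResult(
        sample_id=lesion.sample_id,
        selected_field_ids=[fid for _, fid, _ in chosen],
        per_field_counts=counts,
        aggregate_count=aggregate_sample_count(counts),
        k_requested=k,
        short_of_fields=len(chosen) < k,
    )


def hotspot_value(lesion: LesionImageSet, threshold_mm2: float = 2.0) -> HotspotResult:
    """Convenience: choose k from lesion size, then select and aggregate."""
    k = choose_field_number(lesion.lesion_area_mm2, threshold_mm2)
    return select_hotspots(lesion, k)
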