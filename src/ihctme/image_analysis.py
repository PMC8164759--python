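"""Automated positive-cell detection in brightfield IHC field images.

The detector reproduces a rule-based digital image analysis for
chromogen-stained cells:

1. stain separation — per-pixel optical density (OD) of the chromogen
   (gray OD for nickel-DAB without counterstain, Ruifrok–Johnston color
   deconvolution for DAB over hematoxylin);
2. melanin rejection — an HSV color gate removing endogenous pigment
   before any segmentation;
3. candidate segmentation — connected components of above-threshold OD
   within the retained area, measured in physical units;
4. exclusion rules, applied in a fixed order (size → aspect ratio →
   edge contact → staining intensity), so that rejection tallies are
   reproducible.

An object is counted only if its area lies inside the configured
window, its major/minor axis ratio is ≤ the aspect ceiling (2.0 by
default, boundary inclusive), it does not touch the image border, and
its mean stain OD clearly stands out from the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.color import rgb2hed, rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import dilation, disk

from .datatypes import (
    ACCEPTED,
    DAB_HEMA,
    DAB_NI,
    REJECTED_ASPECT,
    REJECTED_EDGE,
    REJECTED_INTENSITY,
    REJECTED_MELANIN,
    REJECTED_SIZE,
    STAIN_MODELS,
    DetectedCell,
    FieldCount,
    FieldImage,
)

QC_AUTO_OK = "auto_ok"
QC_NEEDS_REVIEW = "needs_manual_review"


@dataclass
class DetectionCriteria:
    """Acceptance rules and color-model thresholds for one stain model.

    Areas are µm², axes µm.  ``max_aspect_ratio`` uses a strict ``>``
    comparison for rejection, so a ratio of exactly 2.0 is accepted.
    The intensity rule has two variants: Otsu's threshold on the stain
    OD channel (with an absolute OD floor so a blank field yields no
    accepted cells), or background mean + k·SD.
    """

    stain_model: str = DAB_NI
    max_aspect_ratio: float = 2.0
    min_area_um2: float = 10.0
    max_area_um2: float = 120.0
    edge_margin_px: int = 0
    intensity_rule: str = "otsu_on_stain_channel"  # or "background_mean_plus_k_sd"
    intensity_k: float = 3.0
    detection_floor_od: float = 0.08
    min_accept_od: float = 0.20
    # melanin gate: hue band may wrap around 0 (lo > hi means wrapped)
    melanin_hue_band: tuple[float, float] = (0.92, 0.15)
    melanin_saturation_min: float = 0.10
    melanin_saturation_max: float = 0.55
    melanin_value_max: float = 0.50
    melanin_dilation_px: int = 2
    min_candidate_px: int = 5
    qc_candidate_factor: float = 3.0
    qc_min_solidity: float = 0.80

    def __post_init__(self) -> None:
        if self.max_aspect_ratio < 1:
            raise ValueError("max_aspect_ratio must be >= 1")
        if not 0 < self.min_area_um2 < self.max_area_um2:
            raise ValueError("need 0 < min_area_um2 < max_area_um2")
        if self.stain_model not in STAIN_MODELS:
            raise ValueError(f"unknown stain model {self.stain_model!r}")

    @classmethod
    def for_model(cls, stain_model: str) -> "DetectionCriteria":
        """Default criteria tuned per stain chemistry.

        The DAB channel extracted by color deconvolution runs on a
        compressed OD scale compared with the gray OD of an
        uncounterstained nickel-DAB field, so its floors are lower.
        """
        if stain_model == DAB_NI:
            return cls(stain_model=DAB_NI)
        if stain_model == DAB_HEMA:
            return cls(stain_model=DAB_HEMA, detection_floor_od=0.04, min_accept_od=0.12)
        raise ValueError(f"unknown stain model {stain_model!r}")


def separate_stain_channels(image: FieldImage, stain_model: str | None = None) -> dict[str, np.ndarray]:
    """Per-pixel stain optical-density maps for the modeled chromogens.

    Returns a dict keyed by stain name.  For ``dab_ni_no_counterstain``
    the single map is the mean gray optical density; for
    ``dab_with_hematoxylin`` the DAB and hematoxylin maps come from
    Ruifrok–Johnston deconvolution.  A blank white image maps to OD ≈ 0
    everywhere; maps are clipped at 0.
    """
    model = stain_model or image.stain_model
    rgb = np.asarray(image.pixels)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("stain separation requires an RGB image")
    if model == DAB_NI:
        transmit = np.clip(rgb.astype(float) / 255.0, 1e-3, 1.0)
        od = -np.log10(transmit).mean(axis=2)
        return {"dab_ni": np.clip(od, 0.0, None)}
    if model == DAB_HEMA:
        hed = rgb2hed(rgb)
        return {
            "dab": np.clip(hed[..., 2], 0.0, None),
            "hematoxylin": np.clip(hed[..., 0], 0.0, None),
        }
    raise ValueError(f"unknown stain model {model!r}")


def primary_stain_od(image: FieldImage, stain_model: str | None = None) -> np.ndarray:
    """The OD map of the chromogen being counted."""
    model = stain_model or image.stain_model
    maps = separate_stain_channels(image, model)
    return maps["dab_ni" if model == DAB_NI else "dab"]


def melanin_mask(image: FieldImage, criteria: DetectionCriteria) -> np.ndarray:
    """Boolean mask of pixels classified as melanin pigment (pre-dilation)."""
    hsv = rgb2hsv(np.asarray(image.pixels))
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    lo, hi = criteria.melanin_hue_band
    in_band = ((hue >= lo) | (hue <= hi)) if lo > hi else ((hue >= lo) & (hue <= hi))
    return (
        in_band
        & (sat >= criteria.melanin_saturation_min)
        & (sat <= criteria.melanin_saturation_max)
        & (val <= criteria.melanin_value_max)
    )


def melanin_rejection_filter(image: FieldImage, criteria: DetectionCriteria) -> np.ndarray:
    """Mask of retained (non-melanin) pixels, True where analysis may proceed.

    The raw melanin mask is dilated slightly so noisy pigment borders
    do not leak into segmentation.
    """
    mel = melanin_mask(image, criteria)
    if criteria.melanin_dilation_px > 0 and mel.any():
        mel = dilation(mel, disk(criteria.melanin_dilation_px))
    return ~mel


def _measure_components(
    binary: np.ndarray,
    od_map: np.ndarray,
    pixel_size_um: float,
    edge_margin_px: int,
) -> list[DetectedCell]:
    h, w = binary.shape
    lbl = cc_label(binary, connectivity=2)
    cells: list[DetectedCell] = []
    for rp in regionprops(lbl, intensity_image=od_map):
        minr, minc, maxr, maxc = rp.bbox
        touches = (
            minr <= edge_margin_px
            or minc <= edge_margin_px
            or maxr >= h - edge_margin_px
            or maxc >= w - edge_margin_px
        )
        cells.append(
            DetectedCell(
                centroid_xy_px=(float(rp.centroid[1]), float(rp.centroid[0])),
                area_um2=float(rp.area) * pixel_size_um**2,
                major_axis_um=float(rp.axis_major_length) * pixel_size_um,
                minor_axis_um=float(rp.axis_minor_length) * pixel_size_um,
                mean_stain_od=float(rp.intensity_mean),
                touches_edge=bool(touches),
                solidity=float(rp.solidity),
                orientation_rad=float(rp.orientation),
                label=int(rp.label),
            )
        )
    return cells


def detect_candidates(
    od_map: np.ndarray,
    retained_mask: np.ndarray,
    criteria: DetectionCriteria,
    pixel_size_um: float,
) -> list[DetectedCell]:
    """Segment candidate cells: above-floor connected components in the retained area.

    Components smaller than ``min_candidate_px`` pixels are treated as
    noise specks and dropped.  No verdicts are assigned here.
    """
    if od_map.shape != retained_mask.shape:
        raise ValueError("OD map and retained mask must share a shape")
    binary = (od_map >= criteria.detection_floor_od) & retained_mask
    cells = _measure_components(binary, od_map, pixel_size_um, criteria.edge_margin_px)
    min_area = criteria.min_candidate_px * pixel_size_um**2
    return [c for c in cells if c.area_um2 >= min_area]


def intensity_threshold(od_map: np.ndarray, criteria: DetectionCriteria) -> float:
    """Acceptance OD threshold implementing "clearly stands out from the background"."""
    if criteria.intensity_rule == "otsu_on_stain_channel":
        vals = od_map.ravel()
        if np.ptp(vals) <= 1e-9:
            return criteria.min_accept_od
        return float(max(threshold_otsu(vals), criteria.min_accept_od))
    if criteria.intensity_rule == "background_mean_plus_k_sd":
        bg = od_map[od_map < criteria.detection_floor_od]
        if bg.size == 0:
            return criteria.min_accept_od
        return float(
            max(bg.mean() + criteria.intensity_k * bg.std(), criteria.min_accept_od)
        )
    raise ValueError(f"unknown intensity rule {criteria.intensity_rule!r}")


def apply_exclusion_rules(
    cells: list[DetectedCell],
    criteria: DetectionCriteria,
    image_bounds: tuple[int, int] | None = None,
    od_threshold: float | None = None,
) -> list[DetectedCell]:
    """Assign one verdict per candidate, testing rules in fixed order.

    Order: size → aspect ratio → edge contact → intensity.  A cell is
    accepted only if it passes every rule; the recorded verdict is the
    first failing rule.  Aspect ratio uses a strict ``>`` rejection, so
    exactly 2.0 is accepted.
    """
    thr = criteria.min_accept_od if od_threshold is None else od_threshold
    out = []
    for cell in cells:
        if not criteria.min_area_um2 <= cell.area_um2 <= criteria.max_area_um2:
            verdict = REJECTED_SIZE
        elif cell.aspect_ratio > criteria.max_aspect_ratio:
            verdict = REJECTED_ASPECT
        elif cell.touches_edge:
            verdict = REJECTED_EDGE
        elif cell.mean_stain_od < thr:
            verdict = REJECTED_INTENSITY
        else:
            verdict = ACCEPTED
        out.append(replace(cell, verdict=verdict))
    return out


def count_field(
    image: FieldImage,
    criteria: DetectionCriteria | None = None,
) -> FieldCount:
    """Full per-field pipeline: separate, reject melanin, segment, judge, tally.

    Melanin regions large enough to be candidate-sized are reported as
    candidates with a ``rejected_melanin`` verdict so every tallied
    object carries exactly one verdict and the counts reconcile.
    """
    criteria = criteria or DetectionCriteria.for_model(image.stain_model)
    od = primary_stain_od(image, criteria.stain_model)
    retained = melanin_rejection_filter(image, criteria)
    cells = detect_candidates(od, retained, criteria, image.pixel_size_um)
    thr = intensity_threshold(od, criteria)
    cells = apply_exclusion_rules(cells, criteria, image.shape, thr)

    mel = melanin_mask(image, criteria)
    mel_cells = _measure_components(mel, od, image.pixel_size_um, criteria.edge_margin_px)
    min_area = criteria.min_candidate_px * image.pixel_size_um**2
    mel_cells = [
        replace(c, verdict=REJECTED_MELANIN)
        for c in mel_cells
        if c.area_um2 >= min_area
    ]

    all_cells = cells + mel_cells
    n_accepted = sum(1 for c in cells if c.verdict == ACCEPTED)
    reasons: dict[str, int] = {}
    for c in all_cells:
        if c.verdict != ACCEPTED:
            reasons[c.verdict] = reasons.get(c.verdict, 0) + 1

    n_candidates = len(cells)
    solidity = (
        float(np.mean([c.solidity for c in cells])) if cells else 1.0
    )
    needs_review = (
        n_candidates > criteria.qc_candidate_factor * max(n_accepted, 1)
        or solidity < criteria.qc_min_solidity
    )
    return FieldCount(
        image_id=image.image_id,
        n_accepted=n_accepted,
        n_rejected_by_reason=reasons,
        qc_flag=QC_NEEDS_REVIEW if needs_review else QC_AUTO_OK,
        cells=all_cells,
    )


# Overlay rendering ------------------------------------------------------------

_VERDICT_COLORS = {
    ACCEPTED: (0, 200, 0),
    REJECTED_SIZE: (230, 120, 0),
    REJECTED_ASPECT: (230, 0, 0),
    REJECTED_EDGE: (0, 120, 230),
    REJECTED_INTENSITY: (180, 180, 0),
    REJECTED_MELANIN: (160, 0, 160),
}


def render_overlay(image: FieldImage, count: FieldCount) -> np.ndarray:
    """RGB copy of the field with fitted-ellipse outlines colored by verdict."""
    from skimage.draw import ellipse_perimeter

    out = np.asarray(image.pixels).copy()
    h, w = out.shape[:2]
    ps = image.pixel_size_um
    for cell in count.cells:
        cx, cy = cell.centroid_xy_px
        ry = max(int(cell.major_axis_um / ps / 2), 1)
        rx = max(int(cell.minor_axis_um / ps / 2), 1)
        rr, cc = ellipse_perimeter(
            int(cy), int(cx), ry, rx,
            orientation=cell.orientation_rad, shape=(h, w),
        )
        out[rr, cc] = _VERDICT_COLORS.get(cell.verdict, (0, 0, 0))
    return out
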