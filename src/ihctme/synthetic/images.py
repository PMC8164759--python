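"""Synthetic brightfield field images with per-object ground truth.

Each generated field emulates one ×200 photomicrograph of an
immunostained melanocytic lesion: positively stained cells, distractor
objects that each violate exactly one detector acceptance rule, and
melanin pigment granules, rendered over a light background.  The
reference geometry is 2560 × 1920 px at 0.11 µm/px.

Two stain chemistries are modeled:

* ``dab_ni_no_counterstain`` — nickel-enhanced DAB (FoxP3 protocol):
  near-black nuclei, no counterstain.
* ``dab_with_hematoxylin`` — plain DAB over Mayer's hematoxylin (IDO
  protocol): brown positive signal plus blue negative nuclei rendered
  as background decoration.

Every planted object is annotated in a label mask and an object list,
so the detector can be validated against construction-time truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from ..datatypes import (
    CLASS_EDGE,
    CLASS_ELONGATED,
    CLASS_FAINT,
    CLASS_MELANIN,
    CLASS_POSITIVE,
    CLASS_TOO_LARGE,
    DAB_HEMA,
    DAB_NI,
    STAIN_MODELS,
    FieldImage,
    GroundTruth,
    GroundTruthObject,
    OvercrowdedFieldError,
)

# Rendered colors (8-bit RGB).  DAB-Ni is a desaturated blue-black,
# plain DAB a saturated brown, melanin a dark low-saturation brown,
# hematoxylin a mid blue.  Chosen so that melanin occupies a hue /
# saturation / value region distinct from both chromogens.
BACKGROUND_RGB = (245, 245, 245)
DABNI_RGB = (45, 45, 75)
DAB_BROWN_RGB = (100, 55, 15)
HEMATOXYLIN_RGB = (70, 80, 160)
MELANIN_RGB = (95, 80, 70)

# Blend factor used for "faint" distractors: strong enough to segment,
# too weak to clearly stand out from the background.
FAINT_ALPHA = {DAB_NI: 0.25, DAB_HEMA: 0.60}

_PLACEMENT_MARGIN_PX = 5.0
_MAX_ATTEMPTS_PER_OBJECT = 400


@dataclass
class ImageSimParams:
    """Parameters of one synthetic field.

    Geometry defaults follow the reference acquisition setup
    (2560 × 1920 px, 0.11 µm/px); object counts default to a realistic
    hotspot-field density for a lymphocyte marker.
    """

    width_px: int = 2560
    height_px: int = 1920
    pixel_size_um: float = 0.11
    n_positive: int = 50
    n_large_distractors: int = 3
    n_elongated_distractors: int = 4
    n_faint_distractors: int = 4
    n_edge_cells: int = 3
    n_melanin_granules: int = 20
    stain_model: str = DAB_NI
    background_noise_sd: float = 3.0
    overlap_fraction: float = 0.0
    overlap_clump_size: int = 4
    n_counterstain_nuclei: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        counts = (
            self.n_positive,
            self.n_large_distractors,
            self.n_elongated_distractors,
            self.n_faint_distractors,
            self.n_edge_cells,
            self.n_melanin_granules,
        )
        if any(c < 0 for c in counts):
            raise ValueError("object counts must be non-negative")
        if self.stain_model not in STAIN_MODELS:
            raise ValueError(f"unknown stain model {self.stain_model!r}")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be non-negative")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.overlap_clump_size < 2:
            raise ValueError("overlap_clump_size must be >= 2")


def _sample_geometry(rng: np.random.Generator, object_class: str, ps: float):
    """Sample (major_um, minor_um) for one object of the given class.

    Positives sit comfortably inside the default acceptance window
    (area 10-120 µm², aspect ≤ 2); each distractor class breaches
    exactly the rule it is named after.
    """
    if object_class in (CLASS_POSITIVE, CLASS_FAINT):
        major = rng.uniform(6.0, 10.0)
        aspect = rng.uniform(1.05, 1.7)
    elif object_class == CLASS_EDGE:
        # circular, so the border-clipped remnant stays below the
        # aspect ceiling and inside the area window
        major = rng.uniform(8.0, 10.0)
        aspect = 1.0
    elif object_class == CLASS_TOO_LARGE:
        # target area well above 2x the acceptance ceiling
        area = rng.uniform(260.0, 380.0)
        aspect = rng.uniform(1.0, 1.5)
        major = 2.0 * np.sqrt(area * aspect / np.pi)
        return major, major / aspect
    elif object_class == CLASS_ELONGATED:
        aspect = rng.uniform(2.5, 4.0)
        major = rng.uniform(9.0, 14.0)
    elif object_class == CLASS_MELANIN:
        major = rng.uniform(6.0, 9.0)
        aspect = rng.uniform(1.0, 1.6)
    else:  # pragma: no cover
        raise ValueError(object_class)
    return major, major / aspect


def _far_enough(cy, cx, rad, placed):
    for (py, px, prad) in placed:
        if np.hypot(cy - py, cx - px) < rad + prad + _PLACEMENT_MARGIN_PX:
            return False
    return True


def generate_field_image(params: ImageSimParams) -> tuple[FieldImage, GroundTruth]:
    """Render one synthetic field and its ground truth.

    Deterministic in ``params.seed``: identical parameters reproduce
    identical pixels and annotations.  Raises
    :class:`OvercrowdedFieldError` if the requested non-overlapping
    objects cannot be placed within a bounded number of attempts.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.height_px, params.width_px
    ps = params.pixel_size_um

    img = np.full((h, w, 3), BACKGROUND_RGB, dtype=float)
    label_mask = np.zeros((h, w), dtype=np.int32)

    stain_rgb = DABNI_RGB if params.stain_model == DAB_NI else DAB_BROWN_RGB
    faint_alpha = FAINT_ALPHA[params.stain_model]

    plan: list[str] = (
        [CLASS_POSITIVE] * params.n_positive
        + [CLASS_TOO_LARGE] * params.n_large_distractors
        + [CLASS_ELONGATED] * params.n_elongated_distractors
        + [CLASS_FAINT] * params.n_faint_distractors
        + [CLASS_EDGE] * params.n_edge_cells
        + [CLASS_MELANIN] * params.n_melanin_granules
    )

    placed: list[tuple[float, float, float, bool]] = []
    objects: list[GroundTruthObject] = []
    label = 0

    # overlap mode: positives are laid down in chained clumps so that
    # neighbouring cells genuinely merge (emulating touching nuclei)
    clumping = params.overlap_fraction > 0
    chain_len = 0
    chain_start = 0
    prev_member: tuple[float, float, float] | None = None

    for object_class in plan:
        major_um, minor_um = _sample_geometry(rng, object_class, ps)
        major_px = major_um / ps
        minor_px = minor_um / ps
        rad = major_px / 2.0
        theta = rng.uniform(0.0, np.pi)

        in_chain = (
            clumping
            and object_class == CLASS_POSITIVE
            and chain_len % params.overlap_clump_size != 0
            and prev_member is not None
        )

        ok = False
        for _ in range(_MAX_ATTEMPTS_PER_OBJECT):
            if object_class == CLASS_EDGE:
                # center sits just inside one border so only a cap is
                # clipped off: the remnant keeps acceptable size/aspect
                side = rng.integers(4)
                off = rng.uniform(0.35, 0.6) * rad
                t_row = rng.uniform(rad + 2, h - rad - 2)
                t_col = rng.uniform(rad + 2, w - rad - 2)
                cy, cx = {
                    0: (off, t_col),
                    1: (h - 1 - off, t_col),
                    2: (t_row, off),
                    3: (t_row, w - 1 - off),
                }[int(side)]
                theta_obj = 0.0
            elif in_chain:
                py, px, prad = prev_member
                d = (1.0 - params.overlap_fraction) * (prad + rad)
                ang = rng.uniform(0.0, 2 * np.pi)
                cy, cx = py + d * np.sin(ang), px + d * np.cos(ang)
                theta_obj = theta
                if not (rad + 2 <= cy <= h - rad - 2 and rad + 2 <= cx <= w - rad - 2):
                    continue
            else:
                cy = rng.uniform(rad + 2, h - rad - 2)
                cx = rng.uniform(rad + 2, w - rad - 2)
                theta_obj = theta
            others = placed[:chain_start] if in_chain else placed
            if _far_enough(cy, cx, rad, others):
                ok = True
                break
        if not ok:
            raise OvercrowdedFieldError(
                f"could not place a {object_class!r} object after "
                f"{_MAX_ATTEMPTS_PER_OBJECT} attempts; reduce object counts "
                "or enlarge the field"
            )

        rr, cc = draw_ellipse(
            cy, cx, major_px / 2.0, minor_px / 2.0,
            rotation=theta_obj, shape=(h, w),
        )
        if rr.size == 0:
            raise OvercrowdedFieldError("degenerate object rasterized to zero pixels")

        if object_class == CLASS_MELANIN:
            color = np.array(MELANIN_RGB, dtype=float)
        elif object_class == CLASS_FAINT:
            bg = np.array(BACKGROUND_RGB, dtype=float)
            color = bg + faint_alpha * (np.array(stain_rgb, dtype=float) - bg)
        else:
            color = np.array(stain_rgb, dtype=float)

        img[rr, cc] = color
        label += 1
        label_mask[rr, cc] = label
        if clumping and object_class == CLASS_POSITIVE:
            if not in_chain:
                chain_start = len(placed)
            chain_len += 1
            prev_member = (cy, cx, rad)
        placed.append((cy, cx, rad))
        objects.append(
            GroundTruthObject(
                centroid_xy_px=(float(cx), float(cy)),
                object_class=object_class,
                major_axis_px=float(major_px),
                minor_axis_px=float(minor_px),
                mean_stain_od=0.0,  # filled below from the rendered image
                label=label,
            )
        )

    # hematoxylin counterstain nuclei (decoration, not ground-truth objects)
    if params.stain_model == DAB_HEMA:
        n_nuc = params.n_counterstain_nuclei
        if n_nuc is None:
            n_nuc = int(round(4e-5 * h * w))
        for _ in range(n_nuc):
            major_um = rng.uniform(5.0, 8.0)
            minor_um = major_um / rng.uniform(1.0, 1.5)
            rad = major_um / ps / 2.0
            for _ in range(_MAX_ATTEMPTS_PER_OBJECT):
                cy = rng.uniform(rad + 2, h - rad - 2)
                cx = rng.uniform(rad + 2, w - rad - 2)
                if _far_enough(cy, cx, rad, placed):
                    rr, cc = draw_ellipse(
                        cy, cx, major_um / ps / 2.0, minor_um / ps / 2.0,
                        rotation=rng.uniform(0, np.pi), shape=(h, w),
                    )
                    img[rr, cc] = HEMATOXYLIN_RGB
                    break
            # counterstain is decoration: silently skip if crowded

    if params.background_noise_sd > 0:
        img += rng.normal(0.0, params.background_noise_sd, img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    field = FieldImage(
        pixels=pixels,
        pixel_size_um=ps,
        stain_model=params.stain_model,
        image_id=f"synthetic-{params.seed}",
    )

    # record each object's realized stain OD from the rendered image
    from ..image_analysis import primary_stain_od  # local import: no cycle at module load

    od = primary_stain_od(field)
    for obj in objects:
        sel = label_mask == obj.label
        if sel.any():
            obj.mean_stain_od = float(od[sel].mean())

    return field, GroundTruth(objects=objects, label_mask=label_mask)


def write_field_image(
    field: FieldImage,
    truth: GroundTruth,
    out_prefix: str | Path,
    image_format: str = "tiff",
) -> dict[str, Path]:
    """Write image, label mask and JSON object list next to each other.

    The image is 8-bit RGB TIFF (or PNG), the label mask 16-bit
    single-channel TIFF, the object list a JSON sidecar.
    """
    import tifffile
    from PIL import Image

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if image_format == "tiff":
        paths["image"] = out_prefix.with_suffix(".tif")
        tifffile.imwrite(paths["image"], field.pixels)
    elif image_format == "png":
        paths["image"] = out_prefix.with_suffix(".png")
        Image.fromarray(field.pixels).save(paths["image"])
    else:
        raise ValueError("image_format must be 'tiff' or 'png'")

    paths["label_mask"] = Path(str(out_prefix) + "_labels.tif")
    tifffile.imwrite(paths["label_mask"], truth.label_mask.astype(np.uint16))

    paths["objects"] = Path(str(out_prefix) + "_objects.json")
    meta = {
        "pixel_size_um": field.pixel_size_um,
        "stain_model": field.stain_model,
        "objects": [asdict(o) for o in truth.objects],
    }
    paths["objects"].write_text(json.dumps(meta, indent=1))
    return paths
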