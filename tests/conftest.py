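"""Shared fixtures: small synthetic fields at the reference pixel pitch.

Image tests run on quarter-scale fields (1280 × 960 px at 0.11 µm/px)
with object counts scaled to keep the reference per-area density, so
the suite stays fast without changing the physics of the problem.
"""

import numpy as np
import pytest

from ihctme.datatypes import DAB_NI
from ihctme.synthetic import ImageSimParams, generate_field_image


def quarter_field_params(seed: int = 0, stain_model: str = DAB_NI, **overrides) -> ImageSimParams:
    """Quarter-area field with default-density object counts (50/4 ≈ 12 positives)."""
    base = dict(
        width_px=1280,
        height_px=960,
        pixel_size_um=0.11,
        n_positive=12,
        n_large_distractors=1,
        n_elongated_distractors=1,
        n_faint_distractors=1,
        n_edge_cells=1,
        n_melanin_granules=5,
        stain_model=stain_model,
        seed=seed,
    )
    base.update(overrides)
    return ImageSimParams(**base)


def verdicts_by_class(field_count, truth):
    """Map each ground-truth object to the verdict of the detected cell covering it."""
    lm = truth.label_mask
    h, w = lm.shape
    out = []
    for obj in truth.objects:
        hits = [
            c
            for c in field_count.cells
            if lm[
                min(int(round(c.centroid_xy_px[1])), h - 1),
                min(int(round(c.centroid_xy_px[0])), w - 1),
            ]
            == obj.label
        ]
        out.append((obj.object_class, hits[0].verdict if hits else None))
    return out


@pytest.fixture(scope="session")
def dabni_field():
    """One quarter-scale DAB-Ni field with all object classes, reused across tests."""
    return generate_field_image(quarter_field_params(seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
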