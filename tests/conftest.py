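import numpy as np
import pytest

import taproot as tp
from taproot.synth import training_profiles


@pytest.fixture(scope="session")
def detip_model():
    """One de-tip model shared by the whole suite (training is seeded)."""
    return tp.train_detip(training_profiles(300, seed=1), seed=1)


@pytest.fixture()
def rect_root():
    """Axis-aligned 200x50 rectangular root with its ground truth."""
    params = tp.RootShapeParams(
        length_px=200, max_width_px=50, fill_exponent=0.0, tip_bluntness=1.0
    )
    return tp.render_root(params)


def measure_root(mask, truth, model):
    """Full pipeline on one synthetic root; returns a summary dict."""
    contour = tp.extract_contour(mask)
    tip = tp.find_tip(contour)
    midline = tp.trace_midline(mask, tip)
    profile = tp.detip(tp.sample_widths(mask, midline), model)
    straight = tp.straighten(profile)
    shoulder_first = midline.points[::-1]
    if mask.metadata.get("residual_tip_px", 0) == 0:
        true_cut = len(profile.widths_px)
    else:
        d = np.hypot(
            shoulder_first[:, 0] - truth.true_tip[0],
            shoulder_first[:, 1] - truth.true_tip[1],
        )
        true_cut = int(np.argmin(d))
    return {
        "profile": profile,
        "midline": midline,
        "length_px": profile.cut_index,
        "max_width_px": float(profile.body_widths_px.max()),
        "straight_area_px": straight.area_px,
        "mask_area_px": mask.area_px,
        "true_cut_measured": true_cut,
    }
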