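"""Measure one synthetic root end to end and compare with ground truth.

Renders a bent, tapered root with a residual taproot, runs the geometric
pipeline (contour -> tip -> midline -> widths -> de-tip -> straighten),
and prints the measured traits next to the values the generator used.
"""

import numpy as np

import taproot as tp
from taproot.synth import training_profiles
from taproot.traits import measure_traits

params = tp.RootShapeParams(
    length_px=600,
    max_width_px=90,
    fill_exponent=1.3,
    tip_bluntness=0.4,
    shoulder_radius_frac=0.4,
    bend_amplitude_px=25,
    bend_wavelength_px=800,
    residual_tip_px=60,
)
mask, truth = tp.render_root(params)
print(f"rendered {mask.raster.shape} mask, {mask.area_px} foreground px")

model = tp.train_detip(training_profiles(300, seed=1), seed=1)
contour = tp.extract_contour(mask)
tip = tp.find_tip(contour)
midline = tp.trace_midline(mask, tip)
profile = tp.detip(tp.sample_widths(mask, midline), model)
straight = tp.straighten(profile, detipped=True)
record = measure_traits(profile, straight)

print(f"measured length   {record.length_mm:7.1f} px  (true {truth.true_length_px:.0f})")
print(f"measured max width{record.max_width_mm:7.1f} px  (true {truth.true_max_width_px:.1f})")
print(f"de-tip cut index  {profile.cut_index:7d}     (true body rows {truth.true_cut_index})")
print(f"root size         {record.root_size_mm2:7.0f} px² (body truth {truth.true_area_px2})")
print(f"tip angle         {record.tip_angle_deg:7.1f} deg")
print(f"shoulder hull     {record.shoulder_hull_area_mm2:7.0f} px²")
# Lengths/areas print in px because mm_per_px = 1 for synthetic masks;
# with a real 100 mm scale bar the same numbers arrive in mm and mm².
n = min(len(profile.body_widths_px), len(truth.true_width_function))
mid_err = np.median(
    np.abs(profile.body_widths_px[25 : n - 25] - truth.true_width_function[25 : n - 25])
)
print(f"median interior width error vs generating function: {mid_err:.2f} px")
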