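"""Segment a root photograph into a binary mask.

Builds a synthetic "photograph" (an orange root on dark felt with sensor
noise), runs the grayscale -> bilateral filter -> threshold -> largest
component chain, and reports the recovered area and physical size.
"""

import numpy as np

import taproot as tp
from taproot.masking import MaskingConfig, rgb_to_mask
from taproot.pipeline import parse_filename

rng = np.random.default_rng(0)
mask_true, _ = tp.render_root(
    tp.RootShapeParams(length_px=500, max_width_px=90, fill_exponent=1.2, tip_bluntness=0.4)
)
photo = np.zeros(mask_true.raster.shape + (3,), dtype=float)
photo[mask_true.raster] = (235, 130, 30)  # carrot orange
photo += rng.normal(0, 8, photo.shape)  # sensor noise
photo = np.clip(photo, 0, 255).astype(np.uint8)

meta, mm_per_px = parse_filename("Nantes_001_500.png")  # 100 mm bar = 500 px
mask = rgb_to_mask(photo, MaskingConfig(background_polarity="dark"), mm_per_px=mm_per_px, metadata=meta)

err = abs(mask.area_px - mask_true.area_px) / mask_true.area_px
print(f"true foreground: {mask_true.area_px} px; segmented: {mask.area_px} px "
      f"({err:.2%} error)")
print(f"at {mm_per_px} mm/px the root covers {mask.area_mm2:.0f} mm²")
print(f"metadata from filename: {mask.metadata}")
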