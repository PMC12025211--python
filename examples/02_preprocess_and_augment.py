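"""Preprocess a CT slice and build a minority augmentation plan.

Shows the window -> stretch -> resize chain and how the augmentation-ratio
design variable d_a turns into an exact oversampling plan: the minority
class is raised to round(d_a * n_majority) samples via seeded rotations
and flips.
"""

from ctbalance import PhantomParams, generate_patient, make_augmentation_plan
from ctbalance.preprocess import apply_hu_window, histogram_stretch, resize_image
from ctbalance.types import RawSlice

v = generate_patient(PhantomParams(image_size=64, slices_per_patient=40), patient_seed=3)
sl = RawSlice(v.slices[0].astype(float), v.pixel_spacing_mm)
print(f"raw HU range: [{sl.hu.min():.0f}, {sl.hu.max():.0f}]")

windowed = apply_hu_window(sl)                      # clip to [-190, 150]
stretched = histogram_stretch(windowed)             # percentiles -> [0, 1]
small = resize_image(stretched, 32)                 # bilinear downsample
print(f"after window: [{windowed.hu.min():.0f}, {windowed.hu.max():.0f}]")
print(f"after stretch: [{stretched.intensity.min():.2f}, {stretched.intensity.max():.2f}]")
print(f"resized {small.native_size} -> {small.current_size} "
      f"(area correction factor {small.resize_factor ** 2:.0f})")

# the clinical imbalance regime: 380 L3 vs 10984 non-L3 training slices
plan = make_augmentation_plan(n_minority=380, n_majority=10984, d_a=0.20, seed=0)
print(f"\nd_a = 0.20: minority target {plan.target_minority} "
      f"({plan.n_augmented_needed} augmented copies needed)")
print("first ops:", plan.op_sequence[:3])
# target = round(0.20 * 10984) = 2197; d_a = 1.0 would demand exact 1:1 balance.
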