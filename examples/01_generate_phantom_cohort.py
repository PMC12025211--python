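"""Generate a synthetic imbalanced CT cohort and inspect its structure.

Phantom patients mimic the class-imbalance regime of abdomen-pelvis CT:
only ~5% of slices per volume are at the L3 vertebral level, and the
tissue intensities are drawn inside the Hounsfield-unit ranges later used
for post-processing (SM [29,150], SAT [-150,-50], VAT [-190,-30]).
"""

import numpy as np

from ctbalance import PhantomParams, generate_cohort
from ctbalance.phantom import HU_SUPPORT, cohort_slice_counts
from ctbalance.types import CLASS_NAMES, SAT, SM, VAT

params = PhantomParams(image_size=64, slices_per_patient=40, l3_fraction=0.05)
cohort = generate_cohort(params, n_patients=10, seed=7)

n_l3, n_non = cohort_slice_counts(cohort)
print(f"{len(cohort)} patients, {n_l3} L3 slices vs {n_non} non-L3 "
      f"(minority fraction {n_l3 / (n_l3 + n_non):.1%})")

v = cohort[0]
print(f"patient {v.patient_id}: L3 slices at indices {v.l3_indices().tolist()}")
for cls in (SM, SAT, VAT):
    vals = np.concatenate([hu[m.codes == cls] for hu, m in zip(v.slices, v.masks)])
    print(f"  {CLASS_NAMES[cls]:>3} HU: observed [{vals.min()}, {vals.max()}] "
          f"inside declared {HU_SUPPORT[cls]}")
# The minority fraction and the in-range HU supports are exactly the two
# dataset properties the imbalance-correction strategy relies on.
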