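"""Constrained class weights and the weighted cross-entropy loss.

Detection weights are bounded below by 1/sqrt(class frequency); the
segmentation rule bounds each weight by the class pixel ratio. Candidate
multipliers d_c are clamped at the minima and rescaled to mean 1 so loss
magnitudes stay comparable across candidates during optimization.
"""

import numpy as np

from ctbalance import compute_class_weights, weighted_cross_entropy
from ctbalance.imbalance import class_weight_minima

# the clinical detection imbalance: 3.34% L3 vs 96.66% non-L3
f = np.array([0.9666, 0.0334])
minima = class_weight_minima(f, "detection")
print(f"detection minima (1/sqrt f): non-L3 {minima[0]:.3f}, L3 {minima[1]:.3f}")

cw = compute_class_weights(f, d_c=np.array([1.0, 8.0]), task="detection")
print(f"after clamping d_c=(1.0, 8.0) and mean-1 rescale: {np.round(cw.weights, 3)}")

probs = np.array([[0.9, 0.1], [0.6, 0.4], [0.2, 0.8]])
labels = np.array([0, 1, 1])
plain = weighted_cross_entropy(probs, labels, np.ones(2))
weighted = weighted_cross_entropy(probs, labels, cw)
print(f"unweighted CE {plain:.4f} vs cost-sensitive CE {weighted:.4f}")
# The minority (L3) rows dominate the weighted loss, countering the bias
# toward the majority class that plain CE induces on imbalanced data.
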