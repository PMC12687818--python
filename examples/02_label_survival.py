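"""Convert raw telemetry detections into binary survival labels.

Detections are binned into 30 ten-day capture occasions; a cohort-level
Cormack-Jolly-Seber model (two-state hidden Markov chain with time-varying
apparent survival phi_t and detection probability p_t) is fitted by maximum
likelihood, and each bird is labelled by its posterior probability of being
alive at the final occasion.
"""

import numpy as np

from hybridsurv import cjs
from hybridsurv.simulate import SimConfig, generate_cohort

_, traits, detections = generate_cohort(SimConfig(n_birds=600, seed=42))

groups = dict(tuple(detections.groupby("bird_id")))
histories = np.stack([
    cjs.bin_detections(groups[b]["days_since_tag"].to_numpy() if b in groups else [])
    for b in traits["bird_id"]
])
probs, labels, fit = cjs.label_cohort(histories, mode="cohort")

print(f"fitted phi_t over the first five intervals: {np.round(fit.phi[:5], 3)}")
print(f"fitted p_t over the first five occasions:  {np.round(fit.p[:5], 3)}")
print(f"labelled survivors: {labels.mean():.1%} of {len(labels)} birds")
near_binary = np.mean((probs < 0.001) | (probs > 0.999))
print(f"{near_binary:.1%} of posteriors are < 0.001 or > 0.999 — the labeling "
      "is effectively binary, as expected when detection probability is high")
truth = traits["survived_true"].to_numpy()
print(f"agreement with the planted ground truth: {np.mean(labels == truth):.1%}")
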