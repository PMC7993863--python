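"""Chance-corrected inter-annotator agreement with Cohen's kappa.

Simulates four annotators labeling 500 records — three mostly agreeing,
one guessing independently — and prints the pairwise kappa matrix and its
mean, the statistic used to report corpus annotation quality.
"""

import numpy as np

import cannarel as cr

rng = np.random.default_rng(0)
labels = np.array(cr.LABELS)
truth = rng.choice(labels, size=500, p=[0.55, 0.12, 0.03, 0.30])


def noisy(agreement: float) -> np.ndarray:
    flip = rng.random(truth.size) > agreement
    out = truth.copy()
    out[flip] = rng.choice(labels, size=flip.sum())
    return out


table = np.stack([noisy(0.9), noisy(0.9), noisy(0.85), rng.choice(labels, 500)], axis=1)
K, mean = cr.pairwise_kappa(table)

print("pairwise kappa matrix (annotators A-D):")
for row in K:
    print("  " + "  ".join(f"{v:6.3f}" for v in row))
print(f"mean over pairs: {mean:.3f}")

# Pairs of careful annotators land around 0.8 (substantial agreement); any
# pair involving the random annotator sits near 0, dragging the mean down.
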