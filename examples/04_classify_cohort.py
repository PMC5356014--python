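"""Label-free morphology classification of a small simulated cohort.

Simulates 40 records (two-daughter colonies, four-daughter colonies,
fragments), reconstructs each with pixel-SR, extracts opacity / area /
HoG-PC1 morphology, clusters with K-means (k = 3), and scores how well the
morphology metric separates the two colony classes.
"""

import numpy as np

from pixelsr import make_cohort, register, roc_auc
from pixelsr.experiments import crop_to_field
from pixelsr.phenotype import extract_features
from pixelsr.reconstruct import ReconParams, pixel_sr

records = make_cohort(40, (0.4, 0.4, 0.2), seed=5)
params = ReconParams(bg_mode="divide")
images, labels = [], []
for rec in records:
    est = register(rec)
    images.append(crop_to_field(pixel_sr(rec, params, estimate=est), rec))
    labels.append(rec.ground_truth.label)

feats = extract_features(images, threshold=0.88, labels=labels, seed=5)

print(f"{'label':9s} {'opacity':>8s} {'area um2':>9s} {'morphology':>11s} cluster")
for f in feats[:12]:
    print(f"{f.label:9s} {f.opacity:8.3f} {f.area:9.1f} {f.morphology:11.3f} "
          f"{f.cluster:4d}")

scores = np.array([f.morphology for f in feats
                   if f.label in ("2lobe", "4lobe") and np.isfinite(f.morphology)])
is4 = np.array([f.label == "4lobe" for f in feats
                if f.label in ("2lobe", "4lobe") and np.isfinite(f.morphology)])
print(f"\n2- vs 4-daughter AUC from pixel-SR images: {roc_auc(scores, is4):.3f}")
# Four-daughter colonies carry more internal wall structure, so their
# HoG-PC1 morphology scores sit higher; opacity alone cannot separate the
# two classes, which is the point of the morphology metric.
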