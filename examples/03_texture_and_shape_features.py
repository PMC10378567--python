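"""Handcrafted features of one ROI: HOG + LBP texture and the 4 shape values.

The texture vector is 8356-dimensional (15x15 HOG blocks x 36 values + 256
LBP histogram bins); across a set of ROIs it is reduced by PCA to 199
components before entering the classifier.
"""

import numpy as np

from fusioncad import (
    LesionSpec,
    make_lesion_image,
    pca_fit,
    pca_transform,
    shape_features,
    texture_vector,
    trace_contours,
)

vectors, labels = [], []
for label, spikes in (("benign", 0), ("malignant", 8)):
    for seed in range(12):
        spec = LesionSpec(
            modality="MG", class_label=label, spiculation_count=spikes,
            spiculation_depth=0.3, noise_level=10.0, seed=seed,
        )
        img, mask = make_lesion_image(spec)
        vectors.append(texture_vector(img))
        labels.append(label)
        if seed == 0:
            sf = shape_features(mask, trace_contours(mask)[0])
            print(
                f"{label:9s} Area={sf.area:6.0f} Perimeter={sf.perimeter:7.1f} "
                f"Eccentricity={sf.eccentricity:10.1f} Circularity={sf.circularity:.3f}"
            )

x = np.vstack(vectors)
print(f"\nraw texture matrix: {x.shape[0]} ROIs x {x.shape[1]} features")
model = pca_fit(x, n_components=10)  # capped automatically on tiny sets
z = pca_transform(model, x)
var = model.explained_variance / model.explained_variance.sum()
print(f"PCA-reduced matrix: {z.shape[0]} x {z.shape[1]}")
print(f"variance captured by the first 3 components: {var[:3].sum():.1%}")
print(
    "\nThe leading components summarise most texture variance; shape features"
    "\n(especially circularity) separate the two classes directly."
)
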