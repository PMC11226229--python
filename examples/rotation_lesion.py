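"""Destroy factorization — and only factorization — with the rotation lesion.

Builds a class-structured population whose class centers live orthogonally
to the within-class noise, rotates the inter-class principal axes onto the
intra-class ones, and shows that invariance survives while factorization
and decoding collapse.  A label-shuffle null puts the observed
factorization in context.
"""

import numpy as np

import popfactor as pf

spectrum = tuple(np.linspace(1.0, 0.3, 10))
responses, design, _ = pf.gen_class_dataset(
    n_classes=8, n_per_class=20, n_units=30,
    center_spread=1.0, within_cov_spec=spectrum, noise_seed=11,
)
labels = list(design.class_labels.loc[responses.condition_ids])
lesioned = pf.rotation_lesion(responses, labels)

for name, rm in (("original", responses), ("lesioned", lesioned)):
    fact = pf.factorization_pca(rm, design, "class")
    inv = pf.invariance(rm, design, "non_class")
    acc = pf.cv_decode(rm, labels, folds=4, regularization_grid=[1.0]).accuracy
    print(f"{name:<9} factorization={fact:.3f}  invariance(non-class)={inv:.3f}  decode={acc:.3f}")

null = pf.shuffle_null(
    responses, design, "class", "factorization_cov", n_permutations=99, seed=0
)
print(
    f"shuffle null: observed={null.observed:.3f} vs null max="
    f"{null.null_samples.max():.3f} (percentile {null.percentile:.0f})"
)
print()
print("The lesion conserves within-class spread (invariance unchanged) but")
print("rotates class centers into the noise subspace: factorization falls to")
print("~0 and cross-validated 8-way decoding drops with it. The observed")
print("factorization also far exceeds every label-shuffled null sample.")
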