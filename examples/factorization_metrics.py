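"""Measure factorization and invariance on a simulated augmentation set.

Simulates a population responding to 100 base scenes, each varied along
four scene parameters at 10 levels (4000 conditions), with the object-pose
subspace deliberately tilted toward the others, then computes the full
per-parameter score report.
"""

import popfactor as pf

config = pf.AugmentationSimConfig(
    n_units=50,
    params=(
        pf.ParamSpec("background", subspace_dim=2, variance=1.0, alignment=0.0),
        pf.ParamSpec("lighting", subspace_dim=2, variance=1.0, alignment=0.0),
        pf.ParamSpec("object_pose", subspace_dim=2, variance=1.0, alignment=0.6),
        pf.ParamSpec("camera_viewpoint", subspace_dim=2, variance=1.0, alignment=0.6),
    ),
    base_scene_variance=1.0,
    noise_sd=0.05,
    seed=0,
)
dataset = pf.gen_augmentation_responses(config)
scores = pf.geometry_scores(dataset.responses, dataset.design)

print(f"conditions: {dataset.responses.n_conditions}, units: {dataset.responses.n_features}")
print(f"{'parameter':<18} {'fact_pca':>9} {'fact_cov':>9} {'invariance':>11}")
for param in pf.PARAM_VOCABULARY:
    print(
        f"{param:<18} {scores.factorization_pca[param]:>9.3f} "
        f"{scores.factorization_cov[param]:>9.3f} {scores.invariance[param]:>11.3f}"
    )
print(f"participation ratio: {scores.participation_ratio:.1f}  (pc count at 90%: {scores.pc_count})")
print()
print("Covariance-based factorization is ~1 for the two orthogonally encoded")
print("parameters and drops for the two whose subspaces share an axis")
print("(pairwise overlap 0.6^2, diluted by pooling over the two orthogonal")
print("parameters' covariances).")
print("Invariance is similar for all four: the tilt changes *where* the")
print("variance lives, not how much of it there is. The PCA-based variant is")
print("low across the board here because this generator's scene-identity")
print("variance is isotropic, so its 90% subspace overlaps every direction;")
print("see gen_two_param_oracle for a construction where both variants agree")
print("with the closed form.")
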