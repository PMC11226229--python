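"""Synthetic populations with known geometric ground truth.

Every generator plants a controlled geometry — subspace dimensions,
variances, and the cosine of the first principal angle between subspaces
("alignment") — so the metric, lesion and decoding modules can be validated
by parameter recovery.  Alignment is always a single cosine applied to the
first principal angle between two subspaces; the remaining principal angles
are 90 degrees.  Noise is isotropic Gaussian in feature space.

Generators cover the four input families the analyses need:

* a binary-feature code (two target features at a configurable alignment
  among otherwise-orthogonal axes) for few-shot decoding simulations;
* augmentation-structured responses (base scenes x varied scene parameters
  x levels) emulating a controlled image-augmentation design at the
  feature level;
* class-structured populations for the rotation-lesion analyses;
* movie-like frame trajectories where consecutive frame pairs carry
  "local" variance at a configurable angle to the "global" trajectory;
* fabricated model-zoo tables with planted metric-to-predictivity
  relationships for the meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PARAM_VOCABULARY, AugmentationDesign, ResponseMatrix
from .errors import DesignError, VocabularyError


def _check_unit_interval(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# binary-feature simulation (few-shot decoding geometry)


@dataclass
class BinaryFactorSimConfig:
    """Ten binary features as axis coefficients; two serve as decoder targets.

    ``alignment`` is the inner product between the two target axes: 0 is a
    fully factorized (orthogonal) code, 1 collapses both targets onto one
    axis.  ``k_train`` is the number of training examples per sign of each
    target variable.
    """

    n_dims: int = 10
    alignment: float = 0.0
    noise_sd: float = 0.5
    k_train: int = 2
    n_test: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dims < 2:
            raise ValueError("need at least 2 dimensions")
        _check_unit_interval(self.alignment, "alignment")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.k_train < 1 or self.n_test < 1:
            raise ValueError("k_train and n_test must be >= 1")


@dataclass
class BinaryFactorData:
    """Balanced train sets (one per target variable) plus a shared test set."""

    train_x: dict[int, np.ndarray]  # target index -> (2K, n_dims)
    train_y: dict[int, np.ndarray]  # target index -> (2K,) in {-1, +1}
    test_x: np.ndarray  # (n_test, n_dims)
    test_y: np.ndarray  # (n_test, 2): both target labels
    target_axes: np.ndarray  # (2, n_dims)
    config: BinaryFactorSimConfig


def _binary_axes(n_dims: int, alignment: float) -> np.ndarray:
    """Feature axes: rows 0 and 1 are the targets at the given alignment."""
    axes = np.zeros((n_dims, n_dims))
    axes[0, 0] = 1.0
    axes[1, 0] = alignment
    axes[1, 1] = np.sqrt(1.0 - alignment**2)
    for i in range(2, n_dims):
        axes[i, i] = 1.0
    return axes


def _embed_binary(
    features: np.ndarray, axes: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    points = features @ axes
    if noise_sd > 0:
        points = points + rng.normal(0.0, noise_sd, size=points.shape)
    return points


def gen_binary_factor_data(config: BinaryFactorSimConfig) -> BinaryFactorData:
    """Sample the binary-feature code with balanced few-shot training sets.

    For each of the two target variables, exactly ``k_train`` positive and
    ``k_train`` negative examples are drawn (the other nine features
    random); the test set samples all features uniformly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_dims
    axes = _binary_axes(n, config.alignment)

    train_x: dict[int, np.ndarray] = {}
    train_y: dict[int, np.ndarray] = {}
    for target in (0, 1):
        feats = rng.choice([-1.0, 1.0], size=(2 * config.k_train, n))
        signs = np.repeat([1.0, -1.0], config.k_train)
        feats[:, target] = signs
        order = rng.permutation(2 * config.k_train)
        feats = feats[order]
        train_x[target] = _embed_binary(feats, axes, config.noise_sd, rng)
        train_y[target] = feats[:, target].copy()

    test_feats = rng.choice([-1.0, 1.0], size=(config.n_test, n))
    test_x = _embed_binary(test_feats, axes, config.noise_sd, rng)
    return BinaryFactorData(
        train_x=train_x,
        train_y=train_y,
        test_x=test_x,
        test_y=test_feats[:, :2].copy(),
        target_axes=axes[:2],
        config=config,
    )


# ---------------------------------------------------------------------------
# augmentation-structured responses


@dataclass
class ParamSpec:
    """One varied scene parameter: its subspace size, variance and alignment.

    ``alignment`` is the cosine of the first principal angle between this
    parameter's subspace and every other parameter's subspace (exact when
    all parameters share one alignment value; with heterogeneous values the
    pairwise cosine is the geometric mean of the two).
    """

    name: str
    subspace_dim: int = 1
    variance: float = 1.0
    alignment: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in PARAM_VOCABULARY:
            raise VocabularyError(f"unknown scene parameter {self.name!r}")
        if self.subspace_dim < 1:
            raise ValueError("subspace_dim must be >= 1")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        _check_unit_interval(self.alignment, "alignment")


@dataclass
class AugmentationSimConfig:
    """Feature-level emulation of a controlled augmentation image set.

    Defaults reproduce the reference design: 100 base scenes, 10 levels for
    each of four varied scene parameters (4000 conditions total).
    """

    n_units: int = 50
    n_base_scenes: int = 100
    n_levels: int = 10
    params: tuple[ParamSpec, ...] = (
        ParamSpec("background"),
        ParamSpec("lighting"),
        ParamSpec("object_pose"),
        ParamSpec("camera_viewpoint"),
    )
    base_scene_variance: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        needed = sum(p.subspace_dim for p in self.params)
        if any(p.alignment > 0 for p in self.params):
            needed += 1  # shared axis carrying the alignment
        if needed > self.n_units:
            raise DesignError(
                f"parameter subspaces need {needed} dimensions but only "
                f"{self.n_units} units are available"
            )


@dataclass
class GroundTruth:
    """Generating bases and variances retained for parameter recovery."""

    bases: dict[str, np.ndarray]  # param -> (n_units, d_p), orthonormal columns
    variances: dict[str, float]
    base_scene_variance: float
    noise_sd: float
    latents: dict[str, np.ndarray] = field(default_factory=dict)

    def covariance(self, param: str) -> np.ndarray:
        b = self.bases[param]
        return self.variances[param] / b.shape[1] * (b @ b.T)

    def factorization_cov(self, param: str) -> float:
        """Covariance-based factorization implied by the generating model."""
        own = self.covariance(param)
        others = [self.covariance(q) for q in self.bases if q != param]
        other = np.mean(others, axis=0)
        denom = np.linalg.norm(own) * np.linalg.norm(other)
        return 1.0 - float(np.sum(own * other)) / denom


@dataclass
class LabeledDataset:
    responses: ResponseMatrix
    design: AugmentationDesign
    ground_truth: GroundTruth


def _aligned_bases(config: AugmentationSimConfig) -> dict[str, np.ndarray]:
    """Orthonormal per-parameter bases with the configured alignments.

    Each parameter receives a private orthonormal block; a parameter with
    alignment a tilts its leading basis vector toward one shared axis by
    sqrt(a), so two parameters with the same a meet at first-principal-angle
    cosine a while all remaining angles stay at 90 degrees.
    """
    n = config.n_units
    any_aligned = any(p.alignment > 0 for p in config.params)
    next_axis = 0
    shared = np.zeros(n)
    if any_aligned:
        shared[0] = 1.0
        next_axis = 1
    bases: dict[str, np.ndarray] = {}
    for spec in config.params:
        block = np.zeros((n, spec.subspace_dim))
        for j in range(spec.subspace_dim):
            block[next_axis, j] = 1.0
            next_axis += 1
        if spec.alignment > 0:
            lead = np.sqrt(spec.alignment) * shared + np.sqrt(
                1.0 - spec.alignment
            ) * block[:, 0]
            block[:, 0] = lead
        bases[spec.name] = block
    return bases


def gen_augmentation_responses(config: AugmentationSimConfig) -> LabeledDataset:
    """Simulate responses to an augmentation-structured stimulus set.

    Each base scene gets an isotropic scene latent; each (parameter, level)
    condition adds a latent offset drawn in that parameter's subspace,
    scaled so the expected within-scene variance equals the configured
    per-parameter variance; isotropic Gaussian noise tops it off.
    """
    rng = np.random.default_rng(config.seed)
    bases = _aligned_bases(config)
    n = config.n_units
    scene_sd = np.sqrt(config.base_scene_variance / n)
    scene_centers = rng.normal(0.0, scene_sd, size=(config.n_base_scenes, n))

    rows = []
    ids = []
    meta = []
    latents: dict[str, np.ndarray] = {}
    for spec in config.params:
        b = bases[spec.name]
        coef_sd = np.sqrt(spec.variance / spec.subspace_dim)
        coefs = rng.normal(
            0.0,
            coef_sd,
            size=(config.n_base_scenes, config.n_levels, spec.subspace_dim),
        )
        latents[spec.name] = coefs
        offsets = coefs @ b.T
        for s in range(config.n_base_scenes):
            for lvl in range(config.n_levels):
                cid = f"s{s:03d}_{spec.name}_{lvl:02d}"
                rows.append(scene_centers[s] + offsets[s, lvl])
                ids.append(cid)
                meta.append((cid, f"scene{s:03d}", spec.name, lvl, None))
    values = np.stack(rows)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)

    design = AugmentationDesign(
        pd.DataFrame(
            meta,
            columns=[
                "condition_id",
                "base_scene_id",
                "varied_param",
                "level",
                "class_label",
            ],
        )
    )
    truth = GroundTruth(
        bases=bases,
        variances={p.name: p.variance for p in config.params},
        base_scene_variance=config.base_scene_variance,
        noise_sd=config.noise_sd,
        latents=latents,
    )
    return LabeledDataset(ResponseMatrix(values, ids), design, truth)


def gen_two_param_oracle(
    theta_deg: float,
    n_units: int = 10,
    n_scenes: int = 50,
    seed: int = 0,
) -> LabeledDataset:
    """Noiseless two-parameter construction with a closed-form answer.

    Base-scene centers spread along a unit axis v; parameter
    ``"background"`` induces deviations of ±1 along v, parameter
    ``"object_pose"`` deviations of ±1 along an axis u at angle
    ``theta_deg`` to v.  For ``"object_pose"``, both factorization variants
    then equal exactly ``1 − cos²(theta)``: the other-parameter subspace is
    span(v), and the two induced covariances are the rank-1 outer products
    u uᵀ and v vᵀ whose normalized Frobenius overlap is cos²(theta).
    """
    if n_units < 2 or n_scenes < 2:
        raise ValueError("need n_units >= 2 and n_scenes >= 2")
    cos_t = np.cos(np.deg2rad(theta_deg))
    sin_t = np.sin(np.deg2rad(theta_deg))
    v = np.zeros(n_units)
    v[0] = 1.0
    u = np.zeros(n_units)
    u[0], u[1] = cos_t, sin_t
    rng = np.random.default_rng(seed)
    gammas = rng.normal(0.0, 1.0, size=n_scenes)

    rows, ids, meta = [], [], []
    for s in range(n_scenes):
        center = gammas[s] * v
        for param, axis in (("object_pose", u), ("background", v)):
            for lvl, sign in enumerate((-1.0, 1.0)):
                cid = f"s{s:03d}_{param}_{lvl}"
                rows.append(center + sign * axis)
                ids.append(cid)
                meta.append((cid, f"scene{s:03d}", param, lvl, None))
    design = AugmentationDesign(
        pd.DataFrame(
            meta,
            columns=[
                "condition_id",
                "base_scene_id",
                "varied_param",
                "level",
                "class_label",
            ],
        )
    )
    truth = GroundTruth(
        bases={"object_pose": u[:, None], "background": v[:, None]},
        variances={"object_pose": 1.0, "background": 1.0},
        base_scene_variance=1.0,
        noise_sd=0.0,
    )
    return LabeledDataset(ResponseMatrix(np.stack(rows), ids), design, truth)


# ---------------------------------------------------------------------------
# class-structured populations (for the rotation lesion)


def gen_class_dataset(
    n_classes: int,
    n_per_class: int,
    n_units: int,
    center_spread: float = 1.0,
    within_cov_spec: tuple[float, ...] = (1.0,),
    center_alignment: float = 0.0,
    noise_seed: int = 0,
) -> tuple[ResponseMatrix, AugmentationDesign, dict]:
    """Class-labeled responses with controlled center/within-class geometry.

    Class centers live in a subspace whose first principal angle to the
    within-class principal subspace has cosine ``center_alignment``;
    within-class residuals share a common covariance with eigenvalues
    ``within_cov_spec``.  ``center_spread`` is the per-dimension standard
    deviation of the centers.  Returns responses, a grouped-mode design and
    a ground-truth dict (centers, center axes, within axes).
    """
    if n_classes < 2 or n_units < 2:
        raise ValueError("need >= 2 classes and >= 2 units")
    if n_per_class < 2:
        raise ValueError("need >= 2 conditions per class (within-class variance)")
    _check_unit_interval(center_alignment, "center_alignment")
    m = len(within_cov_spec)
    d_c = min(n_classes - 1, n_units - m)
    if d_c < 1:
        raise DesignError("not enough units for a center subspace beside the noise")

    rng = np.random.default_rng(noise_seed)
    within_axes = np.eye(n_units)[:, :m]  # columns w_1..w_m, w_1 = leading
    center_axes = np.zeros((n_units, d_c))
    for j in range(d_c):
        center_axes[m + j, j] = 1.0
    if center_alignment > 0:
        center_axes[:, 0] = (
            center_alignment * within_axes[:, 0]
            + np.sqrt(1.0 - center_alignment**2) * center_axes[:, 0]
        )

    center_coefs = rng.normal(0.0, center_spread, size=(n_classes, d_c))
    centers = center_coefs @ center_axes.T
    spectrum = np.sqrt(np.asarray(within_cov_spec, dtype=float))

    rows, ids, labels = [], [], []
    for c in range(n_classes):
        g = rng.normal(0.0, 1.0, size=(n_per_class, m)) * spectrum
        pts = centers[c] + g @ within_axes.T
        for i in range(n_per_class):
            rows.append(pts[i])
            ids.append(f"c{c:02d}_{i:03d}")
            labels.append(f"class{c:02d}")
    responses = ResponseMatrix(np.stack(rows), ids)
    design = AugmentationDesign(
        pd.DataFrame(
            {
                "condition_id": ids,
                "base_scene_id": None,
                "varied_param": None,
                "level": None,
                "class_label": labels,
            }
        )
    )
    truth = {
        "centers": centers,
        "center_axes": center_axes,
        "within_axes": within_axes,
        "within_cov_spec": tuple(within_cov_spec),
    }
    return responses, design, truth


# ---------------------------------------------------------------------------
# movie-like latent trajectories


def gen_movie_responses(
    n_frames: int,
    n_units: int = 30,
    local_dim: int = 1,
    global_dim: int = 5,
    local_var: float = 1.0,
    global_var: float = 1.0,
    local_alignment: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ResponseMatrix:
    """Time-ordered frames in consecutive pairs.

    Pair means wander in a "global" subspace; within-pair differences live
    in a "local" subspace whose first principal angle to the global one has
    cosine ``local_alignment``.  Expected within-pair variance is
    ``local_var`` and the pair means have total variance ``global_var``.
    """
    if n_frames % 2 or n_frames < 4:
        raise DesignError("n_frames must be even and >= 4")
    if local_dim + global_dim + (1 if local_alignment > 0 else 0) > n_units:
        raise DesignError("local and global subspaces do not fit in n_units")
    _check_unit_interval(local_alignment, "local_alignment")
    rng = np.random.default_rng(seed)

    global_axes = np.eye(n_units)[:, :global_dim]
    local_axes = np.zeros((n_units, local_dim))
    for j in range(local_dim):
        local_axes[global_dim + j, j] = 1.0
    if local_alignment > 0:
        local_axes[:, 0] = (
            local_alignment * global_axes[:, 0]
            + np.sqrt(1.0 - local_alignment**2) * local_axes[:, 0]
        )

    n_pairs = n_frames // 2
    means = rng.normal(
        0.0, np.sqrt(global_var / global_dim), size=(n_pairs, global_dim)
    ) @ global_axes.T
    deltas = rng.normal(
        0.0, np.sqrt(local_var / local_dim), size=(n_pairs, local_dim)
    ) @ local_axes.T
    frames = np.empty((n_frames, n_units))
    frames[0::2] = means - deltas
    frames[1::2] = means + deltas
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    ids = [f"frame{t:05d}" for t in range(n_frames)]
    return ResponseMatrix(frames, ids)


# ---------------------------------------------------------------------------
# fabricated model zoos (for the meta-analysis)


def gen_model_table(
    n_models: int = 200,
    n_layers: int = 5,
    effect_classification: float = 1.0,
    effect_factorization: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Model-zoo table with a planted metric-to-predictivity relationship.

    Per model layer: independent uniform ``classification`` and
    ``factorization`` metrics plus a nuisance ``dimensionality`` column;
    ``predictivity`` is their weighted sum plus Gaussian noise.  Tidy
    layout: one row per (model_id, layer_id).
    """
    rng = np.random.default_rng(seed)
    records = []
    for mi in range(n_models):
        cls_base = rng.uniform(0.0, 1.0)
        fac_base = rng.uniform(0.0, 1.0)
        for li in range(n_layers):
            cls = cls_base + rng.normal(0.0, 0.05)
            fac = fac_base + rng.normal(0.0, 0.05)
            pred = (
                effect_classification * cls
                + effect_factorization * fac
                + rng.normal(0.0, noise_sd)
            )
            records.append(
                {
                    "model_id": f"model{mi:03d}",
                    "layer_id": f"layer{li}",
                    "layer_order": li,
                    "classification": cls,
                    "factorization": fac,
                    "dimensionality": rng.uniform(1.0, 50.0),
                    "predictivity": pred,
                }
            )
    return pd.DataFrame.from_records(records)
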