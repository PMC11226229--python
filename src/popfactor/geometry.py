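"""Factorization, invariance and dimensionality of population codes.

A scene parameter (background, lighting, object pose, camera viewpoint —
or, in grouped mode, "class" vs "non-class") induces variance in a
population response.  Three questions are asked of that variance:

* how large is it relative to everything else (**invariance**: 1 minus the
  ratio of parameter-induced variance to total variance; high invariance
  means the parameter barely moves the population);
* how much of it avoids the subspace occupied by variance from the *other*
  parameters (**PCA-based factorization**: 1 minus the fraction of
  parameter-induced variance surviving projection onto the other-parameter
  principal subspace);
* how different its covariance structure is from the other parameters'
  (**covariance-based factorization**: 1 minus the cosine between the two
  flattened covariance matrices).

Both factorization variants live in [0, 1]: the PCA variant because a
projection can never increase variance, the covariance variant because of
Cauchy–Schwarz applied to positive-semidefinite matrices.  All metrics are
invariant to orthogonal transformations of the feature space.

Variance is always summed across features (the trace of the feature-space
covariance) and uses the n denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AnalysisConfig, AugmentationDesign, ResponseMatrix
from .errors import DegenerateSubspaceError, DesignError, UndefinedScoreError

#: Pseudo-parameter names available in grouped mode.
GROUPED_PARAMS = ("class", "non_class")

_RANK_TOL = 1e-12


@dataclass
class Subspace:
    """An affine principal subspace of feature space."""

    basis: np.ndarray  # features x k, orthonormal columns
    variance_threshold: float
    center: np.ndarray  # feature-space mean the PCA was centered on

    def __post_init__(self) -> None:
        k = self.basis.shape[1]
        if k < 1:
            raise DegenerateSubspaceError("subspace must have rank >= 1")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValueError("subspace basis is not orthonormal")

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    def project(self, points: np.ndarray) -> np.ndarray:
        """Coordinates of points in the subspace (after centering)."""
        return (np.asarray(points, dtype=float) - self.center) @ self.basis


@dataclass
class VarianceComponents:
    var_param: float
    var_all: float
    var_param_in_other_subspace: float


@dataclass
class CovariancePair:
    cov_param: np.ndarray
    cov_other_param: np.ndarray

    def __post_init__(self) -> None:
        for name in ("cov_param", "cov_other_param"):
            mat = getattr(self, name)
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")


@dataclass
class GeometryScores:
    """Per-parameter factorization and invariance plus global dimensionality."""

    factorization_pca: dict[str, float]
    factorization_cov: dict[str, float]
    invariance: dict[str, float]
    pc_count: int
    participation_ratio: float


# ---------------------------------------------------------------------------
# array-level primitives (shared with the movie variant and the lesion nulls)


def total_variance(points: np.ndarray) -> float:
    """Variance summed over features, n denominator, about the point mean."""
    points = np.asarray(points, dtype=float)
    dev = points - points.mean(axis=0)
    return float(np.mean(np.sum(dev**2, axis=1)))


def _covariance(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    dev = points - points.mean(axis=0)
    return dev.T @ dev / points.shape[0]


def pca_subspace(points: np.ndarray, threshold: float) -> Subspace:
    """Smallest leading principal subspace reaching the variance threshold.

    Points are mean-centered first; components with numerically zero
    variance never enter the basis.  Ties at the threshold resolve to the
    smaller component count.
    """
    points = np.asarray(points, dtype=float)
    center = points.mean(axis=0)
    dev = points - center
    u, s, vt = np.linalg.svd(dev, full_matrices=False)
    lam = s**2 / points.shape[0]
    total = lam.sum()
    if total <= _RANK_TOL:
        raise DegenerateSubspaceError("all points identical: rank-0 subspace")
    keep = lam > _RANK_TOL * lam[0]
    lam = lam[keep]
    axes = vt[keep]
    cum = np.cumsum(lam) / total
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, len(lam))
    return Subspace(basis=axes[:k].T, variance_threshold=threshold, center=center)


def _group_rows(
    responses: ResponseMatrix, ids: pd.Series, keys: pd.Series
) -> dict[object, np.ndarray]:
    """Rows of the response matrix grouped by a key series over condition ids."""
    idx = responses.row_index()
    out: dict[object, np.ndarray] = {}
    for key, sub in ids.groupby(keys):
        out[key] = responses.values[[idx[c] for c in sub]]
    return out


def _param_groups(
    responses: ResponseMatrix, design: AugmentationDesign, param: str
) -> dict[object, np.ndarray]:
    """Augmentation mode: {base_scene_id: level-responses} for one parameter."""
    sub = design.conditions_for(param)
    return _group_rows(
        responses, sub["condition_id"], sub["base_scene_id"]
    )


def _class_groups(
    responses: ResponseMatrix, design: AugmentationDesign
) -> dict[object, np.ndarray]:
    tab = design.table
    return _group_rows(responses, tab["condition_id"], tab["class_label"])


def _class_centers(responses: ResponseMatrix, design: AugmentationDesign) -> np.ndarray:
    groups = _class_groups(responses, design)
    return np.stack([g.mean(axis=0) for g in groups.values()])


def _class_residuals(
    responses: ResponseMatrix, design: AugmentationDesign
) -> np.ndarray:
    groups = _class_groups(responses, design)
    return np.concatenate([g - g.mean(axis=0) for g in groups.values()])


def _check_grouped_param(param: str) -> None:
    if param not in GROUPED_PARAMS:
        raise DesignError(
            f"grouped-mode parameter must be one of {GROUPED_PARAMS}, got {param!r}"
        )


# ---------------------------------------------------------------------------
# public metric operations


def param_variance(
    responses: ResponseMatrix, design: AugmentationDesign, param: str
) -> float:
    """Variance induced by one scene parameter.

    Augmentation mode: for each base scene, the total variance of the
    responses to that scene's levels of ``param``; averaged across base
    scenes.  Grouped mode: ``"class"`` is the variance of class centers
    about their mean, ``"non_class"`` the mean within-class total variance.
    """
    design.check_matches(responses)
    if design.mode == "augmentation":
        groups = _param_groups(responses, design, param)
        return float(np.mean([total_variance(g) for g in groups.values()]))
    _check_grouped_param(param)
    if param == "class":
        return total_variance(_class_centers(responses, design))
    groups = _class_groups(responses, design)
    return float(np.mean([total_variance(g) for g in groups.values()]))


def all_param_variance(responses: ResponseMatrix, design: AugmentationDesign) -> float:
    """Total variance across every condition in the design, about the global mean."""
    design.check_matches(responses)
    return total_variance(responses.subset(design.condition_ids).values)


def other_param_subspace(
    responses: ResponseMatrix,
    design: AugmentationDesign,
    param: str,
    threshold: float = 0.9,
) -> Subspace:
    """Principal subspace of the variance driven by everything except ``param``.

    Augmentation mode: average each base scene's responses over the levels
    of ``param`` (one vector per base scene) and run PCA on those averages —
    the averaging washes out the parameter of interest, so the leading
    components capture other sources of variance.  Grouped mode: the
    other-structure for ``"class"`` is the pooled within-class residuals,
    and for ``"non_class"`` the class centers.
    """
    design.check_matches(responses)
    if design.mode == "augmentation":
        groups = _param_groups(responses, design, param)
        if len(groups) < 2:
            raise DesignError("need >= 2 base scenes for the other-parameter subspace")
        averages = np.stack([g.mean(axis=0) for g in groups.values()])
        return pca_subspace(averages, threshold)
    _check_grouped_param(param)
    if param == "class":
        return pca_subspace(_class_residuals(responses, design), threshold)
    return pca_subspace(_class_centers(responses, design), threshold)


def _projected_responses(
    responses: ResponseMatrix, subspace: Subspace
) -> ResponseMatrix:
    coords = subspace.project(responses.values)
    return ResponseMatrix(coords, list(responses.condition_ids))


def factorization_pca(
    responses: ResponseMatrix,
    design: AugmentationDesign,
    param: str,
    threshold: float = 0.9,
) -> float:
    """Fraction of parameter-induced variance avoiding the other-parameter subspace."""
    v_param = param_variance(responses, design, param)
    if v_param <= 0.0:
        raise UndefinedScoreError(
            f"parameter {param!r} induces zero variance: factorization undefined"
        )
    sub = other_param_subspace(responses, design, param, threshold)
    v_inside = param_variance(_projected_responses(responses, sub), design, param)
    return 1.0 - v_inside / v_param


def _covariance_overlap(cov_a: np.ndarray, cov_b: np.ndarray) -> float:
    na = np.linalg.norm(cov_a)
    nb = np.linalg.norm(cov_b)
    if na <= 0.0 or nb <= 0.0:
        raise UndefinedScoreError("zero covariance: factorization undefined")
    return float(np.sum(cov_a * cov_b) / (na * nb))


def _param_covariances(
    responses: ResponseMatrix, design: AugmentationDesign, param: str
) -> CovariancePair:
    if design.mode == "augmentation":
        others = [p for p in design.params if p != param]
        if not others:
            raise DesignError("covariance factorization needs >= 2 parameters")
        own = [
            _covariance(g) for g in _param_groups(responses, design, param).values()
        ]
        other = [
            _covariance(g)
            for q in others
            for g in _param_groups(responses, design, q).values()
        ]
        return CovariancePair(
            cov_param=np.mean(own, axis=0), cov_other_param=np.mean(other, axis=0)
        )
    _check_grouped_param(param)
    centers_cov = _covariance(_class_centers(responses, design))
    within = [
        _covariance(g) for g in _class_groups(responses, design).values()
    ]
    within_cov = np.mean(within, axis=0)
    if param == "class":
        return CovariancePair(cov_param=centers_cov, cov_other_param=within_cov)
    return CovariancePair(cov_param=within_cov, cov_other_param=centers_cov)


def factorization_cov(
    responses: ResponseMatrix, design: AugmentationDesign, param: str
) -> float:
    """One minus the cosine between parameter and other-parameter covariances.

    The two covariances are each averaged over base scenes (augmentation
    mode) or taken as between-center vs pooled within-class covariance
    (grouped mode); the score is 1 minus their normalized Frobenius inner
    product.  Parameter-free, unlike the PCA variant.
    """
    design.check_matches(responses)
    pair = _param_covariances(responses, design, param)
    return 1.0 - _covariance_overlap(pair.cov_param, pair.cov_other_param)


def invariance(
    responses: ResponseMatrix, design: AugmentationDesign, param: str
) -> float:
    """1 minus the ratio of parameter-induced variance to total variance."""
    v_all = all_param_variance(responses, design)
    if v_all <= 0.0:
        raise UndefinedScoreError("zero total variance: invariance undefined")
    return 1.0 - param_variance(responses, design, param) / v_all


def target_param_subspace(
    responses: ResponseMatrix,
    design: AugmentationDesign,
    target_param: str,
    threshold: float = 0.9,
) -> Subspace:
    """Principal subspace of the variance *driven by* ``target_param``.

    Grouped mode, ``"class"``: PCA on class centers (the identity
    subspace); ``"non_class"``: PCA on within-class residuals.
    Augmentation mode: PCA on the per-scene-centered deviations of the
    target parameter's level responses, pooled over base scenes.
    """
    design.check_matches(responses)
    if design.mode == "grouped":
        _check_grouped_param(target_param)
        if target_param == "class":
            return pca_subspace(_class_centers(responses, design), threshold)
        return pca_subspace(_class_residuals(responses, design), threshold)
    groups = _param_groups(responses, design, target_param)
    deviations = np.concatenate([g - g.mean(axis=0) for g in groups.values()])
    return pca_subspace(deviations, threshold)


def invariance_within_subspace(
    responses: ResponseMatrix,
    design: AugmentationDesign,
    param: str,
    target_param: str,
    threshold: float = 0.9,
) -> float:
    """Invariance to ``param`` measured inside the ``target_param`` subspace.

    High values mean the target parameter's subspace (e.g. the identity
    subspace capturing 90% of class-driven variance) is itself tolerant to
    the nuisance parameter — the quantity a downstream decoder cares about.
    """
    sub = target_param_subspace(responses, design, target_param, threshold)
    return invariance(_projected_responses(responses, sub), design, param)


def dimensionality(
    responses: ResponseMatrix, method: str = "participation_ratio", threshold: float = 0.9
) -> float:
    """Effective dimensionality of the response set.

    ``pc_count``: smallest number of principal components whose cumulative
    explained variance reaches the threshold.  ``participation_ratio``:
    (sum of eigenvalues)^2 / sum of squared eigenvalues of the covariance —
    its threshold-free analogue.
    """
    dev = responses.values - responses.values.mean(axis=0)
    s = np.linalg.svd(dev, compute_uv=False)
    lam = s**2 / responses.n_conditions
    total = lam.sum()
    if total <= 0.0:
        raise UndefinedScoreError("zero total variance: dimensionality undefined")
    if method == "pc_count":
        cum = np.cumsum(lam) / total
        return float(np.searchsorted(cum, threshold - 1e-12) + 1)
    if method == "participation_ratio":
        return float(total**2 / np.sum(lam**2))
    raise ValueError(f"unknown dimensionality method {method!r}")


def geometry_scores(
    responses: ResponseMatrix,
    design: AugmentationDesign,
    config: AnalysisConfig | None = None,
) -> GeometryScores:
    """All per-parameter scores plus dimensionality, in one report."""
    config = config or AnalysisConfig()
    params = design.params if design.mode == "augmentation" else list(GROUPED_PARAMS)
    thr = config.pca_variance_threshold
    return GeometryScores(
        factorization_pca={
            p: factorization_pca(responses, design, p, thr) for p in params
        },
        factorization_cov={p: factorization_cov(responses, design, p) for p in params},
        invariance={p: invariance(responses, design, p) for p in params},
        pc_count=int(dimensionality(responses, "pc_count", thr)),
        participation_ratio=dimensionality(responses, "participation_ratio"),
    )


# ---------------------------------------------------------------------------
# natural-movie variant


def movie_factorization(
    frames: ResponseMatrix, variant: str = "pca", threshold: float = 0.9
) -> tuple[float, float]:
    """Factorization and invariance of frame-to-frame (local) variance.

    Consecutive frame pairs act as 2-level augmentations of a pseudo base
    scene (the pair mean): within-pair differences are the locally induced
    variance (object/observer motion at the frame separation), while
    variance of the pair means across the movie stands in for all other
    sources.  Returns ``(factorization, invariance)``.

    If the local variance is zero, factorization is undefined and an
    :class:`UndefinedScoreError` is raised carrying ``invariance = 1.0`` as
    an attribute.
    """
    x = frames.values
    n = x.shape[0]
    if n < 4 or n % 2:
        raise DesignError("movie needs an even number of frames >= 4")
    pairs = x.reshape(n // 2, 2, x.shape[1])
    means = pairs.mean(axis=1)
    half_dev = pairs - means[:, None, :]  # +/- d/2
    local_var = float(np.mean(np.sum(half_dev**2, axis=2).sum(axis=1) / 2))
    var_all = total_variance(x)
    if var_all <= 0.0:
        raise UndefinedScoreError("constant movie: all metrics undefined")
    inv = 1.0 - local_var / var_all
    if local_var <= 0.0:
        err = UndefinedScoreError("zero local variance: movie factorization undefined")
        err.invariance = 1.0
        raise err
    if variant == "pca":
        sub = pca_subspace(means, threshold)
        proj = (half_dev.reshape(n, -1)) @ sub.basis
        local_inside = float(
            np.mean(np.sum(proj.reshape(n // 2, 2, -1) ** 2, axis=2).sum(axis=1) / 2)
        )
        fact = 1.0 - local_inside / local_var
    elif variant == "cov":
        d = half_dev[:, 1, :] * 2  # within-pair difference
        # 2-point covariance of a pair is d d^T / 4; average over pairs
        cov_local = np.einsum("pi,pj->ij", d, d) / (4 * d.shape[0])
        cov_other = _covariance(means)
        fact = 1.0 - _covariance_overlap(cov_local, cov_other)
    else:
        raise ValueError(f"unknown movie variant {variant!r}")
    return fact, inv
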