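"""Rotation lesion of representational geometry, plus permutation nulls.

The lesion is a statistical intervention on a class-labeled population:
rotate the class centers so that the inter-class principal axes land on
the intra-class principal axes, while keeping every within-class deviation
fixed.  Mean rates, within-class covariance, the inter-center variance
spectrum and pairwise center distances are all conserved; the only thing
destroyed is the *angle* between class-driven and nuisance-driven variance
— i.e. factorization — which is what makes the lesion a causal probe of
factorization's contribution to decodability.

The shuffle null answers the complementary question: how much apparent
factorization arises from dimensionality alone?  Grouping labels are
permuted and the metric recomputed to build a permutation distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import AugmentationDesign, ResponseMatrix
from .errors import DesignError, RankError
from . import geometry

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10


@dataclass
class ClassStructure:
    """Inter/intra-class principal axes and the rotation pairing them."""

    class_labels: pd.Series  # condition_id -> label
    class_centers: np.ndarray  # classes x features
    class_order: list[str]
    global_center: np.ndarray  # unweighted mean of class centers
    inter_pcs: np.ndarray  # features x M, orthonormal columns
    intra_pcs: np.ndarray  # features x M, orthonormal columns
    rotation: np.ndarray  # features x features: W_inter->intra

    @property
    def n_paired(self) -> int:
        return self.inter_pcs.shape[1]


def _principal_axes(deviations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal PCs (columns) of a centered point set, by eigenvalue.

    Sign convention: each component's largest-magnitude coefficient is
    positive, so the decomposition — and hence the rotation — is
    reproducible across platforms.
    """
    _, s, vt = np.linalg.svd(deviations, full_matrices=False)
    lam = s**2 / deviations.shape[0]
    keep = lam > _RANK_TOL * max(lam[0], 1.0)
    axes = vt[keep]
    for row in axes:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return axes.T, lam[keep]


def fit_class_structure(
    responses: ResponseMatrix, labels: Sequence[str] | pd.Series
) -> ClassStructure:
    """Class centers, inter/intra-class PCs, and the pairing rotation W.

    The inter-class PCs are all components of the centered class centers
    with nonzero eigenvalue (M of them, at most classes − 1); the
    intra-class PCs come from the center-subtracted residuals, which must
    have rank at least M so every inter component has a partner.
    W = sum_i v_i^intra (v_i^inter)^T maps the inter basis isometrically
    onto the intra basis.
    """
    labels = pd.Series(list(labels), index=responses.condition_ids)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise DesignError("need at least 2 classes")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise RankError("every class needs >= 2 conditions")

    idx = responses.row_index()
    centers = []
    residuals = np.empty_like(responses.values)
    for c in classes:
        rows = [idx[cid] for cid in labels.index[labels == c]]
        center = responses.values[rows].mean(axis=0)
        centers.append(center)
        residuals[rows] = responses.values[rows] - center
    centers = np.stack(centers)
    global_center = centers.mean(axis=0)

    inter_pcs, _ = _principal_axes(centers - global_center)
    m = inter_pcs.shape[1]
    intra_pcs, _ = _principal_axes(residuals - residuals.mean(axis=0))
    if intra_pcs.shape[1] < m:
        raise RankError(
            f"intra-class rank {intra_pcs.shape[1]} < inter-class rank {m}: "
            "cannot pair components"
        )
    intra_pcs = intra_pcs[:, :m]
    rotation = intra_pcs @ inter_pcs.T
    return ClassStructure(
        class_labels=labels,
        class_centers=centers,
        class_order=list(classes),
        global_center=global_center,
        inter_pcs=inter_pcs,
        intra_pcs=intra_pcs,
        rotation=rotation,
    )


def rotation_lesion(
    responses: ResponseMatrix, labels: Sequence[str] | pd.Series
) -> ResponseMatrix:
    """Rotate class centers into the intra-class subspace; keep residuals.

    Each response becomes ``global_center + W (x^c − global_center) +
    (x − x^c)``: the center's deviation from the grand mean of centers is
    rotated, the within-class deviation is carried over bitwise.
    """
    structure = fit_class_structure(responses, labels)
    idx = responses.row_index()
    out = np.empty_like(responses.values)
    for c, center in zip(structure.class_order, structure.class_centers):
        rows = [
            idx[cid]
            for cid in structure.class_labels.index[structure.class_labels == c]
        ]
        new_center = structure.global_center + structure.rotation @ (
            center - structure.global_center
        )
        out[rows] = new_center + (responses.values[rows] - center)
    return responses.with_values(out)


# ---------------------------------------------------------------------------
# permutation nulls


@dataclass
class NullDistribution:
    observed: float
    null_samples: np.ndarray
    percentile: float
    n_permutations: int
    seed: int


_METRICS: dict[str, Callable[..., float]] = {
    "factorization_pca": geometry.factorization_pca,
    "factorization_cov": geometry.factorization_cov,
}


def _permuted_design(
    design: AugmentationDesign, rng: np.random.Generator
) -> AugmentationDesign:
    table = design.table.copy()
    if design.mode == "grouped":
        table["class_label"] = rng.permutation(table["class_label"].to_numpy())
    else:
        # permute base-scene assignment within each varied parameter so the
        # level bookkeeping (constant level counts) stays valid
        for param in design.params:
            mask = table["varied_param"] == param
            table.loc[mask, "base_scene_id"] = rng.permutation(
                table.loc[mask, "base_scene_id"].to_numpy()
            )
    return AugmentationDesign(table)


def shuffle_null(
    responses: ResponseMatrix,
    design: AugmentationDesign,
    param: str,
    metric: str = "factorization_pca",
    n_permutations: int = 100,
    seed: int = 0,
    **metric_kwargs,
) -> NullDistribution:
    """Permutation null for a factorization metric.

    Grouping labels (class labels in grouped mode, base-scene assignments
    in augmentation mode) are permuted uniformly at random and the metric
    recomputed.  The observed value's percentile is its strictly-less-than
    rank in the null, scaled to [0, 100].
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if n_permutations < 20:
        logger.warning(
            "n_permutations=%d < 20: percentile estimate will be unstable",
            n_permutations,
        )
    fn = _METRICS[metric]
    observed = fn(responses, design, param, **metric_kwargs)
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            fn(responses, _permuted_design(design, rng), param, **metric_kwargs)
            for _ in range(n_permutations)
        ]
    )
    percentile = 100.0 * float(np.sum(null < observed)) / n_permutations
    return NullDistribution(
        observed=float(observed),
        null_samples=null,
        percentile=percentile,
        n_permutations=n_permutations,
        seed=seed,
    )
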