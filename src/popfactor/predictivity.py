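"""Scoring a feature representation against target data.

Three complementary scores:

* **encoding fit** — cross-validated ridge regression from the
  representation's leading principal components to each target unit or
  voxel; per-target held-out Pearson correlation, aggregated as the median;
* **RDM similarity** — Spearman rank correlation between the two
  representations' matrices of pairwise condition dot products;
* **behavioral signatures** — image-level difficulty (I1) and
  image-by-distractor confusion (I2) derived from a classifier's choice
  probabilities, compared to reference signatures by Pearson correlation.

PCA and penalty selection for the encoding fit are refit inside each
training fold, so no test information leaks into the mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge, RidgeCV
from sklearn.model_selection import KFold

from .data import AnalysisConfig, ResponseMatrix
from .errors import AlignmentError, FormatError, UndefinedScoreError


@dataclass
class EncodingFitResult:
    per_target_score: np.ndarray  # NaN where a target was constant
    aggregate: float  # median over defined targets
    chosen_penalty: dict[int, float]
    n_components: int


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    condition_ids: list[str]

    def __post_init__(self) -> None:
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise FormatError("similarity matrix must be symmetric")

    def upper_triangle(self) -> np.ndarray:
        i, j = np.triu_indices(self.values.shape[0], k=1)
        return self.values[i, j]


@dataclass
class BehavioralSignature:
    i1: np.ndarray  # per-image difficulty, in [0, 1]
    i2: np.ndarray  # image x distractor confusion; NaN on true-class column
    classes: list[str]


def _check_aligned(a: ResponseMatrix, b: ResponseMatrix) -> None:
    if a.condition_ids != b.condition_ids:
        raise AlignmentError("condition ids differ or are ordered differently")


def encoding_fit(
    features: ResponseMatrix,
    targets: ResponseMatrix,
    config: AnalysisConfig | None = None,
) -> EncodingFitResult:
    """Cross-validated ridge encoding fit on leading PCs of the features.

    Per outer fold: PCA (top ``encoding_n_components`` or the training
    rank, whichever is smaller) is fit on training conditions only, a ridge
    map fit with its penalty chosen by efficient leave-one-out selection on
    the training folds, and held-out conditions predicted.  Each target's
    score is the Pearson correlation between its concatenated held-out
    predictions and true values; constant targets score NaN and are
    excluded from the median aggregate.
    """
    config = config or AnalysisConfig()
    _check_aligned(features, targets)
    n = features.n_conditions
    if n <= config.cv_folds:
        raise FormatError("need more conditions than folds")
    x, y = features.values, targets.values
    splitter = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    preds = np.empty_like(y)
    chosen: dict[int, float] = {}
    n_comp_used = 0
    for fold, (tr, te) in enumerate(splitter.split(x)):
        k = min(config.encoding_n_components, len(tr) - 1, x.shape[1])
        pca = PCA(n_components=k, svd_solver="auto", random_state=0).fit(x[tr])
        z_tr, z_te = pca.transform(x[tr]), pca.transform(x[te])
        n_comp_used = max(n_comp_used, pca.n_components_)
        ridge = RidgeCV(alphas=config.ridge_penalty_grid).fit(z_tr, y[tr])
        chosen[fold] = float(ridge.alpha_)
        refit = Ridge(alpha=ridge.alpha_).fit(z_tr, y[tr])
        preds[te] = refit.predict(z_te)

    scores = np.full(y.shape[1], np.nan)
    for t in range(y.shape[1]):
        if np.std(y[:, t]) == 0 or np.std(preds[:, t]) == 0:
            continue
        scores[t] = stats.pearsonr(preds[:, t], y[:, t]).statistic
    defined = scores[~np.isnan(scores)]
    if defined.size == 0:
        raise UndefinedScoreError("all targets constant: encoding fit undefined")
    return EncodingFitResult(
        per_target_score=scores,
        aggregate=float(np.median(defined)),
        chosen_penalty=chosen,
        n_components=n_comp_used,
    )


def similarity_matrix(features: ResponseMatrix) -> SimilarityMatrix:
    """Pairwise dot products of condition representations."""
    return SimilarityMatrix(
        values=features.values @ features.values.T,
        condition_ids=list(features.condition_ids),
    )


def rdm_similarity(features_a: ResponseMatrix, features_b: ResponseMatrix) -> float:
    """Spearman correlation between the two pairwise-similarity matrices.

    Only strictly-upper-triangle entries enter the correlation; average
    ranks break ties.
    """
    _check_aligned(features_a, features_b)
    if features_a.n_conditions < 3:
        raise FormatError("need >= 3 conditions for an off-diagonal correlation")
    ua = similarity_matrix(features_a).upper_triangle()
    ub = similarity_matrix(features_b).upper_triangle()
    return float(stats.spearmanr(ua, ub).statistic)


def behavioral_signatures(
    class_probabilities: np.ndarray,
    true_labels: list[str] | np.ndarray,
    classes: list[str],
) -> BehavioralSignature:
    """I1/I2 signatures from classifier choice probabilities.

    The confusion rate for image i against distractor class d is the
    two-alternative rate ``p_d / (p_true + p_d)``; a cell with
    ``p_true + p_d = 0`` is undefined (NaN).  Image difficulty I1 is the
    mean of ``1 − I2`` over that image's defined distractors.
    """
    p = np.asarray(class_probabilities, dtype=float)
    if (p < -1e-9).any() or np.abs(p.sum(axis=1) - 1.0).max() > 1e-6:
        raise FormatError("rows must be nonnegative and sum to 1")
    true_idx = np.array([classes.index(t) for t in true_labels])
    n, c = p.shape
    i2 = np.full((n, c), np.nan)
    for i in range(n):
        pt = p[i, true_idx[i]]
        for d in range(c):
            if d == true_idx[i]:
                continue
            denom = pt + p[i, d]
            if denom > 0:
                i2[i, d] = p[i, d] / denom
    with np.errstate(invalid="ignore"):
        i1 = np.nanmean(1.0 - i2, axis=1)
    return BehavioralSignature(i1=i1, i2=i2, classes=list(classes))


def signature_correlation(
    model_sig: BehavioralSignature, data_sig: BehavioralSignature
) -> tuple[float, float]:
    """Pearson correlations of I1 vectors and defined I2 cells."""
    if model_sig.classes != data_sig.classes or model_sig.i1.shape != data_sig.i1.shape:
        raise AlignmentError("signatures cover different images or classes")

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        mask = ~(np.isnan(a) | np.isnan(b))
        a, b = a[mask], b[mask]
        if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
            raise UndefinedScoreError("zero-variance or empty signature")
        return float(stats.pearsonr(a, b).statistic)

    return (
        _corr(model_sig.i1, data_sig.i1),
        _corr(model_sig.i2.ravel(), data_sig.i2.ravel()),
    )
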