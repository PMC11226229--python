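"""Metric-versus-predictivity meta-analysis across a model zoo.

Given a tidy table of per-model-layer representation metrics
(factorization, invariance, dimensionality, classification accuracy) and
per-dataset predictivity scores, this module: averages metrics over each
model's final layers; correlates a metric with predictivity across models
(Spearman, with a bootstrap SD over models); and asks whether *combining*
metrics — e.g. classification plus factorization — predicts which models
are most brainlike better than classification alone, via linear regression
evaluated by held-out Spearman correlation over repeated 80/20 splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, RankError, UndefinedScoreError

KEY_COLUMNS = ("model_id", "layer_id")


def validate_model_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"model table missing key columns: {missing}")
    if table.duplicated(list(KEY_COLUMNS)).any():
        raise FormatError("duplicate (model_id, layer_id) keys")
    return table


@dataclass
class MetaResult:
    spearman_rho: dict[tuple[str, str], float]
    bootstrap_sd: dict[tuple[str, str], float]
    combined_rho: dict[tuple[tuple[str, ...], str], float]
    n_models: int
    n_splits: int
    seed: int


def layer_average(table: pd.DataFrame, n_layers: int = 5) -> pd.DataFrame:
    """Average every numeric column over each model's final ``n_layers`` layers.

    Layer order comes from a ``layer_order`` column if present, else from
    the row order within each model.  A model with fewer layers than
    requested is an error rather than a silent partial average.
    """
    validate_model_table(table)
    rows = []
    for model_id, sub in table.groupby("model_id", sort=False):
        if "layer_order" in sub.columns:
            sub = sub.sort_values("layer_order")
        if len(sub) < n_layers:
            raise FormatError(
                f"model {model_id!r} has {len(sub)} layers < n_layers={n_layers}"
            )
        tail = sub.tail(n_layers)
        rec = {"model_id": model_id}
        for col in tail.columns:
            if col in KEY_COLUMNS or col == "layer_order":
                continue
            rec[col] = float(tail[col].mean())
        rows.append(rec)
    return pd.DataFrame(rows)


def metric_fit_correlation(
    table: pd.DataFrame,
    metric: str,
    dataset: str,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Across-model Spearman rho between a metric and predictivity.

    Models are the resampling unit: the bootstrap SD is the standard
    deviation of rho over ``n_bootstrap`` resamples of models with
    replacement.
    """
    sub = table[[metric, dataset]].dropna()
    if len(sub) < 5:
        raise FormatError("need >= 5 models with both values")
    x = sub[metric].to_numpy()
    y = sub[dataset].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedScoreError("constant column: correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(x), size=len(x))
        if np.std(x[idx]) == 0 or np.std(y[idx]) == 0:
            continue
        boots.append(stats.spearmanr(x[idx], y[idx]).statistic)
    return rho, float(np.std(boots))


def combined_metric_regression(
    table: pd.DataFrame,
    metrics: list[str],
    dataset: str,
    train_fraction: float = 0.8,
    n_splits: int = 100,
    seed: int = 0,
) -> float:
    """Held-out predictive power of a linear combination of metrics.

    Per split: ordinary least squares of predictivity on the metric
    columns over the training models; Spearman correlation between
    predicted and actual predictivity on the held-out models; the mean
    over splits is returned.
    """
    sub = table[list(metrics) + [dataset]].dropna()
    n = len(sub)
    if n < 10:
        raise FormatError("need >= 10 models for split regression")
    x = sub[list(metrics)].to_numpy()
    y = sub[dataset].to_numpy()
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), x])) < x.shape[1] + 1:
        raise RankError("metric columns are collinear or constant")
    n_train = max(2, int(round(train_fraction * n)))
    if n_train >= n:
        n_train = n - 2
    rng = np.random.default_rng(seed)
    rhos = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        design = np.column_stack([np.ones(len(tr)), x[tr]])
        coef, *_ = np.linalg.lstsq(design, y[tr], rcond=None)
        pred = np.column_stack([np.ones(len(te)), x[te]]) @ coef
        rhos.append(stats.spearmanr(pred, y[te]).statistic)
    return float(np.mean(rhos))


def meta_analysis(
    table: pd.DataFrame,
    metrics: list[str],
    datasets: list[str],
    combined_sets: list[list[str]] | None = None,
    n_layers: int = 5,
    n_bootstrap: int = 1000,
    n_splits: int = 100,
    seed: int = 0,
) -> MetaResult:
    """Full meta-analysis: layer-average, correlate, and combine metrics."""
    averaged = layer_average(table, n_layers)
    rho: dict[tuple[str, str], float] = {}
    sd: dict[tuple[str, str], float] = {}
    for metric in metrics:
        for ds in datasets:
            r, s = metric_fit_correlation(averaged, metric, ds, n_bootstrap, seed)
            rho[(metric, ds)] = r
            sd[(metric, ds)] = s
    combined: dict[tuple[tuple[str, ...], str], float] = {}
    for metric_set in combined_sets or []:
        for ds in datasets:
            combined[(tuple(metric_set), ds)] = combined_metric_regression(
                averaged, metric_set, ds, n_splits=n_splits, seed=seed
            )
    return MetaResult(
        spearman_rho=rho,
        bootstrap_sd=sd,
        combined_rho=combined,
        n_models=len(averaged),
        n_splits=n_splits,
        seed=seed,
    )
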