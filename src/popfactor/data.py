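"""Core containers and file I/O.

The package-wide orientation convention is rows = conditions (images,
stimuli, movie frames), columns = features (units, voxels, model channels).
Total "variance summed across all dimensions of activity space" is then the
trace of the feature-space covariance, and every metric module relies on it.

Two container types travel together through the pipeline:

* :class:`ResponseMatrix` — the conditions x features activity matrix.
* :class:`AugmentationDesign` — per-condition metadata saying which base
  scene the condition belongs to, which scene parameter was varied to
  produce it and at which level ("augmentation" mode), or which class it
  belongs to ("grouped" mode, for datasets where identity and nuisance
  variables co-vary and only class labels are available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import DesignError, FormatError, VocabularyError

#: Scene parameters recognised in augmentation-mode designs.
PARAM_VOCABULARY = ("background", "lighting", "object_pose", "camera_viewpoint")

DESIGN_COLUMNS = ("condition_id", "base_scene_id", "varied_param", "level", "class_label")


@dataclass
class ResponseMatrix:
    """Population responses: one row per condition, one column per feature."""

    values: np.ndarray
    condition_ids: list[str]
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.condition_ids = [str(c) for c in self.condition_ids]
        if self.values.ndim != 2:
            raise FormatError("response matrix must be 2-D (conditions x features)")
        if self.values.shape[0] < 2:
            raise FormatError("need at least 2 conditions")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("response matrix contains non-finite values")
        if len(self.condition_ids) != self.values.shape[0]:
            raise FormatError("condition_ids length must equal number of rows")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise FormatError("condition_ids must be unique")
        if self.feature_ids is not None:
            self.feature_ids = [str(f) for f in self.feature_ids]
            if len(self.feature_ids) != self.values.shape[1]:
                raise FormatError("feature_ids length must equal number of columns")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def row_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.condition_ids)}

    def subset(self, condition_ids: Sequence[str]) -> "ResponseMatrix":
        """Rows for the given conditions, in the given order."""
        idx = self.row_index()
        rows = [idx[c] for c in condition_ids]
        return ResponseMatrix(
            self.values[rows], list(condition_ids), self.feature_ids
        )

    def with_values(self, values: np.ndarray) -> "ResponseMatrix":
        return ResponseMatrix(values, list(self.condition_ids), self.feature_ids)


class AugmentationDesign:
    """Per-condition metadata defining the variance decomposition.

    Modes
    -----
    ``"augmentation"``
        ``base_scene_id`` and ``varied_param`` are populated: each condition
        is one level of one varied scene parameter of one base scene.  Every
        parameter present within a base scene must have a constant number of
        levels across base scenes.
    ``"grouped"``
        only ``class_label`` is populated: conditions are grouped into
        classes, with all nuisance variation folded into the within-class
        spread.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        missing = [c for c in DESIGN_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"design table missing columns: {missing}")
        table["condition_id"] = table["condition_id"].astype(str)
        if table["condition_id"].duplicated().any():
            raise DesignError("duplicate condition_id in design")

        has_aug = table["base_scene_id"].notna() & table["varied_param"].notna()
        has_class = table["class_label"].notna()
        if has_aug.all():
            self.mode = "augmentation"
        elif has_class.all() and not has_aug.any():
            self.mode = "grouped"
        else:
            raise DesignError(
                "design must be fully augmentation-mode (base_scene_id + "
                "varied_param populated) or fully grouped-mode (class_label populated)"
            )

        if self.mode == "augmentation":
            unknown = set(table["varied_param"].astype(str)) - set(PARAM_VOCABULARY)
            if unknown:
                raise VocabularyError(f"unknown scene parameter(s): {sorted(unknown)}")
            table["level"] = table["level"].astype(int)
            if (table["level"] < 0).any():
                raise DesignError("levels must be >= 0")
            # Per parameter, every base scene must carry the same level count.
            counts = table.groupby(["varied_param", "base_scene_id"]).size()
            for param, sub in counts.groupby(level="varied_param"):
                if sub.nunique() != 1:
                    raise DesignError(
                        f"unequal level counts across base scenes for {param!r}"
                    )
        self.table = table.reset_index(drop=True)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.table["condition_id"])

    @property
    def params(self) -> list[str]:
        if self.mode != "augmentation":
            return []
        seen: list[str] = []
        for p in self.table["varied_param"]:
            if p not in seen:
                seen.append(p)
        return seen

    @property
    def class_labels(self) -> pd.Series:
        if self.mode != "grouped":
            raise DesignError("class labels only defined in grouped mode")
        return self.table.set_index("condition_id")["class_label"]

    def __len__(self) -> int:
        return len(self.table)

    def check_matches(self, responses: ResponseMatrix) -> None:
        if set(self.condition_ids) != set(responses.condition_ids):
            raise DesignError("design and response matrix conditions differ")

    def conditions_for(self, param: str) -> pd.DataFrame:
        """Augmentation-mode rows for one varied parameter."""
        if self.mode != "augmentation":
            raise DesignError("parameter lookup requires augmentation mode")
        sub = self.table[self.table["varied_param"] == param]
        if sub.empty:
            raise KeyError(f"parameter {param!r} not present in design")
        return sub


@dataclass
class AnalysisConfig:
    """Shared analysis knobs.

    pca_variance_threshold
        cumulative explained-variance fraction defining principal subspaces
        (the "90% of the variance" rule), in (0, 1].
    encoding_n_components
        number of leading PCs a representation is reduced to before ridge
        encoding fits.
    ridge_penalty_grid
        candidate ridge penalties for inner cross-validation.
    """

    pca_variance_threshold: float = 0.9
    encoding_n_components: int = 300
    ridge_penalty_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pca_variance_threshold <= 1.0):
            raise FormatError("pca_variance_threshold must be in (0, 1]")
        if self.encoding_n_components < 1:
            raise FormatError("encoding_n_components must be positive")
        if len(self.ridge_penalty_grid) == 0 or any(
            p <= 0 for p in self.ridge_penalty_grid
        ):
            raise FormatError("ridge_penalty_grid must be non-empty positive reals")
        if self.cv_folds < 2:
            raise FormatError("cv_folds must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError("config file must contain a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "ridge_penalty_grid" in raw:
            raw["ridge_penalty_grid"] = tuple(raw["ridge_penalty_grid"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "pca_variance_threshold": self.pca_variance_threshold,
            "encoding_n_components": self.encoding_n_components,
            "ridge_penalty_grid": list(self.ridge_penalty_grid),
            "cv_folds": self.cv_folds,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)


# ---------------------------------------------------------------------------
# File I/O


def read_response_matrix(path: str | Path, format: str | None = None) -> ResponseMatrix:
    """Read a response matrix from CSV or HDF5.

    CSV layout: ``condition_id`` first column, one column per feature.
    HDF5 layout: datasets ``values``, ``condition_ids`` and (optionally)
    ``feature_ids``.  Row order in the file is preserved.
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in {".h5", ".hdf5"} else "csv"
    if format == "csv":
        frame = pd.read_csv(path, dtype={0: str})
        if frame.columns[0] != "condition_id":
            raise FormatError("first CSV column must be condition_id")
        values = frame.iloc[:, 1:].to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric cells in response matrix CSV")
        return ResponseMatrix(
            values, list(frame["condition_id"]), list(frame.columns[1:])
        )
    if format == "hdf5":
        with h5py.File(path, "r") as fh:
            values = fh["values"][()]
            condition_ids = [c.decode() for c in fh["condition_ids"][()]]
            feature_ids = None
            if "feature_ids" in fh:
                feature_ids = [f.decode() for f in fh["feature_ids"][()]]
        return ResponseMatrix(values, condition_ids, feature_ids)
    raise FormatError(f"unknown format {format!r}")


def write_response_matrix(
    matrix: ResponseMatrix, path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in {".h5", ".hdf5"} else "csv"
    if format == "csv":
        cols = matrix.feature_ids or [f"f{i}" for i in range(matrix.n_features)]
        frame = pd.DataFrame(matrix.values, columns=cols)
        frame.insert(0, "condition_id", matrix.condition_ids)
        frame.to_csv(path, index=False)
    elif format == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=matrix.values)
            fh.create_dataset(
                "condition_ids",
                data=np.array([c.encode() for c in matrix.condition_ids]),
            )
            if matrix.feature_ids is not None:
                fh.create_dataset(
                    "feature_ids",
                    data=np.array([f.encode() for f in matrix.feature_ids]),
                )
    else:
        raise FormatError(f"unknown format {format!r}")


def read_design(path: str | Path) -> AugmentationDesign:
    """Read a design table from CSV (or TSV, by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    table = pd.read_csv(path, sep=sep, dtype={"condition_id": str})
    return AugmentationDesign(table)


def write_design(design: AugmentationDesign, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    design.table.to_csv(path, sep=sep, index=False)
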