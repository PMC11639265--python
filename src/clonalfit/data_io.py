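"""Dataset loading, preprocessing and fold splitting.

Four delimited-text dialects of UCI clinical tables are supported.  Rows
containing the literal ``?`` missing marker are deleted (listwise) and
counted; identifier columns are dropped; targets are binarized to {0, 1}.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import InvalidInputError, ParseError

__all__ = [
    "Dataset",
    "ScalerParams",
    "load_dataset",
    "fit_scaler",
    "apply_scaler",
    "kfold_split",
    "drop_features",
    "DIALECTS",
    "FEATURE_DROP_PRESETS",
    "DEFAULT_SCALERS",
]

HEART_FEATURES = [
    "age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
    "thalach", "exang", "oldpeak", "slope", "ca", "thal",
]

WBCO_FEATURES = [
    "clump_thickness", "cell_size_uniformity", "cell_shape_uniformity",
    "marginal_adhesion", "single_epithelial_cell_size", "bare_nuclei",
    "bland_chromatin", "normal_nucleoli", "mitoses",
]

_WBCD_BASE = [
    "radius", "texture", "perimeter", "area", "smoothness", "compactness",
    "concavity", "concave_points", "symmetry", "fractal_dimension",
]
WBCD_FEATURES = [f"{b}_{s}" for s in ("mean", "se", "worst") for b in _WBCD_BASE]

#: feature-drop presets motivated by near-zero / unstable fold weights
FEATURE_DROP_PRESETS = {
    "statlog_fs": ["restecg"],
    "cleveland_fs": ["trestbps", "fbs", "restecg"],
}

#: scaling method used for each replication dataset
DEFAULT_SCALERS = {"cleveland": "minmax", "statlog": "minmax", "wbco": "minmax", "wbcd": "zscore"}


@dataclass(frozen=True)
class Dataset:
    """A clean binary-classification table: features, labels, names."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    name: str = ""
    n_dropped: int = 0

    def __post_init__(self):
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=np.int64))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if self.X.ndim != 2 or self.y.ndim != 1 or self.X.shape[0] != self.y.shape[0]:
            raise InvalidInputError("X must be (M, N) with a matching y")
        if len(self.feature_names) != self.X.shape[1]:
            raise InvalidInputError("feature_names length must equal feature count")
        if not np.all(np.isfinite(self.X)):
            raise InvalidInputError("X must be finite after loading")
        if not np.isin(np.unique(self.y), (0, 1)).all():
            raise InvalidInputError("y must be binary")

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class _Dialect:
    sep: str
    n_columns: int
    feature_names: tuple[str, ...]
    target_column: int          # position in the raw table
    id_columns: tuple[int, ...] = ()

    def binarize(self, target: pd.Series) -> np.ndarray:
        raise NotImplementedError


class _ClevelandDialect(_Dialect):
    def binarize(self, target):
        return (pd.to_numeric(target) > 0).to_numpy(dtype=np.int64)


class _StatlogDialect(_Dialect):
    def binarize(self, target):
        return (pd.to_numeric(target) == 2).to_numpy(dtype=np.int64)


class _WbcoDialect(_Dialect):
    def binarize(self, target):
        return (pd.to_numeric(target) == 4).to_numpy(dtype=np.int64)


class _WbcdDialect(_Dialect):
    def binarize(self, target):
        vals = target.astype(str).str.strip()
        bad = ~vals.isin(["M", "B"])
        if bad.any():
            raise ParseError(f"unexpected diagnosis label {vals[bad].iloc[0]!r}",
                             line=int(bad.idxmax()) + 1)
        return (vals == "M").to_numpy(dtype=np.int64)


DIALECTS: dict[str, _Dialect] = {
    "cleveland": _ClevelandDialect(sep=",", n_columns=14, feature_names=tuple(HEART_FEATURES),
                                   target_column=13),
    "statlog": _StatlogDialect(sep=r"\s+", n_columns=14, feature_names=tuple(HEART_FEATURES),
                               target_column=13),
    "wbco": _WbcoDialect(sep=",", n_columns=11, feature_names=tuple(WBCO_FEATURES),
                         target_column=10, id_columns=(0,)),
    "wbcd": _WbcdDialect(sep=",", n_columns=32, feature_names=tuple(WBCD_FEATURES),
                         target_column=1, id_columns=(0,)),
}


def load_dataset(source, dialect: str, name: str | None = None) -> Dataset:
    """Parse a delimited UCI-style text table into a clean :class:`Dataset`.

    ``source`` may be a path or an open text buffer.  Rows containing the
    literal ``?`` marker in any field are removed and counted in the returned
    dataset's ``n_dropped``.
    """
    if dialect not in DIALECTS:
        raise InvalidInputError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    d = DIALECTS[dialect]
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    try:
        raw = pd.read_csv(io.StringIO(text), sep=d.sep, header=None, dtype=str,
                          skipinitialspace=True, comment=None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {dialect} table: {exc}") from exc
    raw = raw.dropna(how="all")
    if raw.shape[1] != d.n_columns:
        raise ParseError(
            f"{dialect} dialect expects {d.n_columns} columns, found {raw.shape[1]}")

    stripped = raw.apply(lambda col: col.astype(str).str.strip())
    missing = stripped.apply(lambda col: col == "?").any(axis=1)
    n_dropped = int(missing.sum())
    kept = stripped.loc[~missing].reset_index(drop=True)
    if kept.empty:
        raise ParseError("no rows remain after removing missing-value rows")

    y = d.binarize(kept.iloc[:, d.target_column])
    feat_positions = [c for c in range(d.n_columns)
                      if c != d.target_column and c not in d.id_columns]
    feats = kept.iloc[:, feat_positions]
    try:
        X = feats.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError):
        for r in range(feats.shape[0]):
            for c in range(feats.shape[1]):
                try:
                    float(feats.iat[r, c])
                except ValueError:
                    raise ParseError(
                        f"non-numeric feature value {feats.iat[r, c]!r}", line=r + 1
                    ) from None
        raise
    return Dataset(X=X, y=y, feature_names=d.feature_names,
                   name=name or dialect, n_dropped=n_dropped)


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature statistics learned from training rows only."""

    method: str                       # 'minmax' or 'zscore'
    center: np.ndarray                # min (minmax) or mean (zscore)
    scale: np.ndarray                 # range or population std; 0 marks a constant feature


def fit_scaler(X, method: str = "minmax") -> ScalerParams:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise InvalidInputError("train X must be a non-empty 2-D array")
    if method == "minmax":
        lo = X.min(axis=0)
        scale = X.max(axis=0) - lo
        return ScalerParams("minmax", center=lo, scale=scale)
    if method == "zscore":
        mean = X.mean(axis=0)
        std = X.std(axis=0)  # population std
        if np.any(std == 0):
            warnings.warn("constant feature under zscore scaling; mapped to 0", stacklevel=2)
        return ScalerParams("zscore", center=mean, scale=std)
    raise InvalidInputError(f"unknown scaling method {method!r}")


def apply_scaler(params: ScalerParams, X) -> np.ndarray:
    """Transform rows with training statistics; constant features map to 0."""
    X = np.asarray(X, dtype=float)
    safe = np.where(params.scale == 0, 1.0, params.scale)
    out = (X - params.center) / safe
    out[:, params.scale == 0] = 0.0
    return out


def kfold_split(dataset, k: int, seed: int = 0, stratified: bool = True) -> list[np.ndarray]:
    """Disjoint covering test-fold index lists, sizes within 1, seeded shuffle."""
    if isinstance(dataset, Dataset):
        y = dataset.y
    else:
        y = np.asarray(dataset)
    m = y.shape[0]
    if not 2 <= k <= m:
        raise InvalidInputError(f"k must lie in [2, {m}], got {k}")
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros((m, 1)), y)]


def drop_features(dataset: Dataset, names: Sequence[str]) -> Dataset:
    """Remove named feature columns, preserving the order of the rest."""
    unknown = [n for n in names if n not in dataset.feature_names]
    if unknown:
        raise InvalidInputError(f"unknown feature(s): {unknown}")
    keep = [i for i, n in enumerate(dataset.feature_names) if n not in set(names)]
    return replace(dataset,
                   X=dataset.X[:, keep],
                   feature_names=tuple(dataset.feature_names[i] for i in keep))
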