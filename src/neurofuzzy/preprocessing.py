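"""Data preparation pipeline for the classifiers.

Stages, in the order the pipeline applies them: categorical encoding, mean
imputation of missing entries, correlation-based removal of duplicate
features, stratified train/test splitting, and per-feature range
normalisation to [-1, +1] fitted on the training part only (so test values
may fall outside the bounds — that is the leakage-free contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, NeuroFuzzyError


@dataclass
class Dataset:
    """Numeric feature matrix with integer class labels.

    Missing entries are NaN until the imputation stage removes them.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list = field(default_factory=list)
    class_names: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise NeuroFuzzyError("X and y row counts differ")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        if not self.class_names:
            self.class_names = [str(c) for c in range(int(self.y.max()) + 1 if self.y.size else 0)]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class PipelineConfig:
    """Knobs of the preparation pipeline."""

    correlation_threshold: float = 0.95
    norm_lo: float = -1.0
    norm_hi: float = 1.0
    split_fraction: float = 0.7
    seed: int = 0
    stratified: bool = True
    encoding: str = "ordinal"          # {"ordinal", "one_hot"}
    clip_test: bool = False
    paper_literal_order: bool = False  # normalise before splitting (leaky)

    def __post_init__(self):
        if not self.norm_lo < self.norm_hi:
            raise ConfigurationError("normalisation bounds need lo < hi")
        if not 0 < self.split_fraction < 1:
            raise ConfigurationError("split fraction must lie in (0, 1)")


def impute_mean(data: Dataset) -> Dataset:
    """Replace every missing entry with its feature's observed mean."""
    X = data.X.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        mask = np.isnan(col)
        if mask.all():
            raise NeuroFuzzyError(
                f"feature {data.feature_names[j]!r} has no observed values to impute from")
        if mask.any():
            col[mask] = col[~mask].mean()
    return replace(data, X=X)


def _pairwise_corr(a, b) -> float:
    """|Pearson r| with degenerate columns treated as uncorrelated,
    except exact duplicates which count as fully correlated."""
    if np.array_equal(a, b):
        return 1.0
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


def select_features_correlation(data: Dataset, threshold: float = 0.95):
    """Drop one member of every near-duplicate feature pair.

    For each pair with |Pearson r| >= threshold the member less correlated
    (in absolute value) with the class labels is dropped; on a tie the
    later column goes.  Survivors keep their original order.  Returns
    ``(reduced dataset, dropped feature names)``.
    """
    if data.n_samples < 2:
        raise NeuroFuzzyError("need at least 2 samples for correlation analysis")
    X, y = data.X, data.y.astype(float)
    k = data.n_features
    class_corr = np.array([
        0.0 if X[:, j].std() == 0 or y.std() == 0
        else abs(float(np.corrcoef(X[:, j], y)[0, 1]))
        for j in range(k)])
    class_corr = np.nan_to_num(class_corr)
    dropped = set()
    for i in range(k):
        if i in dropped:
            continue
        for j in range(i + 1, k):
            if j in dropped:
                continue
            if _pairwise_corr(X[:, i], X[:, j]) >= threshold:
                victim = j if class_corr[j] <= class_corr[i] else i
                dropped.add(victim)
                if victim == i:
                    break
    keep = [j for j in range(k) if j not in dropped]
    reduced = replace(data, X=X[:, keep],
                      feature_names=[data.feature_names[j] for j in keep])
    return reduced, [data.feature_names[j] for j in sorted(dropped)]


def normalize_range(train: Dataset, test: Dataset | None = None,
                    lo: float = -1.0, hi: float = 1.0, clip_test: bool = False):
    """Affine map of each feature's training range onto [lo, hi].

    The map is fitted on the training split only and then applied to the
    test split, whose values may therefore exceed the bounds (clipped only
    when ``clip_test``).  A constant training feature maps to the midpoint.
    Returns ``(train, test, (mins, maxs))``; ``test`` is None if not given.
    """
    if np.isnan(train.X).any():
        raise NeuroFuzzyError("normalise after imputation; training data has NaNs")
    mins = train.X.min(axis=0)
    maxs = train.X.max(axis=0)
    span = maxs - mins

    def _apply(X):
        out = np.empty_like(X, dtype=float)
        mid = 0.5 * (lo + hi)
        for j in range(X.shape[1]):
            if span[j] == 0:
                out[:, j] = mid
            else:
                out[:, j] = lo + (X[:, j] - mins[j]) * (hi - lo) / span[j]
        return out

    train_out = replace(train, X=_apply(train.X))
    test_out = None
    if test is not None:
        Xt = _apply(test.X)
        if clip_test:
            Xt = np.clip(Xt, lo, hi)
        test_out = replace(test, X=Xt)
    return train_out, test_out, (mins, maxs)


def split(data: Dataset, fraction: float = 0.7, seed=None, stratified: bool = True):
    """Seeded train/test partition; train size = round(fraction * n).

    With ``stratified`` (the default) the rounding applies per class, so
    class proportions carry over to both parts.
    """
    rng = np.random.default_rng(seed)
    n = data.n_samples
    if stratified:
        train_idx, test_idx = [], []
        for c in np.unique(data.y):
            idx = np.flatnonzero(data.y == c)
            rng.shuffle(idx)
            n_train = int(np.floor(fraction * len(idx) + 0.5))
            if n_train == 0:
                raise ConfigurationError(
                    f"class {c} would be absent from the training split")
            train_idx.extend(idx[:n_train])
            test_idx.extend(idx[n_train:])
        train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    else:
        perm = rng.permutation(n)
        n_train = int(np.floor(fraction * n + 0.5))
        train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ConfigurationError("split left one part empty")

    def _take(idx):
        return replace(data, X=data.X[idx], y=data.y[idx])

    return _take(train_idx), _take(test_idx)


class CategoricalEncoder:
    """Maps string-valued columns to numbers; reusable on test data.

    ``ordinal`` assigns integers by sorted category name; ``one_hot``
    expands a column into per-category indicators.  Categories unseen
    during fitting raise an error at transform time.
    """

    def __init__(self, encoding: str = "ordinal"):
        if encoding not in ("ordinal", "one_hot"):
            raise ConfigurationError(f"unknown encoding {encoding!r}")
        self.encoding = encoding
        self.mappings_: dict = {}

    def fit_transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        return self._run(frame, fit=True)

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        return self._run(frame, fit=False)

    def _run(self, frame, fit):
        out = {}
        for col in frame.columns:
            series = frame[col]
            if pd.api.types.is_numeric_dtype(series):
                out[col] = pd.to_numeric(series)
                continue
            observed = series.dropna().astype(str)
            if fit:
                self.mappings_[col] = sorted(observed.unique())
            if col not in self.mappings_:
                raise NeuroFuzzyError(f"column {col!r} was not seen during fitting")
            cats = self.mappings_[col]
            unseen = set(observed.unique()) - set(cats)
            if unseen:
                raise NeuroFuzzyError(
                    f"column {col!r} has unseen categories {sorted(unseen)}")
            if self.encoding == "ordinal":
                lookup = {c: i for i, c in enumerate(cats)}
                out[col] = series.map(lambda v: np.nan if pd.isna(v) else lookup[str(v)])
            else:
                for c in cats:
                    out[f"{col}={c}"] = series.map(
                        lambda v, c=c: np.nan if pd.isna(v) else float(str(v) == c))
        return pd.DataFrame(out, index=frame.index)


def encode_categoricals(frame: pd.DataFrame, class_column: str | None = None,
                        encoding: str = "ordinal"):
    """Encode a raw table into a :class:`Dataset`.

    The class column (last column by default) is label-encoded by sorted
    name; feature columns go through :class:`CategoricalEncoder`.  String
    categoricals are mode-imputed before encoding; numeric missing values
    stay NaN for the mean-imputation stage.  Returns ``(dataset, encoder)``.
    """
    if class_column is None:
        class_column = frame.columns[-1]
    if class_column not in frame.columns:
        raise NeuroFuzzyError(f"class column {class_column!r} not in table")
    y_raw = frame[class_column]
    if y_raw.isna().any():
        raise NeuroFuzzyError("class column contains missing values")
    class_names = sorted(y_raw.astype(str).unique())
    y = y_raw.astype(str).map({c: i for i, c in enumerate(class_names)}).to_numpy()
    features = frame.drop(columns=[class_column]).copy()
    for col in features.columns:
        if not pd.api.types.is_numeric_dtype(features[col]) and features[col].isna().any():
            mode = features[col].mode(dropna=True)
            if len(mode) == 0:
                raise NeuroFuzzyError(f"feature {col!r} is entirely missing")
            features[col] = features[col].fillna(mode.iloc[0])
    encoder = CategoricalEncoder(encoding=encoding)
    encoded = encoder.fit_transform(features)
    data = Dataset(X=encoded.to_numpy(dtype=float), y=y,
                   feature_names=list(encoded.columns), class_names=class_names)
    return data, encoder


def prepare(data: Dataset, config: PipelineConfig):
    """Run imputation, selection, splitting and normalisation in order.

    Returns ``(train, test, info)`` where info records dropped features and
    the fitted normalisation parameters.  With ``paper_literal_order`` the
    normalisation is fitted on the full dataset before splitting.
    """
    data = impute_mean(data)
    data, dropped = select_features_correlation(data, config.correlation_threshold)
    if config.paper_literal_order:
        data, _, norm = normalize_range(data, None, config.norm_lo, config.norm_hi)
        train, test = split(data, config.split_fraction, config.seed, config.stratified)
    else:
        train, test = split(data, config.split_fraction, config.seed, config.stratified)
        train, test, norm = normalize_range(train, test, config.norm_lo,
                                            config.norm_hi, config.clip_test)
    info = {"dropped_features": dropped,
            "norm_mins": norm[0].tolist(), "norm_maxs": norm[1].tolist()}
    return train, test, info
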