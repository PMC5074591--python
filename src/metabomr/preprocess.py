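"""Metabolomics feature-table quality control and normalization.

The pipeline applied to LC/MS feature intensities is: log-transform,
ANOVA-type removal of unwanted technical variation (plate intercepts plus a
linear acquisition-order drift), then feature filtering (early retention
times, low between-duplicate correlation, per-value outlier masking, a
minimum non-missing count) and finally per-feature standardization to
mean 0, SD 1.  Sample SDs use the n-1 denominator throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

__all__ = [
    "FeatureTable", "log_transform", "anova_standardize",
    "filter_features", "standardize",
]


@dataclass
class FeatureTable:
    """An intensity matrix with feature and sample metadata.

    features: one row per feature (id, mz, rt_seconds, annotation).
    intensities: samples x features, non-negative or NaN.
    sample_meta: per-sample plate, acquisition order, duplicate-pair id.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    log_scale: bool = False
    history: list[str] = field(default_factory=list)

    def __post_init__(self):
        if list(self.intensities.columns) != list(self.features["id"]):
            raise DataError("intensity columns do not match feature ids")
        if not self.intensities.index.equals(self.sample_meta.index):
            raise DataError("intensity rows do not match sample metadata")
        if (self.features["rt_seconds"] < 0).any():
            raise DataError("retention times must be non-negative")
        if not self.log_scale and (self.intensities < 0).any().any():
            raise DataError("raw intensities must be non-negative or missing")

    def copy_with(self, **kw) -> "FeatureTable":
        return replace(
            self,
            features=kw.get("features", self.features).copy(),
            intensities=kw.get("intensities", self.intensities).copy(),
            sample_meta=self.sample_meta.copy(),
            log_scale=kw.get("log_scale", self.log_scale),
            history=self.history + [kw["step"]] if "step" in kw else list(self.history),
        )

    @property
    def n_features(self) -> int:
        return len(self.features)


def log_transform(table: FeatureTable, pseudo_half_min: bool = True) -> FeatureTable:
    """Natural log of intensities; missing values are preserved.

    Zero intensities are replaced by half the feature's minimum positive
    value before the log (configurable; the rule is a documented
    pseudo-count convention, not a measurement).
    """
    if table.log_scale:
        return table
    x = table.intensities.to_numpy(dtype=float).copy()
    if np.nanmin(x) < 0:
        raise DataError("negative intensity encountered")
    zeros = x == 0
    if zeros.any():
        if not pseudo_half_min:
            raise DataError("zero intensities present and pseudo-count disabled")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_min = np.nanmin(np.where(x > 0, x, np.nan), axis=0)
        for j in np.where(zeros.any(axis=0))[0]:
            if not np.isfinite(col_min[j]):
                raise DataError(f"feature {table.features['id'].iloc[j]} has no positive values")
            x[zeros[:, j], j] = 0.5 * col_min[j]
    out = pd.DataFrame(np.log(x), index=table.intensities.index,
                       columns=table.intensities.columns)
    return table.copy_with(intensities=out, log_scale=True, step="log_transform")


def anova_standardize(
    table: FeatureTable,
    factors: tuple[str, ...] = ("plate",),
    order_col: str | None = "order",
) -> FeatureTable:
    """Remove batch structure per feature by linear-model residualization.

    For each feature, log intensity is regressed on the categorical batch
    factors (plate, analysis date, ...) plus a linear acquisition-order
    drift term; the residuals plus the feature's grand mean are returned,
    so per-plate means agree afterwards.  Missing values are excluded from
    each feature's fit and stay missing.  Idempotent up to numerical noise.
    """
    if not table.log_scale:
        raise DataError("anova_standardize expects log-scale intensities")
    meta = table.sample_meta
    cols = []
    for f in factors:
        if f not in meta:
            raise ConfigurationError(f"sample metadata lacks factor column {f!r}")
        levels = meta[f].astype("category")
        counts = levels.value_counts()
        single = counts[counts == 1]
        if len(single):
            warnings.warn(
                f"factor {f!r} has single-sample levels {list(single.index)}; "
                "their effects are estimated from one observation",
                stacklevel=2,
            )
        dummies = pd.get_dummies(levels, drop_first=True, dtype=float)
        cols.append(dummies.to_numpy())
    if order_col is not None:
        if order_col not in meta:
            raise ConfigurationError(f"sample metadata lacks order column {order_col!r}")
        order = meta[order_col].to_numpy(dtype=float)
        cols.append((order - order.mean())[:, None])

    n = len(meta)
    X = np.column_stack([np.ones(n)] + cols) if cols else np.ones((n, 1))
    Y = table.intensities.to_numpy(dtype=float)
    out = np.full_like(Y, np.nan)
    complete = np.isfinite(Y).all(axis=0)
    # complete features share one design: solve in a single lstsq
    if complete.any():
        beta, *_ = np.linalg.lstsq(X, Y[:, complete], rcond=None)
        resid = Y[:, complete] - X @ beta
        out[:, complete] = resid + Y[:, complete].mean(axis=0)
    for j in np.where(~complete)[0]:
        m = np.isfinite(Y[:, j])
        if m.sum() <= X.shape[1]:
            out[m, j] = Y[m, j]  # too few points to adjust; pass through
            continue
        beta, *_ = np.linalg.lstsq(X[m], Y[m, j], rcond=None)
        out[m, j] = Y[m, j] - X[m] @ beta + Y[m, j].mean()
    res = pd.DataFrame(out, index=table.intensities.index, columns=table.intensities.columns)
    return table.copy_with(intensities=res, step="anova_standardize")


def filter_features(
    table: FeatureTable,
    min_rt: float | None = 35.0,
    min_dup_corr: float | None = 0.5,
    outlier_sd: float | None = 3.0,
    min_nonmissing: int | None = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Feature QC: retention time, duplicate correlation, outliers, missingness.

    Filters run in a fixed order: (1) drop features eluting before
    ``min_rt`` seconds; (2) drop features whose Pearson correlation across
    duplicate sample pairs (log scale, pairwise-complete) falls below
    ``min_dup_corr``; (3) mask individual values further than
    ``outlier_sd`` sample SDs from the feature mean; (4) drop features
    left with fewer than ``min_nonmissing`` values.  Pass None to disable
    any step.  Returns the filtered table and a report with one row per
    removed feature (columns feature_id, reason, value) plus per-feature
    masked-value counts under reason ``outlier_masked``.
    """
    feats = table.features.copy()
    X = table.intensities.copy()
    report_rows: list[dict] = []

    if min_rt is not None:
        bad = feats["rt_seconds"] < min_rt
        for _, row in feats[bad].iterrows():
            report_rows.append(
                {"feature_id": row["id"], "reason": "retention_time", "value": row["rt_seconds"]}
            )
        feats = feats[~bad].reset_index(drop=True)
        X = X[feats["id"]]

    if min_dup_corr is not None:
        if "duplicate_pair" not in table.sample_meta:
            raise ConfigurationError(
                "duplicate-correlation filter requested but sample metadata has no duplicate_pair"
            )
        pair = table.sample_meta["duplicate_pair"]
        counts = pair.value_counts()
        pair_ids = counts[counts == 2].index
        if len(pair_ids) == 0:
            raise ConfigurationError("no complete duplicate pairs available")
        first, second = [], []
        for pid in pair_ids:
            a, b = table.sample_meta.index[pair == pid]
            first.append(a)
            second.append(b)
        vals = X if table.log_scale else np.log(X.where(X > 0))
        a = vals.loc[first].to_numpy(dtype=float)
        b = vals.loc[second].to_numpy(dtype=float)
        corrs = np.full(X.shape[1], np.nan)
        for j in range(X.shape[1]):
            m = np.isfinite(a[:, j]) & np.isfinite(b[:, j])
            if m.sum() >= 3 and a[m, j].std() > 0 and b[m, j].std() > 0:
                corrs[j] = np.corrcoef(a[m, j], b[m, j])[0, 1]
        bad = ~(corrs >= min_dup_corr)  # NaN correlation counts as failing
        for j in np.where(bad)[0]:
            report_rows.append(
                {"feature_id": feats["id"].iloc[j], "reason": "duplicate_correlation",
                 "value": corrs[j]}
            )
        feats = feats[~bad].reset_index(drop=True)
        X = X[feats["id"]]

    if outlier_sd is not None:
        arr = X.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(arr, axis=0)
            sd = np.nanstd(arr, axis=0, ddof=1)
        dev = np.abs(arr - mu)
        mask = np.isfinite(arr) & (sd > 0) & (dev > outlier_sd * sd)
        n_masked = mask.sum(axis=0)
        for j in np.where(n_masked > 0)[0]:
            report_rows.append(
                {"feature_id": feats["id"].iloc[j], "reason": "outlier_masked",
                 "value": int(n_masked[j])}
            )
        arr[mask] = np.nan
        X = pd.DataFrame(arr, index=X.index, columns=X.columns)

    if min_nonmissing is not None:
        nn = X.notna().sum(axis=0)
        bad = nn < min_nonmissing
        for fid in X.columns[bad]:
            report_rows.append(
                {"feature_id": fid, "reason": "non_missing_count", "value": int(nn[fid])}
            )
        feats = feats[~bad.to_numpy()].reset_index(drop=True)
        X = X[feats["id"]]

    report = pd.DataFrame(report_rows, columns=["feature_id", "reason", "value"])
    out = table.copy_with(features=feats, intensities=X, step="filter_features")
    return out, report


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature standardization to mean 0, SD 1 on non-missing entries.

    Zero-variance features cannot be scaled; they are dropped with a
    warning.  Idempotent: standardize(standardize(x)) == standardize(x).
    """
    x = matrix.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0, ddof=1)
    nn = np.isfinite(x).sum(axis=0)
    bad = (nn < 2) | (sd == 0) | ~np.isfinite(sd)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} zero-variance or under-observed features: "
            f"{list(matrix.columns[bad])[:5]}...",
            stacklevel=2,
        )
    z = (x[:, ~bad] - mu[~bad]) / sd[~bad]
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns[~bad])
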