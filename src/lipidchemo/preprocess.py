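"""Pre-treatment chain: imputation, log transform, autoscaling, QC CV.

Order of operations in the pipeline: impute on the raw intensity scale,
log10-transform, then autoscale (per-feature mean centring and division
by the standard deviation).  No between-sample normalisation is applied;
instrument stability is instead audited through QC coefficients of
variation (features with CV >= 30 % over pooled QC injections are
considered unreliable).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

IMPUTE_METHODS = ("linear_interpolation", "movemedian", "column_median")


def impute_missing(matrix: pd.DataFrame, method: str = "linear_interpolation") -> pd.DataFrame:
    """Fill missing entries column-wise; observed entries are never altered.

    ``linear_interpolation`` interpolates within each feature column along
    the sample (acquisition) order, extending the nearest observed value at
    the boundaries.  ``movemedian`` replaces a missing value with the median
    over a centred window of three points; ``column_median`` uses the
    feature's overall median.
    """
    if method not in IMPUTE_METHODS:
        raise ValueError(f"unknown imputation method {method!r}; choose from {IMPUTE_METHODS}")
    fully_missing = matrix.columns[matrix.isna().all(axis=0)]
    if len(fully_missing):
        raise ValueError(f"features with no observed values: {list(fully_missing)}")
    if not matrix.isna().any().any():
        return matrix.copy()

    if method == "linear_interpolation":
        # positional interpolation along rows, constant extrapolation at edges
        out = matrix.reset_index(drop=True).interpolate(
            method="linear", limit_direction="both", axis=0
        )
        out.index = matrix.index
    elif method == "movemedian":
        rolled = matrix.rolling(window=3, center=True, min_periods=1).median()
        out = matrix.fillna(rolled)
        # missing runs longer than the window: fall back to nearest value
        out = out.ffill().bfill()
    else:
        out = matrix.fillna(matrix.median(axis=0))
    return out


def log_transform(matrix: pd.DataFrame, base: int = 10) -> pd.DataFrame:
    """Element-wise log10 / log2; rejects non-positive entries by coordinate."""
    if base not in (10, 2):
        raise ValueError(f"log base must be 10 or 2, got {base}")
    values = matrix.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = ~(values > 0) & ~np.isnan(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "non-positive intensity at sample "
            f"{matrix.index[i]!r}, feature {matrix.columns[j]!r}: {values[i, j]}"
        )
    fn = np.log10 if base == 10 else np.log2
    return pd.DataFrame(fn(values), index=matrix.index, columns=matrix.columns)


@dataclass
class ScalingModel:
    """Frozen autoscaling parameters, reusable on held-out samples."""

    mean: pd.Series
    sd: pd.Series
    log_base: int | None = None

    def apply(self, matrix: pd.DataFrame) -> pd.DataFrame:
        cols = self.mean.index
        return (matrix[cols] - self.mean) / self.sd

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean.to_dict(),
                "sd": self.sd.to_dict(),
                "log_base": self.log_base,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalingModel":
        d = json.loads(text)
        return cls(pd.Series(d["mean"]), pd.Series(d["sd"]), d["log_base"])


def autoscale(
    matrix: pd.DataFrame, model: ScalingModel | None = None, ddof: int = 1
) -> tuple[pd.DataFrame, ScalingModel]:
    """Mean-centre and scale each feature to unit standard deviation.

    With ``model`` given, applies stored parameters (e.g. to a test fold).
    Zero-variance features are dropped with a warning rather than erroring.
    """
    if model is not None:
        return model.apply(matrix), model
    if matrix.isna().any().any():
        raise ValueError("autoscale requires a complete matrix; impute first")
    if len(matrix) < 2:
        raise ValueError("autoscale needs at least 2 samples")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=ddof)
    degenerate = sd.index[(sd == 0) | sd.isna()]
    if len(degenerate):
        warnings.warn(
            f"dropping {len(degenerate)} zero-variance feature(s): "
            f"{list(degenerate[:5])}{'...' if len(degenerate) > 5 else ''}",
            stacklevel=2,
        )
        mean = mean.drop(degenerate)
        sd = sd.drop(degenerate)
    model = ScalingModel(mean=mean, sd=sd)
    return model.apply(matrix), model


@dataclass
class QcReport:
    """Per-feature QC coefficients of variation (percent) and pass flags."""

    intra_day_cv: pd.Series
    inter_day_cv: pd.Series
    threshold: float
    passed: pd.Series

    def summary(self) -> dict:
        return {
            "threshold_percent": self.threshold,
            "n_features": int(len(self.passed)),
            "n_passed": int(self.passed.sum()),
            "median_intra_cv": float(self.intra_day_cv.median()),
            "median_inter_cv": float(self.inter_day_cv.median()),
        }


def qc_cv(
    matrix: pd.DataFrame,
    qc_sample_ids,
    batch_labels: pd.Series | None = None,
    threshold: float = 30.0,
) -> QcReport:
    """CV = 100 * sd / mean per feature over QC injections.

    Intra-day CV pools the per-batch CVs (mean over batches with >= 2 QC
    samples); inter-day CV is taken over all QC samples.  A feature passes
    when both CVs are strictly below ``threshold`` (a CV exactly at the
    threshold fails).
    """
    qc = matrix.loc[list(qc_sample_ids)]
    if len(qc) < 2:
        raise ValueError(f"need >= 2 QC samples, got {len(qc)}")

    def _cv(frame: pd.DataFrame) -> pd.Series:
        return 100.0 * frame.std(axis=0, ddof=1) / frame.mean(axis=0)

    inter = _cv(qc)
    if batch_labels is not None:
        batches = pd.Series(batch_labels).loc[qc.index]
        per_batch = [
            _cv(qc.loc[idx]) for _, idx in batches.groupby(batches).groups.items()
            if len(idx) >= 2
        ]
        if not per_batch:
            raise ValueError("no batch holds >= 2 QC samples; cannot compute intra-day CV")
        intra = pd.concat(per_batch, axis=1).mean(axis=1)
    else:
        intra = inter.copy()
    passed = (intra < threshold) & (inter < threshold)
    return QcReport(intra_day_cv=intra, inter_day_cv=inter, threshold=threshold, passed=passed)
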