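"""Feature-subset validation, permutation testing, shared-feature analysis.

Ranked-feature subsets are validated by refitting the grouped OPLS-DA
cross-validation on prefixes of the ranking and choosing the smallest
subset whose RMSECV is within one standard error of the minimum.
Significance of a discrimination model is assessed by permuting class
labels at the individual level (all replicates of an individual move
together — permuting within replicate groups would leave the class
structure intact) and recomputing the full cross-validated statistic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .oplsda import (
    cross_validate,
    decision_threshold,
    evaluate_predictions,
    partition_folds,
)


@dataclass
class SubsetValidationResult:
    sizes: list
    rmsecv: dict                      # size -> RMSECV
    r2cv: dict
    accuracy: dict
    chosen_size: int
    chosen_features: list


def _cv_statistics(X, y, samples, k, component_grid, seed):
    part = partition_folds(samples, k=k, seed=seed)
    cv = cross_validate(X, y, part, component_grid)
    thr = decision_threshold(cv.y_cv, y)
    metrics = evaluate_predictions(cv.y_cv, y, thr.threshold)
    # per-fold RMSE spread, for the 1-SE rule
    fold_rmse = [
        float(np.sqrt(np.mean((y[f] - cv.y_cv[f]) ** 2))) for f in part.folds
    ]
    se = float(np.std(fold_rmse, ddof=1) / np.sqrt(len(fold_rmse)))
    return cv, metrics, se


def validate_feature_subsets(
    X: pd.DataFrame,
    y,
    samples: pd.DataFrame,
    ranking,
    sizes,
    k: int = 5,
    component_grid=(1, 2, 3),
    seed: int = 0,
) -> SubsetValidationResult:
    """Grouped-CV performance of top-m ranked feature prefixes.

    The chosen size is the smallest m with RMSECV <= min RMSECV + 1 SE
    (standard error of the per-fold RMSE at the minimiser).
    """
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes:
        raise ValueError("size grid is empty")
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    ranking = list(ranking)
    if max(sizes) > len(ranking):
        raise ValueError("size grid exceeds the number of ranked features")
    if isinstance(ranking[0], (int, np.integer)):
        ranked_cols = [X.columns[i] for i in ranking]
    else:
        ranked_cols = list(ranking)
    rmsecv, r2cv, accuracy, ses = {}, {}, {}, {}
    for m in sizes:
        cv, metrics, se = _cv_statistics(
            X[ranked_cols[:m]], y, samples, k, component_grid, seed
        )
        rmsecv[m], r2cv[m], accuracy[m], ses[m] = cv.rmsecv, cv.r2cv, metrics.accuracy, se
    best = min(sizes, key=lambda m: rmsecv[m])
    limit = rmsecv[best] + ses[best]
    chosen = min(m for m in sizes if rmsecv[m] <= limit)
    chosen_features = ranked_cols[:chosen]
    return SubsetValidationResult(
        sizes=sizes, rmsecv=rmsecv, r2cv=r2cv, accuracy=accuracy,
        chosen_size=chosen, chosen_features=list(chosen_features),
    )


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p_value: float

    def __post_init__(self) -> None:
        assert 0.0 < self.p_value <= 1.0


def permutation_test(
    X: pd.DataFrame,
    y,
    samples: pd.DataFrame,
    B: int = 999,
    statistic: str = "accuracy",
    k: int = 5,
    component_grid=(1, 2),
    seed: int = 0,
) -> PermutationResult:
    """Individual-level label-permutation test of the CV discrimination.

    Class labels are permuted across individuals (replicates inherit their
    individual's permuted label); the full pipeline — fold partition,
    cross-validation, threshold refit, statistic — is recomputed per
    permutation.  p = (1 + #{perm >= observed}) / (B + 1).
    """
    if B < 19:
        raise ValueError(f"B must be >= 19, got {B}")
    if statistic not in ("accuracy", "r2cv"):
        raise ValueError(f"unknown statistic {statistic!r}")
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    samples = samples.reset_index(drop=False)

    def stat_for(y_curr, seed_curr):
        cv, metrics, _ = _cv_statistics(X, y_curr, samples, k, component_grid, seed_curr)
        return metrics.accuracy if statistic == "accuracy" else cv.r2cv

    observed = stat_for(y, seed)

    individuals = samples["individual_id"].drop_duplicates().to_numpy()
    ind_label = {
        ind: y[samples["individual_id"].to_numpy() == ind][0] for ind in individuals
    }
    labels_vec = np.array([ind_label[i] for i in individuals])
    master = np.random.SeedSequence(seed)
    permuted = np.empty(B)
    for b, child in enumerate(master.spawn(B)):
        rng = np.random.default_rng(child)
        shuffled = rng.permutation(labels_vec)
        mapping = dict(zip(individuals, shuffled))
        y_perm = np.array([mapping[i] for i in samples["individual_id"]])
        permuted[b] = stat_for(y_perm, int(rng.integers(2**31 - 1)))
    p = (1.0 + np.sum(permuted >= observed)) / (B + 1.0)
    return PermutationResult(observed=observed, permuted=permuted, p_value=float(p))


_MARKUP = re.compile(r"[*#^]|\s+$|^\s+")


def canonical_label(label: str) -> str:
    """Strip typographic markup (bold/hash/superscript) from a feature label."""
    out = re.sub(r"[*#^]", "", str(label))
    return re.sub(r"\s+", " ", out).strip()


def shared_features(list_a, list_b) -> list:
    """Canonical-label intersection of two validated-feature lists.

    Assignment-suffix letters (chromatographic variants, e.g. "LPC 16:0 A3")
    are retained: two variants of the same lipid are distinct features.
    """
    a = {canonical_label(x) for x in list_a}
    b = {canonical_label(x) for x in list_b}
    return sorted(a & b)
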