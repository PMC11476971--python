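"""Replicate-aware stability feature ranking.

Two ranking filters are provided.  The F-ratio ranks features by the
one-way ANOVA F statistic with (g-1, n-g) degrees of freedom and a
parametric critical value.  Random-Forest importance ranks by Mean
Decrease Gini (split-impurity reduction) or Mean Decrease Accuracy
(out-of-bag permutation loss).

Because every individual contributes replicate injections, a plain
bootstrap over samples lets some individuals contribute more replicates
than others.  The stability procedure therefore draws, before each forest,
exactly one randomly chosen replicate per individual, fits the forest,
records the importance ranking, and repeats B times; the B ranking lists
are summarised by rank-segment frequency counts and aggregated with the
Borda count (equivalent to ordering by average rank).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier


# --------------------------------------------------------------------------
# F-ratio filter
# --------------------------------------------------------------------------

@dataclass
class FRatioResult:
    f: np.ndarray
    df_num: int
    df_den: int
    alpha: float
    critical_value: float
    selected: np.ndarray

    @property
    def ranking(self) -> np.ndarray:
        return np.argsort(-self.f, kind="stable")


def fisher_ratio(X, labels, alpha: float = 0.05) -> FRatioResult:
    """Per-feature one-way ANOVA F statistic with a parametric threshold.

    F = (between-class sum of squares / (g-1)) / (within-class SS / (n-g)).
    A feature is selected when F exceeds the upper-alpha F quantile.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, inverse = np.unique(labels, return_inverse=True)
    g = len(classes)
    n = len(labels)
    if g < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(inverse)
    if counts.min() < 2:
        small = classes[np.argmin(counts)]
        raise ValueError(f"class {small!r} has fewer than 2 samples")

    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for c in range(g):
        Xc = X[inverse == c]
        mc = Xc.mean(axis=0)
        ss_between += len(Xc) * (mc - grand) ** 2
        ss_within += ((Xc - mc) ** 2).sum(axis=0)
    df_num, df_den = g - 1, n - g
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_num) / (ss_within / df_den)
    f = np.where(np.isfinite(f), f, 0.0)
    crit = float(stats.f.ppf(1 - alpha, df_num, df_den))
    return FRatioResult(
        f=f, df_num=df_num, df_den=df_den, alpha=alpha,
        critical_value=crit, selected=f > crit,
    )


# --------------------------------------------------------------------------
# Random-Forest importance (hand-rolled bagging for OOB control)
# --------------------------------------------------------------------------

@dataclass
class ImportanceTable:
    mean_decrease_gini: np.ndarray
    mean_decrease_accuracy: np.ndarray | None = None
    p_value: np.ndarray | None = None

    def ranking(self, metric: str = "gini") -> np.ndarray:
        if metric == "gini":
            values = self.mean_decrease_gini
        elif metric == "accuracy":
            if self.mean_decrease_accuracy is None:
                raise ValueError("mean decrease accuracy was not computed")
            values = self.mean_decrease_accuracy
        else:
            raise ValueError(f"unknown metric {metric!r}")
        return np.argsort(-values, kind="stable")


def _tree_impurity_importance(tree: DecisionTreeClassifier, p: int) -> np.ndarray:
    """Unnormalised mean decrease in Gini impurity, per sample at the root."""
    t = tree.tree_
    imp = np.zeros(p)
    w = t.weighted_n_node_samples
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            continue
        decrease = w[node] * t.impurity[node] - w[left] * t.impurity[left] - w[right] * t.impurity[right]
        imp[t.feature[node]] += decrease
    return imp / w[0]


def rf_importance(
    X,
    labels,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int = 0,
    compute_mda: bool = True,
) -> ImportanceTable:
    """Bagged-tree (Random Forest) variable importance.

    Each tree is grown on a bootstrap sample with ``mtry`` features tried
    per split (default floor(sqrt(p))); the ~1/3 of samples left out of a
    tree's bootstrap form its out-of-bag set.  Mean Decrease Gini averages
    impurity reduction over trees; Mean Decrease Accuracy is the drop in
    out-of-bag accuracy when a feature is permuted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    n, p = X.shape
    mtry = mtry or max(1, int(np.sqrt(p)))
    rng = np.random.default_rng(seed)

    gini = np.zeros(p)
    mda_sum = np.zeros(p)
    mda_count = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features=mtry, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        gini += _tree_impurity_importance(tree, p)
        if compute_mda and len(oob):
            X_oob, y_oob = X[oob], y[oob]
            base = np.mean(tree.predict(X_oob) == y_oob)
            for j in range(p):
                perm = rng.permutation(len(oob))
                Xp = X_oob.copy()
                Xp[:, j] = X_oob[perm, j]
                acc = np.mean(tree.predict(Xp) == y_oob)
                mda_sum[j] += base - acc
                mda_count[j] += 1
    gini /= n_trees
    mda = None
    if compute_mda:
        with np.errstate(invalid="ignore"):
            mda = np.where(mda_count > 0, mda_sum / np.maximum(mda_count, 1), 0.0)
    return ImportanceTable(mean_decrease_gini=gini, mean_decrease_accuracy=mda)


# --------------------------------------------------------------------------
# Replicate-aware sub-sampling and the stability ensemble
# --------------------------------------------------------------------------

def replicate_subsample(samples: pd.DataFrame, seed_or_rng=0) -> np.ndarray:
    """Positional indices picking one random replicate per individual.

    Every draw contains every individual exactly once, so the class make-up
    is constant across draws while the technical replicates vary.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    positions = []
    pos = pd.Series(np.arange(len(samples)), index=samples.index)
    for _, group in pos.groupby(samples["individual_id"].to_numpy(), sort=True):
        positions.append(group.iloc[rng.integers(len(group))])
    return np.asarray(sorted(positions))


def assert_permutation(lst: np.ndarray, p: int) -> None:
    if sorted(lst) != list(range(p)):
        raise ValueError("ranking list is not a permutation of 0..p-1")


@dataclass
class StabilityResult:
    B: int
    lists: np.ndarray                 # B x p, feature indices best-first
    segments: tuple
    segment_counts: pd.DataFrame      # features x segments
    borda_scores: np.ndarray
    mean_rank: np.ndarray
    aggregate: np.ndarray             # feature indices best-first


def segment_counts(lists: np.ndarray, segments=((1, 5), (6, 10), (11, 15))) -> pd.DataFrame:
    """How often each feature lands in each 1-based rank segment.

    Segments are inclusive position ranges (e.g. (1, 5) = the first five
    ranking positions) and must not overlap.
    """
    lists = np.atleast_2d(np.asarray(lists))
    B, p = lists.shape
    spans = sorted(segments)
    for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
        if hi1 >= lo2:
            raise ValueError(f"overlapping segments {(lo1, hi1)} and {(lo2, hi2)}")
    for lst in lists:
        assert_permutation(lst, p)
    ranks = np.empty_like(lists)
    rows = np.arange(B)[:, None]
    ranks[rows, lists] = np.arange(1, p + 1)
    counts = {}
    for lo, hi in segments:
        counts[f"rank_{lo}_{hi}"] = ((ranks >= lo) & (ranks <= hi)).sum(axis=0)
    return pd.DataFrame(counts)


def borda_aggregate(lists: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Borda scores, mean ranks, and the aggregated ranking.

    A feature's Borda score sums, over lists, the number of features ranked
    below it; the aggregate orders by descending score with ties broken by
    ascending mean rank, then feature index.  Ordering by Borda score is
    equivalent to ordering by average rank.
    """
    lists = np.atleast_2d(np.asarray(lists))
    B, p = lists.shape
    for lst in lists:
        assert_permutation(lst, p)
    ranks = np.empty_like(lists)
    rows = np.arange(B)[:, None]
    ranks[rows, lists] = np.arange(1, p + 1)
    borda = (p - ranks).sum(axis=0)
    mean_rank = ranks.mean(axis=0)
    order = np.lexsort((np.arange(p), mean_rank, -borda))
    return borda, mean_rank, order


def stability_ranking(
    X,
    labels,
    samples: pd.DataFrame,
    B: int = 1000,
    n_trees: int = 100,
    mtry: int | None = None,
    segments=((1, 5), (6, 10), (11, 15)),
    metric: str = "gini",
    seed: int = 0,
) -> StabilityResult:
    """B replicate-subsampled forests -> B ranking lists -> Borda aggregate."""
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    p = X.shape[1]
    master = np.random.SeedSequence(seed)
    lists = np.empty((B, p), dtype=int)
    for b, child in enumerate(master.spawn(B)):
        rng = np.random.default_rng(child)
        idx = replicate_subsample(samples, rng)
        imp = rf_importance(
            X[idx], y[idx], n_trees=n_trees, mtry=mtry,
            seed=int(rng.integers(2**31 - 1)),
            compute_mda=(metric == "accuracy"),
        )
        lists[b] = imp.ranking(metric)
    counts = segment_counts(lists, segments)
    borda, mean_rank, aggregate = borda_aggregate(lists)
    return StabilityResult(
        B=B, lists=lists, segments=tuple(segments), segment_counts=counts,
        borda_scores=borda, mean_rank=mean_rank, aggregate=aggregate,
    )


# --------------------------------------------------------------------------
# Corrected-importance p-values and the significant-count interval
# --------------------------------------------------------------------------

def corrected_importance_pvalues(
    X,
    labels,
    samples: pd.DataFrame | None = None,
    n_classifiers: int = 1000,
    n_trees: int = 100,
    mtry: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed corrected Gini importance with label-permutation p-values.

    Each of ``n_classifiers`` rounds fits three forests on the (optionally
    replicate-subsampled) data: one on the real labels, one on a fresh
    per-round label permutation (the baseline that removes the structural
    positive bias of impurity importance), and one on a single *fixed*
    label permutation drawn once up front (the null channel).  The
    corrected importance of a feature is its ensemble-mean real-minus-
    baseline importance; the null pool collects the same statistic for the
    fixed-permutation channel, which is distributionally identical to the
    real channel when labels carry no information — in particular it keeps
    the dataset-level chance association a fixed label vector accumulates
    across the ensemble, so the resulting p-values are calibrated.
    p_j = (1 + #{null >= corrected_j}) / (n_null + 1).

    Returns (corrected_importance, p_values).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    master = np.random.SeedSequence(seed)
    p = X.shape[1]
    rng0 = np.random.default_rng(master.spawn(1)[0])
    y_fixed = rng0.permutation(y)  # the frozen null-channel labels
    corrected = np.zeros(p)
    null_channel = np.zeros(p)
    for child in master.spawn(n_classifiers):
        rng = np.random.default_rng(child)
        if samples is not None:
            idx = replicate_subsample(samples, rng)
        else:
            idx = np.arange(len(y))
        Xb = X[idx]
        real = rf_importance(
            Xb, y[idx], n_trees=n_trees, mtry=mtry,
            seed=int(rng.integers(2**31 - 1)), compute_mda=False,
        ).mean_decrease_gini
        baseline = rf_importance(
            Xb, rng.permutation(y[idx]), n_trees=n_trees, mtry=mtry,
            seed=int(rng.integers(2**31 - 1)), compute_mda=False,
        ).mean_decrease_gini
        fixed = rf_importance(
            Xb, y_fixed[idx], n_trees=n_trees, mtry=mtry,
            seed=int(rng.integers(2**31 - 1)), compute_mda=False,
        ).mean_decrease_gini
        corrected += real - baseline
        null_channel += fixed - baseline
    corrected /= n_classifiers
    null_channel /= n_classifiers
    pvals = (1.0 + (null_channel[None, :] >= corrected[:, None]).sum(axis=1)) / (
        len(null_channel) + 1.0
    )
    return corrected, pvals


def significance_threshold_count(pvalue_lists, alpha: float = 0.05):
    """Mean +/- sd of the per-ensemble-member count of significant features.

    Returns (mean, sd, (mean - sd, mean + sd)).
    """
    pvalue_lists = [np.asarray(pv) for pv in pvalue_lists]
    if len(pvalue_lists) < 2:
        raise ValueError("need >= 2 ensemble members")
    counts = np.array([(pv < alpha).sum() for pv in pvalue_lists], dtype=float)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    return mean, sd, (mean - sd, mean + sd)
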