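"""OPLS-DA: orthogonal PLS discriminant analysis for a binary class code.

The class membership is coded 0/1 (control = 0, case = 1) and regressed
on the autoscaled feature matrix.  A single predictive latent variable
carries all class-correlated variation; the remaining ``n_components - 1``
latent variables are orthogonal to the class code and absorb structured
but class-irrelevant variation.  With no orthogonal components the model
is exactly single-component PLS1.

Model assessment follows the replicate-preserving scheme: samples are
partitioned into k folds that never split a triplicate group; each fold in
turn is the prediction set while the remaining folds form the calibration
set, inside which leave-one-group-out cross-validation produces RMSECV and
R2cv and selects the component count.  Discrimination thresholds are the
equal-posterior point of per-class Gaussian fits to the cross-validated
predictions; the thresholds of the two complementary 0/1 codings sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .preprocess import ScalingModel, autoscale


# --------------------------------------------------------------------------
# replicate-preserving fold partition
# --------------------------------------------------------------------------

@dataclass
class FoldPartition:
    folds: list                       # list of np.ndarray of positional indices
    groups: pd.Series                 # positional index -> replicate-group id

    def validate(self) -> None:
        all_idx = np.concatenate(self.folds)
        n = len(self.groups)
        if sorted(all_idx) != list(range(n)):
            raise ValueError("folds must partition all samples")
        for i, fold in enumerate(self.folds):
            fold_groups = set(self.groups.iloc[fold])
            for j, other in enumerate(self.folds):
                if i >= j:
                    continue
                if fold_groups & set(self.groups.iloc[other]):
                    raise ValueError(f"replicate group split across folds {i} and {j}")


def partition_folds(
    samples: pd.DataFrame, k: int = 5, seed: int = 0, stratify_by_class: bool = True
) -> FoldPartition:
    """k disjoint folds of approximately even size; replicate groups intact.

    Groups (individuals) are shuffled within each class and dealt
    round-robin over a shuffled fold order, so per-fold class proportions
    stay within a couple of groups of the overall proportions.
    """
    rng = np.random.default_rng(seed)
    groups = samples["individual_id"]
    unique_groups = groups.drop_duplicates()
    if k > len(unique_groups):
        raise ValueError(f"k={k} exceeds the {len(unique_groups)} replicate groups")
    group_sizes = groups.value_counts()
    fold_members: list[list] = [[] for _ in range(k)]
    fold_sizes = np.zeros(k)
    fold_class_counts = {}
    strata = (
        samples.drop_duplicates("individual_id").groupby("class_label")["individual_id"]
        if stratify_by_class
        else [("all", unique_groups)]
    )
    for cls, grp_ids in strata:
        ids = list(grp_ids)
        rng.shuffle(ids)
        counts = fold_class_counts.setdefault(cls, np.zeros(k))
        for gid in ids:
            # fewest groups of this class first, then smallest fold, random tie-break
            key = counts * 1e6 + fold_sizes + rng.random(k) * 1e-3
            target = int(np.argmin(key))
            fold_members[target].append(gid)
            fold_sizes[target] += group_sizes[gid]
            counts[target] += 1
    pos = np.arange(len(samples))
    folds = []
    for members in fold_members:
        mask = groups.isin(members).to_numpy()
        folds.append(pos[mask])
    part = FoldPartition(folds=folds, groups=groups.reset_index(drop=True))
    part.validate()
    return part


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

@dataclass
class OplsdaModel:
    w: np.ndarray                     # predictive weights, unit norm
    p_load: np.ndarray                # predictive loadings (the LV1 loadings)
    q: float                          # y-loading
    t: np.ndarray                     # predictive scores (training)
    W_o: np.ndarray                   # p x n_orth orthogonal weights
    P_o: np.ndarray                   # p x n_orth orthogonal loadings
    T_o: np.ndarray                   # n x n_orth orthogonal scores (training)
    n_orth: int
    y_mean: float
    class_coding: dict = field(default_factory=lambda: {"C": 0.0, "SCH": 1.0})
    scaling: ScalingModel | None = None

    @property
    def n_components(self) -> int:
        return 1 + self.n_orth

    def transform(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Return (predictive scores, orthogonal scores) for new data."""
        X = np.array(X, dtype=float, copy=True)
        T_o = np.zeros((len(X), self.n_orth))
        for a in range(self.n_orth):
            t_o = X @ self.W_o[:, a]
            X -= np.outer(t_o, self.P_o[:, a])
            T_o[:, a] = t_o
        return X @ self.w, T_o

    def predict(self, X) -> np.ndarray:
        t, _ = self.transform(X)
        return self.y_mean + t * self.q

    def regression_coefficients(self) -> np.ndarray:
        """Coefficients b with yhat = y_mean + X_filtered @ b for filtered X."""
        return self.w * self.q


def fit_oplsda(X, y_coded, n_components: int = 1) -> OplsdaModel:
    """Fit 1 predictive + (n_components - 1) orthogonal latent variables.

    ``X`` must already be column-centred/scaled; ``y_coded`` is the 0/1
    class code.  Orthogonal score columns have exactly zero covariance with
    the class code by construction.
    """
    X = np.array(X, dtype=float, copy=True)
    y = np.asarray(y_coded, dtype=float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if np.ptp(y) == 0:
        raise ValueError("class code is constant; no between-class variation to model")
    rank = np.linalg.matrix_rank(X)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank(X)={rank}")
    y_mean = float(y.mean())
    y_c = y - y_mean

    w = X.T @ y_c
    w /= np.linalg.norm(w)

    n_orth = n_components - 1
    W_o = np.zeros((X.shape[1], n_orth))
    P_o = np.zeros((X.shape[1], n_orth))
    T_o = np.zeros((len(X), n_orth))
    for a in range(n_orth):
        t = X @ w
        p = X.T @ t / (t @ t)
        p_orth = p - (w @ p) * w
        norm = np.linalg.norm(p_orth)
        if norm < 1e-12:
            raise ValueError(
                f"no orthogonal variation left after {a} orthogonal component(s)"
            )
        w_o = p_orth / norm
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X -= np.outer(t_o, p_o)
        W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o

    t = X @ w
    p_load = X.T @ t / (t @ t)
    q = float(y_c @ t / (t @ t))
    return OplsdaModel(
        w=w, p_load=p_load, q=q, t=t, W_o=W_o, P_o=P_o, T_o=T_o,
        n_orth=n_orth, y_mean=y_mean,
    )


# --------------------------------------------------------------------------
# cross-validation and evaluation
# --------------------------------------------------------------------------

@dataclass
class CvResult:
    y_cv: np.ndarray
    rmsecv: float
    r2cv: float
    n_components: int
    grid: dict                        # n_comp -> (rmsecv, r2cv)


def _rmse(y, yhat) -> float:
    return float(np.sqrt(np.mean((np.asarray(y) - np.asarray(yhat)) ** 2)))


def _r2(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    partition: FoldPartition,
    component_grid=(1, 2, 3, 4),
    scale: bool = True,
) -> CvResult:
    """Grouped cross-validation over a component grid.

    For every grid point, each fold is predicted by a model trained (and
    scaled) on the remaining folds; the chosen component count minimises
    RMSECV.  RMSECV and R2cv are inversely ordered by construction
    (both are functions of the same residual sum of squares).
    """
    component_grid = list(component_grid)
    if not component_grid:
        raise ValueError("component grid is empty")
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    for fold in partition.folds:
        train = np.setdiff1d(np.arange(len(y)), fold)
        if np.ptp(y[train]) == 0:
            raise ValueError("a training split contains a single class")
    grid_results = {}
    y_cv_by_comp = {}
    for n_comp in component_grid:
        y_cv = np.empty_like(y)
        for fold in partition.folds:
            train = np.setdiff1d(np.arange(len(y)), fold)
            X_tr = X.iloc[train]
            if scale:
                X_tr_s, scaler = autoscale(X_tr)
                X_te_s = scaler.apply(X.iloc[fold])
            else:
                X_tr_s, X_te_s = X_tr, X.iloc[fold]
            model = fit_oplsda(X_tr_s.to_numpy(), y[train], n_comp)
            y_cv[fold] = model.predict(X_te_s.to_numpy())
        grid_results[n_comp] = (_rmse(y, y_cv), _r2(y, y_cv))
        y_cv_by_comp[n_comp] = y_cv
    best = min(grid_results, key=lambda c: grid_results[c][0])
    rmsecv, r2cv = grid_results[best]
    return CvResult(
        y_cv=y_cv_by_comp[best], rmsecv=rmsecv, r2cv=r2cv,
        n_components=best, grid=grid_results,
    )


@dataclass
class ThresholdPair:
    threshold: float                  # for the supplied 0/1 coding
    complement: float                 # for the flipped coding

    def __post_init__(self) -> None:
        if abs(self.threshold + self.complement - 1.0) > 1e-9:
            raise ValueError("complementary thresholds must sum to 1")


def decision_threshold(y_cv, labels_coded) -> ThresholdPair:
    """Equal-posterior point of per-class Gaussian fits to the predictions.

    With equal priors the threshold solves f0(x) = f1(x) for the two class
    densities; equal variances give the midpoint of the class means, and a
    tighter class pulls the threshold toward itself.  Degenerate classes
    (fewer than 2 samples or zero variance) fall back to the midpoint of
    the class means, or 0.5 with a warning.
    """
    y_cv = np.asarray(y_cv, dtype=float)
    lab = np.asarray(labels_coded, dtype=float)
    if len(np.unique(lab)) != 2:
        raise ValueError("both classes must be present")
    y0, y1 = y_cv[lab == 0], y_cv[lab == 1]
    if len(y0) < 2 or len(y1) < 2:
        warnings.warn("a class has fewer than 2 samples; threshold falls back to 0.5",
                      stacklevel=2)
        return ThresholdPair(0.5, 0.5)
    m0, s0 = y0.mean(), y0.std(ddof=1)
    m1, s1 = y1.mean(), y1.std(ddof=1)
    lo, hi = (m0, m1) if m0 < m1 else (m1, m0)
    if s0 < 1e-12 or s1 < 1e-12 or abs(s0 - s1) < 1e-12:
        thr = 0.5 * (m0 + m1)
    else:
        # equal-density point: quadratic a x^2 + b x + c = 0
        a = 1.0 / s1**2 - 1.0 / s0**2
        b = -2.0 * (m1 / s1**2 - m0 / s0**2)
        c = m1**2 / s1**2 - m0**2 / s0**2 + 2.0 * np.log(s1 / s0)
        roots = np.roots([a, b, c])
        roots = roots[np.isreal(roots)].real
        inside = roots[(roots > lo) & (roots < hi)]
        if len(inside):
            thr = float(inside[0])
        elif len(roots):
            thr = float(roots[np.argmin(np.abs(roots - 0.5 * (m0 + m1)))])
        else:
            thr = 0.5 * (m0 + m1)
    return ThresholdPair(float(thr), float(1.0 - thr))


@dataclass
class EvalMetrics:
    rmsep: float
    r2p: float
    accuracy: float
    misclassification_rate: float
    confusion: np.ndarray             # rows true 0/1, cols predicted 0/1

    def __post_init__(self) -> None:
        assert abs(self.accuracy + self.misclassification_rate - 1.0) < 1e-9


def evaluate_predictions(y_pred, y_true, threshold: float) -> EvalMetrics:
    """Threshold continuous predictions and tabulate classification metrics."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty test set")
    pred_class = (y_pred > threshold).astype(int)
    true_class = (y_true > 0.5).astype(int)
    confusion = np.zeros((2, 2), dtype=int)
    for t, pr in zip(true_class, pred_class):
        confusion[t, pr] += 1
    acc = float(np.mean(pred_class == true_class))
    return EvalMetrics(
        rmsep=_rmse(y_true, y_pred),
        r2p=_r2(y_true, y_pred),
        accuracy=acc,
        misclassification_rate=1.0 - acc,
        confusion=confusion,
    )


def evaluate(model: OplsdaModel, threshold: float, X_test, y_test) -> EvalMetrics:
    X_test = np.asarray(X_test, dtype=float)
    if model.scaling is not None:
        X_test = (
            model.scaling.apply(pd.DataFrame(X_test, columns=model.scaling.mean.index))
            .to_numpy()
        )
    return evaluate_predictions(model.predict(X_test), y_test, threshold)


# --------------------------------------------------------------------------
# VIP
# --------------------------------------------------------------------------

@dataclass
class VipVector:
    vip: np.ndarray
    selected: np.ndarray

    def __post_init__(self) -> None:
        msq = float(np.mean(self.vip**2))
        if abs(msq - 1.0) > 1e-8:
            raise ValueError(f"mean squared VIP must be 1, got {msq}")


def vip_scores(model: OplsdaModel) -> VipVector:
    """Variable importance in projection over all model components.

    VIP_j = sqrt(p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a), where
    SSY_a is the class-code variation explained by component a.  Orthogonal
    components explain none by construction, so the predictive weights
    dominate; the mean of squared VIPs is exactly 1, making VIP > 1 the
    natural above-average-contribution cutoff.
    """
    p = len(model.w)
    weights = [model.w] + [model.W_o[:, a] for a in range(model.n_orth)]
    t_cols = [model.t] + [model.T_o[:, a] for a in range(model.n_orth)]
    # SSY per component: class-code variation explained (zero for orthogonal)
    y_c_hat_ss = []
    for t_a in t_cols:
        q_a = model.q if t_a is model.t else 0.0
        y_c_hat_ss.append((q_a**2) * float(t_a @ t_a))
    ssy = np.asarray(y_c_hat_ss)
    total = ssy.sum()
    acc = np.zeros(p)
    for w_a, ssy_a in zip(weights, ssy):
        acc += ssy_a * (w_a / np.linalg.norm(w_a)) ** 2
    vip = np.sqrt(p * acc / total)
    return VipVector(vip=vip, selected=vip > 1.0)
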