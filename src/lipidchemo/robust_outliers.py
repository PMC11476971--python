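"""Robust-PCA outlier map and classical PCA exploration.

The outlier screen follows the ROBPCA recipe: reduce to the affine span
of the data by SVD, measure each sample's Stahel-Donoho outlyingness over
random directions through data-point pairs, fit classical PCA to the h
least outlying samples, then reweight once using orthogonal distances.
Each sample gets a score distance (robust Mahalanobis distance inside the
PCA subspace) and an orthogonal distance (Euclidean distance to the
subspace); the two cutoffs partition samples into regular, good-leverage,
orthogonal-outlier and bad-leverage categories.

``classical_pca`` adds scree/RMSECV diagnostics, where RMSECV is computed
element-wise: each held-out entry is reconstructed from the remaining
features of its (held-out) row under the training-fold model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FeatureTable

CATEGORIES = ("regular", "good_leverage", "orthogonal_outlier", "bad_leverage")
REMOVAL_POLICIES = ("categorical", "distinctive", "none")


@dataclass
class RobustPcaModel:
    center: np.ndarray
    loadings: np.ndarray          # p x k, orthonormal columns
    eigenvalues: np.ndarray       # k, positive, descending
    k: int

    def __post_init__(self) -> None:
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("loadings are not orthonormal")
        if np.any(self.eigenvalues <= 0) or np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be positive and non-increasing")

    def scores(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.center) @ self.loadings


@dataclass
class OutlierMap:
    sample_ids: list
    sd: np.ndarray
    od: np.ndarray
    sd_cutoff: float
    od_cutoff: float
    category: np.ndarray  # array of str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"SD": self.sd, "OD": self.od, "category": self.category},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    @property
    def flagged(self) -> list:
        mask = np.isin(self.category, ("orthogonal_outlier", "bad_leverage"))
        return [s for s, m in zip(self.sample_ids, mask) if m]


def _stahel_donoho_outlyingness(Z: np.ndarray, n_directions: int, rng) -> np.ndarray:
    """Max over random directions of |projection - median| / MAD."""
    n = Z.shape[0]
    outl = np.zeros(n)
    n_found = 0
    attempts = 0
    while n_found < n_directions and attempts < 10 * n_directions:
        attempts += 1
        i, j = rng.choice(n, size=2, replace=False)
        d = Z[i] - Z[j]
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        d /= norm
        proj = Z @ d
        med = np.median(proj)
        mad = np.median(np.abs(proj - med)) * 1.4826
        if mad < 1e-12:
            continue
        outl = np.maximum(outl, np.abs(proj - med) / mad)
        n_found += 1
    return outl


def _pca_of(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    Xc = X - center
    cov = Xc.T @ Xc / (len(X) - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    return center, vecs[:, order], vals[order]


def _orthogonal_distances(X, center, loadings) -> np.ndarray:
    Xc = np.asarray(X) - center
    resid = Xc - (Xc @ loadings) @ loadings.T
    return np.linalg.norm(resid, axis=1)


def _wilson_hilferty_cutoff(od: np.ndarray, quantile: float = 0.975) -> float:
    """Cutoff for orthogonal distances: OD^(2/3) is treated as normal with
    robust location/scale (median, scaled MAD)."""
    g = od ** (2.0 / 3.0)
    med = np.median(g)
    mad = np.median(np.abs(g - med)) * 1.4826
    z = stats.norm.ppf(quantile)
    return float(max(med + mad * z, 0.0) ** 1.5)


def fit_robust_pca(
    X,
    k: int,
    h_fraction: float = 0.75,
    n_directions: int = 250,
    seed: int = 0,
) -> RobustPcaModel:
    """Fit a robust k-component PCA model resistant to gross row corruption."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (0.5 < h_fraction <= 1.0):
        raise ValueError(f"h_fraction must lie in (0.5, 1], got {h_fraction}")
    if k < 1 or n <= k:
        raise ValueError(f"need rows > k >= 1, got n={n}, k={k}")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if k > rank:
        raise ValueError(f"k={k} exceeds data rank {rank}")

    rng = np.random.default_rng(seed)

    # step 1: reduce to the affine span of the data
    mean0 = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean0, full_matrices=False)
    keep = s > max(s) * 1e-12
    V = Vt[keep].T                      # p x r
    Z = (X - mean0) @ V                 # n x r

    # step 2: projection-pursuit outlyingness, keep h least outlying rows
    outl = _stahel_donoho_outlyingness(Z, n_directions, rng)
    h = int(np.ceil(h_fraction * n))
    core = np.argsort(outl)[:h]

    center_z, load_z, eig_z = _pca_of(Z[core], k)

    # step 3: one reweighting step based on orthogonal distances
    od = _orthogonal_distances(Z, center_z, load_z)
    cutoff = _wilson_hilferty_cutoff(od)
    keep_rows = od <= cutoff if cutoff > 0 else np.ones(len(Z), bool)
    if keep_rows.sum() > k + 1:
        center_z, load_z, eig_z = _pca_of(Z[keep_rows], k)

    eig_z = np.maximum(eig_z, 1e-12)
    return RobustPcaModel(
        center=mean0 + V @ center_z,
        loadings=V @ load_z,
        eigenvalues=eig_z,
        k=k,
    )


def outlier_map(model: RobustPcaModel, X, sample_ids=None, quantile: float = 0.975) -> OutlierMap:
    """Score distance / orthogonal distance diagnostics for every sample."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.loadings.shape[0]:
        raise ValueError("feature count does not match the model")
    if sample_ids is None:
        sample_ids = list(range(len(X)))
    t = model.scores(X)
    sd = np.sqrt(np.sum(t**2 / model.eigenvalues, axis=1))
    od = _orthogonal_distances(X, model.center, model.loadings)
    sd_cutoff = float(np.sqrt(stats.chi2.ppf(quantile, df=model.k)))
    od_cutoff = _wilson_hilferty_cutoff(od, quantile)
    high_sd = sd > sd_cutoff
    high_od = od > od_cutoff
    category = np.where(
        high_sd & high_od, "bad_leverage",
        np.where(high_od, "orthogonal_outlier",
                 np.where(high_sd, "good_leverage", "regular")),
    )
    return OutlierMap(list(sample_ids), sd, od, sd_cutoff, od_cutoff, category)


def _distinctive_ids(omap: OutlierMap) -> list:
    """OD-outliers separated from the bulk by the largest gap above the cutoff.

    Mirrors how an analyst reads the outlier map: samples beyond the OD
    cutoff that additionally sit apart from the regular cloud.  The split
    point is the largest gap in sorted OD among the above-cutoff samples
    (measured from the last below-cutoff sample).
    """
    od = omap.od
    above = np.where(od > omap.od_cutoff)[0]
    if len(above) == 0:
        return []
    order = np.argsort(od)
    sorted_od = od[order]
    n_below = len(od) - len(above)
    if n_below == 0:
        return [omap.sample_ids[i] for i in above]
    # gaps between consecutive sorted ODs, from the last regular sample up
    gaps = np.diff(sorted_od[n_below - 1:])
    split = int(np.argmax(gaps))  # 0 = right at the cutoff boundary
    cut_idx = n_below - 1 + split + 1
    flagged_pos = order[cut_idx:]
    return [omap.sample_ids[i] for i in flagged_pos]


def drop_outliers(
    table: FeatureTable, omap: OutlierMap, policy: str = "categorical"
) -> tuple[FeatureTable, list]:
    """Remove outlying samples; returns (retained table, removed sample ids)."""
    if policy not in REMOVAL_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {REMOVAL_POLICIES}")
    if set(omap.sample_ids) < set(table.samples.index):
        raise ValueError("outlier map does not cover all samples")
    if policy == "none":
        return table.copy(), []
    removed = omap.flagged if policy == "categorical" else _distinctive_ids(omap)
    removed = [s for s in removed if s in table.samples.index]
    keep = [s for s in table.samples.index if s not in set(removed)]
    kept_classes = table.samples.loc[keep, "class_label"]
    for cls in table.samples["class_label"].unique():
        if (kept_classes == cls).sum() == 0:
            raise ValueError(f"outlier removal would discard every sample of class {cls!r}")
    return table.subset_samples(keep), removed


@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    total_variance: float
    rmsecv: np.ndarray | None  # RMSECV for 1..k components


def classical_pca(
    X, k: int, compute_rmsecv: bool = False, cv_folds: int = 5, seed: int = 0
) -> PcaResult:
    """Classical PCA with scree data and optional element-wise RMSECV."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need more than one sample")
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n-1, p)={min(n - 1, p)}")
    center, loadings, eig = _pca_of(X, k)
    Xc = X - center
    total_var = float(np.sum(Xc**2) / (n - 1))
    scores = Xc @ loadings
    result = PcaResult(
        scores=scores,
        loadings=loadings,
        eigenvalues=eig,
        explained_variance_ratio=eig / total_var,
        total_variance=total_var,
        rmsecv=None,
    )
    if compute_rmsecv:
        result.rmsecv = _pca_rmsecv(X, k, cv_folds, seed)
    return result


def _pca_rmsecv(X: np.ndarray, kmax: int, cv_folds: int, seed: int) -> np.ndarray:
    """Element-wise cross-validated reconstruction error for 1..kmax components.

    Rows are split into folds; for a held-out row each entry x_ij is
    predicted from the row's other features via least squares on the
    training loadings with row j removed, so the entry itself never enters
    its own prediction.
    """
    n, p = X.shape
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, cv_folds)
    sq_err = np.zeros(kmax)
    count = 0
    for fold in folds:
        train = np.setdiff1d(order, fold)
        if len(train) <= kmax:
            continue
        center, loadings, _ = _pca_of(X[train], kmax)
        Xc_test = X[fold] - center
        count += Xc_test.size
        for a in range(1, kmax + 1):
            P = loadings[:, :a]
            for j in range(p):
                Pm = np.delete(P, j, axis=0)
                xm = np.delete(Xc_test, j, axis=1)
                t, *_ = np.linalg.lstsq(Pm, xm.T, rcond=None)
                pred = P[j] @ t
                sq_err[a - 1] += np.sum((Xc_test[:, j] - pred) ** 2)
    return np.sqrt(sq_err / count)
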