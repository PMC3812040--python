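"""Condition-level statistics on length-resolved motility features.

The statistical design treats each experimental condition as one *main*
dataset plus B bootstrap replicate datasets (filament-level resampling, see
:mod:`~actomotility.features`).  All datasets of all conditions are
assembled into one matrix of concatenated length-resolved features, reduced
to three principal components, and conditions are compared through the
spread of their bootstrap clouds: two conditions differ significantly when
their 95% confidence regions in PC space do not overlap.  Scalar fold
changes of length-averaged features relative to a baseline, a joint
two-feature projection test, agglomerative clustering of the bootstrap
clouds, and a split-resample type-I error self-check complete the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.optimize import minimize
from sklearn.decomposition import PCA

from .features import FEATURES, LengthCurveSet, windowed_curves, \
    bootstrap_curves

__all__ = [
    "ConditionMatrix",
    "PCEmbedding",
    "FoldChangeResult",
    "assemble",
    "pca3",
    "separation_test",
    "pairwise_separation",
    "hcluster",
    "fold_changes",
    "joint_fold_test",
    "type_i_assessment",
]


# ---------------------------------------------------------------------------
# Assembly and PCA
# ---------------------------------------------------------------------------

@dataclass
class ConditionMatrix:
    """Standardised (datasets x features) matrix with row/column metadata.

    Rows are the main and bootstrap datasets of every condition; columns are
    feature/window pairs kept only where finite in every dataset, then
    standardised to zero mean and unit variance.
    """

    X: np.ndarray
    row_condition: np.ndarray
    row_is_main: np.ndarray
    col_feature: np.ndarray
    col_window: np.ndarray
    col_mean: np.ndarray
    col_sd: np.ndarray
    dropped_columns: list = field(default_factory=list)


def assemble(curve_sets: dict[str, LengthCurveSet]) -> ConditionMatrix:
    """Stack main + bootstrap curves of all conditions into one matrix.

    All curve sets must share the window grid and carry replicates.
    Feature/window columns that are missing (NaN) in any dataset are
    dropped globally, as are columns constant across rows (logged in
    ``dropped_columns``).
    """
    names = list(curve_sets)
    grids = [tuple(np.round(cs.centers, 9)) for cs in curve_sets.values()]
    if len(set(grids)) != 1:
        raise ValueError("curve sets use different window grids")
    rows, cond, is_main = [], [], []
    for name in names:
        cs = curve_sets[name]
        if cs.replicates is None:
            raise ValueError(f"condition {name!r} has no bootstrap replicates")
        rows.append(cs.est.to_numpy().T.ravel()[None, :])  # feature-major
        cond.append(name)
        is_main.append(True)
        B = cs.replicates.shape[0]
        rows.append(cs.replicates.transpose(0, 2, 1).reshape(B, -1))
        cond.extend([name] * B)
        is_main.extend([False] * B)
    X = np.vstack(rows)
    n_windows = len(next(iter(curve_sets.values())).centers)
    col_feature = np.repeat(FEATURES, n_windows)
    col_window = np.tile(np.arange(n_windows), len(FEATURES))

    keep = np.all(np.isfinite(X), axis=0)
    sd = np.where(keep, np.nanstd(X, axis=0), 0.0)
    const = keep & (sd < 1e-12)
    dropped = [(f, int(w)) for f, w, k in
               zip(col_feature, col_window, keep & ~const) if not k]
    keep = keep & ~const
    X = X[:, keep]
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    return ConditionMatrix(
        X=(X - mean) / std,
        row_condition=np.array(cond), row_is_main=np.array(is_main),
        col_feature=col_feature[keep], col_window=col_window[keep],
        col_mean=mean, col_sd=std, dropped_columns=dropped)


@dataclass
class PCEmbedding:
    """First three principal components of the assembled matrix."""

    scores: np.ndarray            # (rows, 3)
    explained_var_ratio: np.ndarray
    loadings: np.ndarray          # (3, columns)
    row_condition: np.ndarray
    row_is_main: np.ndarray

    def condition_scores(self, name: str, *, bootstrap_only: bool = True):
        m = self.row_condition == name
        if bootstrap_only:
            m = m & ~self.row_is_main
        return self.scores[m]


def pca3(matrix: ConditionMatrix) -> PCEmbedding:
    """Project the matrix onto its first three principal components.

    Uses a deterministic sign convention (the largest-magnitude loading of
    each component is positive).  Requires data of rank >= 3.
    """
    if np.linalg.matrix_rank(matrix.X) < 3:
        raise ValueError("matrix rank < 3: cannot extract three components")
    pca = PCA(n_components=3, svd_solver="full")
    scores = pca.fit_transform(matrix.X)
    loadings = pca.components_
    for k in range(3):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    return PCEmbedding(scores=scores,
                       explained_var_ratio=pca.explained_variance_ratio_,
                       loadings=loadings,
                       row_condition=matrix.row_condition,
                       row_is_main=matrix.row_is_main)


# ---------------------------------------------------------------------------
# Separation testing in PC space
# ---------------------------------------------------------------------------

def _ellipsoid(points: np.ndarray, level: float = 0.95):
    mu = points.mean(axis=0)
    cov = np.cov(points.T)
    cov = np.atleast_2d(cov) + 1e-12 * np.eye(points.shape[1])
    r2 = sps.chi2.ppf(level, df=points.shape[1])
    return mu, np.linalg.inv(cov), r2


def _ellipsoids_overlap(pa, pb, level: float = 0.95) -> bool:
    """Do the Mahalanobis-radius confidence ellipsoids of two point clouds
    intersect?

    Minimises the Mahalanobis distance to cloud B subject to staying inside
    cloud A's ellipsoid (a convex program solved with SLSQP); the clouds
    overlap iff the minimum is within B's radius.
    """
    mu_a, prec_a, r2_a = _ellipsoid(pa, level)
    mu_b, prec_b, r2_b = _ellipsoid(pb, level)

    def f(x):
        d = x - mu_b
        return d @ prec_b @ d

    def grad(x):
        return 2 * prec_b @ (x - mu_b)

    cons = {"type": "ineq",
            "fun": lambda x: r2_a - (x - mu_a) @ prec_a @ (x - mu_a),
            "jac": lambda x: -2 * prec_a @ (x - mu_a)}
    res = minimize(f, mu_a, jac=grad, constraints=[cons], method="SLSQP",
                   options={"maxiter": 200, "ftol": 1e-10})
    return bool(res.fun <= r2_b)


def separation_test(embedding: PCEmbedding, cond_a: str, cond_b: str, *,
                    level: float = 0.95, min_points: int = 100) -> bool:
    """Are two conditions significantly separated in PC1-3?

    Significance is claimed when the ``level`` confidence ellipsoids of the
    two conditions' bootstrap scores are disjoint.  A condition compared
    with itself is never significant.
    """
    if cond_a == cond_b:
        return False
    pa = embedding.condition_scores(cond_a)
    pb = embedding.condition_scores(cond_b)
    if len(pa) < min_points or len(pb) < min_points:
        raise ValueError(
            f"need >= {min_points} bootstrap points per condition")
    return not _ellipsoids_overlap(pa, pb, level)


def pairwise_separation(embedding: PCEmbedding, *, level: float = 0.95,
                        min_points: int = 100) -> pd.DataFrame:
    """Symmetric condition x condition significance matrix (bool)."""
    names = list(dict.fromkeys(embedding.row_condition))
    out = pd.DataFrame(False, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sig = separation_test(embedding, a, b, level=level,
                                  min_points=min_points)
            out.loc[a, b] = out.loc[b, a] = sig
    return out


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

def hcluster(embedding: PCEmbedding, max_k: int = 8, *,
             structural_factor: float = 3.0):
    """Ward-linkage clustering of all bootstrap scores in PC1-3.

    The cluster count is read off the linkage profile (merge height
    versus remaining cluster count): the finest splits set the noise
    scale of the profile (median of the last three heights), a merge is
    *structural* when it costs at least ``structural_factor`` times that
    scale, and k is one more than the number of structural merges --
    equivalently, the largest k whose formation still involved a
    relatively large reduction of linkage.  Data whose profile never
    rises above the noise scale yield k = 1.  Returns ``(k, assignments,
    linkage_profile, composition)`` where ``composition`` is a condition
    x cluster count table over the bootstrap rows.
    """
    mask = ~embedding.row_is_main
    pts = embedding.scores[mask]
    conds = embedding.row_condition[mask]
    if len(pts) < max_k:
        raise ValueError("need at least max_k points")
    if np.allclose(pts, pts[0]):
        prof = pd.DataFrame({"k": [1], "height": [0.0]})
        comp = pd.crosstab(conds, np.ones(len(pts), dtype=int))
        return 1, np.ones(len(pts), dtype=int), prof, comp
    Z = hierarchy.ward(pts)
    n = len(pts)
    heights = {k: Z[n - k - 1, 2] for k in range(1, max_k + 1)}
    profile = pd.DataFrame({"k": list(heights),
                            "height": [heights[k] for k in heights]})
    tail = float(np.median([heights[j]
                            for j in (max_k - 2, max_k - 1, max_k)]))
    structural = [j for j in range(1, max_k + 1)
                  if heights[j] >= structural_factor * max(tail, 1e-12)]
    k = max(structural) + 1 if structural else 1
    assign = hierarchy.fcluster(Z, k, criterion="maxclust")
    composition = pd.crosstab(pd.Series(conds, name="condition"),
                              pd.Series(assign, name="cluster"))
    return k, assign, profile, composition


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeResult:
    """Length-averaged fold change of one feature vs the baseline.

    ``fold`` is the ratio of window-averaged point estimates; the CI is the
    percentile interval of the target's bootstrap window-averages divided
    by the baseline point estimate.  ``significant`` applies the
    non-overlap rule to the two conditions' mean CIs, and ``margin`` is the
    signed distance between the facing CI limits in fold units (positive =
    significant), the quantity tallied by the type-I assessment.
    """

    feature: str
    fold: float
    ci_low: float
    ci_high: float
    significant: bool
    margin: float


def _window_average(cs: LengthCurveSet, feature: str, wsel=None):
    fi = list(FEATURES).index(feature)
    est = cs.est[feature].to_numpy()
    reps = cs.replicates[:, :, fi]
    ok = np.isfinite(est) & np.all(np.isfinite(reps), axis=0)
    if wsel is not None:
        ok = ok & wsel
    if not np.any(ok):
        raise ValueError(f"no usable windows for feature {feature!r}")
    return float(est[ok].mean()), reps[:, ok].mean(axis=1), ok


def fold_changes(target: LengthCurveSet, baseline: LengthCurveSet,
                 feature: str, *, window_sel=None, level: float = 0.95,
                 ) -> FoldChangeResult:
    """Fold change of a length-averaged feature relative to the baseline.

    Only windows finite in both conditions (optionally restricted by
    ``window_sel``) enter the average.  Significance follows the
    non-overlap rule on the two percentile CIs of the window-averaged
    means; a target identical to its baseline therefore yields fold 1 and
    no significance.
    """
    if not np.allclose(target.centers, baseline.centers):
        raise ValueError("target and baseline use different window grids")
    pt_t, reps_t, ok_t = _window_average(target, feature, window_sel)
    sel = np.isfinite(target.est[feature].to_numpy()) & \
        np.isfinite(baseline.est[feature].to_numpy())
    if window_sel is not None:
        sel = sel & window_sel
    pt_t, reps_t, _ = _window_average(target, feature, sel)
    pt_b, reps_b, _ = _window_average(baseline, feature, sel)
    if abs(pt_b) < 1e-12:
        raise ValueError("baseline mean is zero; fold change undefined")
    q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
    lo_t, hi_t = np.percentile(reps_t, q)
    lo_b, hi_b = np.percentile(reps_b, q)
    if pt_t >= pt_b:
        margin = (lo_t - hi_b) / pt_b
    else:
        margin = (lo_b - hi_t) / pt_b
    return FoldChangeResult(
        feature=feature, fold=pt_t / pt_b,
        ci_low=float(lo_t / pt_b), ci_high=float(hi_t / pt_b),
        significant=bool(margin > 0), margin=float(margin))


def joint_fold_test(target: LengthCurveSet, baseline: LengthCurveSet,
                    feature1: str, feature2: str, *, level: float = 0.95,
                    window_sel=None) -> bool:
    """Joint two-feature significance by projection.

    Each condition's bootstrap replicates give a 2-D cloud of
    (fold_f1, fold_f2) points; both clouds are projected onto the unit
    vector joining the two condition means, and significance is claimed
    when the percentile intervals of the projections do not overlap.  This
    can detect aligned shifts that are too small per feature.
    """
    clouds = []
    centers = []
    for cs in (target, baseline):
        pts = []
        ctr = []
        for f in (feature1, feature2):
            sel = np.isfinite(target.est[f].to_numpy()) & \
                np.isfinite(baseline.est[f].to_numpy())
            if window_sel is not None:
                sel = sel & window_sel
            pt_b, _, _ = _window_average(baseline, f, sel)
            pt, reps, _ = _window_average(cs, f, sel)
            pts.append(reps / pt_b)
            ctr.append(pt / pt_b)
        clouds.append(np.column_stack(pts))
        centers.append(np.array(ctr))
    u = centers[0] - centers[1]
    norm = np.linalg.norm(u)
    if norm < 1e-12:
        return False
    u = u / norm
    q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
    proj_t = clouds[0] @ u
    proj_b = clouds[1] @ u
    lo_t, hi_t = np.percentile(proj_t, q)
    lo_b, hi_b = np.percentile(proj_b, q)
    return bool(lo_t > hi_b or lo_b > hi_t)


# ---------------------------------------------------------------------------
# Type-I error self-check
# ---------------------------------------------------------------------------

def type_i_assessment(records: pd.DataFrame, n_comparisons: int = 300,
                      seed: int = 0, *, B: int = 200,
                      features=FEATURES, **window_kw) -> pd.DataFrame:
    """Split-resample null comparisons of one condition against itself.

    Two full-size resamples of the record table (drawn with replacement,
    as in the bootstrap) are treated as pseudo-conditions; the
    length-averaged fold-change analysis is run for each feature and the
    non-overlap margin recorded.  A type-I event is a positive margin.
    Returns a (n_comparisons x features) table of margins; their
    empirical distribution should sit clearly below zero.
    """
    if len(records) < 2:
        raise ValueError("need at least two records to split")
    rng = np.random.default_rng(seed)
    n = len(records)
    out = np.empty((n_comparisons, len(features)))
    for i in range(n_comparisons):
        half_a = records.iloc[rng.integers(0, n, n)].reset_index(drop=True)
        half_b = records.iloc[rng.integers(0, n, n)].reset_index(drop=True)
        cs_a = bootstrap_curves(half_a, B=B,
                                seed=int(rng.integers(2 ** 31 - 1)),
                                **window_kw)
        cs_b = bootstrap_curves(half_b, B=B,
                                seed=int(rng.integers(2 ** 31 - 1)),
                                **window_kw)
        for j, f in enumerate(features):
            out[i, j] = fold_changes(cs_a, cs_b, f).margin
    return pd.DataFrame(out, columns=list(features))
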