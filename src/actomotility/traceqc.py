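"""Machine-learning rejection of filament traces with crossings or
irregular motion.

Each trace is summarised by a deterministic feature vector (trajectory
corner count, coefficient-of-variation features, complex-length fraction,
proximity/overlap statistics) and scored by a bagged decision-tree
ensemble.  The acceptance threshold on the ensemble score is chosen by
minimising an asymmetric misclassification cost (a bad trace kept is worse
than a good trace lost), and monitoring uses out-of-bag error versus tree
count plus ROC curves for cross-day style validation.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import corner_harris, corner_peaks
from scipy.ndimage import gaussian_filter
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve, roc_auc_score

__all__ = [
    "QC_FEATURES",
    "featurize",
    "featurize_all",
    "QCModel",
    "train",
    "choose_threshold",
    "filter_traces",
]

#: Feature order of the QC vector.
QC_FEATURES = (
    "corner_count", "velocity_cv", "area_cv", "length_cv",
    "complex_fraction", "min_distance_um", "overlap_events",
)

#: Corner detection settings: Gaussian smoothing kernel (length, sigma),
#: corner cap, Harris sensitivity and relative quality level.
CORNER_KERNEL_LEN = 21
CORNER_SIGMA = 2.5
MAX_CORNERS = 200
CORNER_SENSITIVITY = 0.2
CORNER_QUALITY = 0.15


def _corner_count(xy_um: np.ndarray, pixel_um: float = 0.16) -> int:
    """Harris corners along the rasterised trajectory polyline."""
    span = xy_um.max(axis=0) - xy_um.min(axis=0)
    if np.all(span < pixel_um):
        return 0  # degenerate single-pixel trajectory
    pts = (xy_um - xy_um.min(axis=0)) / pixel_um
    pad = CORNER_KERNEL_LEN
    W = int(np.ceil(pts[:, 0].max())) + 2 * pad + 1
    H = int(np.ceil(pts[:, 1].max())) + 2 * pad + 1
    img = np.zeros((H, W))
    # draw the polyline by dense sampling of the segments
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(2, int(np.hypot(*(b - a)) * 2) + 1)
        seg = np.linspace(a, b, n)
        img[np.round(seg[:, 1]).astype(int) + pad,
            np.round(seg[:, 0]).astype(int) + pad] = 1.0
    img = gaussian_filter(img, CORNER_SIGMA, truncate=(
        (CORNER_KERNEL_LEN - 1) / 2) / CORNER_SIGMA)
    resp = corner_harris(img, k=CORNER_SENSITIVITY / 4)
    peaks = corner_peaks(resp, min_distance=3,
                         threshold_rel=CORNER_QUALITY,
                         num_peaks=MAX_CORNERS)
    if len(peaks) == 0:
        return 0
    # the free ends of any open polyline respond like corners; only
    # interior direction changes are evidence of irregular motion
    ends = np.array([pts[0][::-1] + pad, pts[-1][::-1] + pad])
    d_end = np.sqrt(((peaks[:, None, :] - ends[None, :, :]) ** 2
                     ).sum(-1)).min(axis=1)
    return int(np.sum(d_end > 3 * CORNER_SIGMA))


def featurize(trace: pd.DataFrame, all_traces: pd.DataFrame,
              dt: float) -> np.ndarray:
    """QC feature vector of one trace (requires >= 3 frames).

    ``all_traces`` is the full tracked object table of the same video and
    provides the proximity features: the minimum same-frame distance to any
    other trace and the number of frames with another trace within the
    filament's own length (potential crossing frames).
    """
    trace = trace.sort_values("frame")
    if len(trace) < 3:
        raise ValueError("QC features are defined for traces >= 3 frames")
    xy = trace[["x_um", "y_um"]].to_numpy()
    v = np.hypot(*np.diff(xy, axis=0).T) / dt
    area = trace["area_um2"].to_numpy()
    length = trace["length_um"].to_numpy()

    def cv(x):
        m = np.mean(x)
        return float(np.std(x) / m) if m > 0 else 0.0

    tid = trace["trace_id"].iloc[0]
    others = all_traces.loc[all_traces["trace_id"] != tid]
    min_d = np.inf
    overlaps = 0
    if len(others):
        for fr, row in zip(trace["frame"], xy):
            o = others.loc[others["frame"] == fr]
            if len(o) == 0:
                continue
            d = np.hypot(o["x_um"] - row[0], o["y_um"] - row[1]).min()
            min_d = min(min_d, float(d))
            if d < max(1.0, length.mean()):
                overlaps += 1
    if not np.isfinite(min_d):
        min_d = 100.0  # no neighbour ever present
    return np.array([
        _corner_count(xy),
        cv(v) if v.mean() > 0 else 10.0,
        cv(area), cv(length),
        float(np.mean(trace["complex_flag"].to_numpy(dtype=bool))),
        min_d, float(overlaps),
    ])


def featurize_all(tracked: pd.DataFrame, dt: float, *,
                  min_frames: int = 3):
    """Feature matrix for every trace with at least ``min_frames`` frames.

    Returns ``(trace_ids, X)``.
    """
    ids, rows = [], []
    for tid, tr in tracked.groupby("trace_id"):
        if len(tr) < min_frames:
            continue
        ids.append(tid)
        rows.append(featurize(tr, tracked, dt))
    X = np.array(rows) if rows else np.empty((0, len(QC_FEATURES)))
    return np.array(ids), X


def label_traces_from_truth(tracked: pd.DataFrame, truth: pd.DataFrame,
                            trace_ids, *, dt: float = 1 / 3,
                            native_fps: float = 30.0,
                            match_radius_um: float = 3.0) -> np.ndarray:
    """Keep/reject labels for tracked traces from a scripted truth table.

    A trace is rejected (label 0) if any of its frames matches a truth
    filament that is flagged as overlapping (a crossing event) or scripted
    as irregular motion; otherwise it is clean (label 1).  Matching is by
    nearest truth centroid at the corresponding native frame within
    ``match_radius_um``.  Used to build training sets for the classifier
    from mock videos; hand scoring plays this role for real data.
    """
    merge = int(round(dt * native_fps))
    last = int(truth["frame"].max())
    labels = []
    for tid in trace_ids:
        tr = tracked[tracked["trace_id"] == tid]
        lab = 1
        for _, row in tr.iterrows():
            fr_nat = min(int(row["frame"] * merge + merge // 2), last)
            nat = truth[truth["frame"] == fr_nat]
            if len(nat) == 0:
                continue
            d = np.hypot(nat["x_um"] - row["x_um"], nat["y_um"] - row["y_um"])
            if d.min() > match_radius_um:
                continue
            near = nat.loc[d.idxmin()]
            if near["label"] == "irregular" or near["overlap"]:
                lab = 0
                break
        labels.append(lab)
    return np.array(labels)


@dataclass
class QCModel:
    """Bagged decision-tree ensemble scoring traces as clean vs reject.

    ``score`` is the ensemble fraction of trees voting "keep"; traces with
    score >= ``threshold`` are accepted.  ``oob_curve`` records the
    out-of-bag error as a function of tree count.
    """

    forest: RandomForestClassifier
    oob_curve: pd.DataFrame
    threshold: float = 0.5
    feature_names: tuple = QC_FEATURES
    version: int = 1

    def score(self, X: np.ndarray) -> np.ndarray:
        keep_col = list(self.forest.classes_).index(1)
        return self.forest.predict_proba(X)[:, keep_col]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "QCModel":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a QCModel")
        return obj


def train(X: np.ndarray, y: np.ndarray, n_trees: int = 150,
          seed: int = 0, *, oob_checkpoints=(10, 25, 50, 75, 100, 150),
          ) -> QCModel:
    """Train the bagged tree ensemble; labels are 1 = keep, 0 = reject.

    The out-of-bag error is evaluated at increasing tree counts (warm
    start), giving the error-vs-trees curve used to verify that
    performance has plateaued by the default 150 trees.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    checkpoints = sorted({c for c in oob_checkpoints if c <= n_trees}
                         | {n_trees})
    forest = RandomForestClassifier(
        n_estimators=checkpoints[0], oob_score=True, warm_start=True,
        random_state=seed, n_jobs=1)
    curve = []
    for c in checkpoints:
        forest.set_params(n_estimators=c)
        forest.fit(X, y)
        curve.append((c, 1.0 - forest.oob_score_))
    return QCModel(forest=forest,
                   oob_curve=pd.DataFrame(curve,
                                          columns=["n_trees", "oob_error"]))


def choose_threshold(model: QCModel, X_val: np.ndarray, y_val: np.ndarray,
                     cost_fp: float = 5.0, cost_fn: float = 1.0):
    """Acceptance threshold minimising the asymmetric misclassification cost.

    A false positive is a reject-worthy trace that is kept (cost 5 by
    default), a false negative a clean trace that is lost (cost 1).  The
    total cost ``cost_fp * FPR + cost_fn * FNR`` is evaluated on a grid of
    candidate thresholds; the midpoint of the optimal plateau is returned
    together with the ROC curve for cross-validation reporting.
    """
    y_val = np.asarray(y_val)
    if len(np.unique(y_val)) < 2:
        raise ValueError("validation labels must contain both classes")
    scores = model.score(X_val)
    grid = np.unique(np.concatenate([[0.0, 1.0 + 1e-9], scores]))
    best = None
    for thr in grid:
        keep = scores >= thr
        fpr = np.mean(keep[y_val == 0]) if np.any(y_val == 0) else 0.0
        fnr = np.mean(~keep[y_val == 1]) if np.any(y_val == 1) else 0.0
        cost = cost_fp * fpr + cost_fn * fnr
        if best is None or cost < best[0] - 1e-12:
            best = (cost, [thr])
        elif abs(cost - best[0]) <= 1e-12:
            best[1].append(thr)
    threshold = float(np.median(best[1]))
    fpr, tpr, thr = roc_curve(y_val, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    roc.attrs["auc"] = float(roc_auc_score(y_val, scores))
    roc.attrs["total_cost"] = float(best[0])
    return threshold, roc


def filter_traces(model: QCModel, tracked: pd.DataFrame, dt: float, *,
                  threshold: float | None = None, min_frames: int = 3):
    """Apply the QC model; return accepted trace ids and a rejection log.

    The log records score and feature values for every scored trace, with
    an ``accepted`` flag; traces shorter than ``min_frames`` are dropped
    (logged with NaN score).
    """
    thr = model.threshold if threshold is None else threshold
    ids, X = featurize_all(tracked, dt, min_frames=min_frames)
    log_rows = []
    accepted = []
    if len(ids):
        scores = model.score(X)
        for tid, s, feats in zip(ids, scores, X):
            ok = bool(s >= thr)
            if ok:
                accepted.append(tid)
            log_rows.append({"trace_id": tid, "score": float(s),
                             "accepted": ok,
                             **dict(zip(QC_FEATURES, feats))})
    short = set(tracked["trace_id"].unique()) - set(ids)
    for tid in sorted(short):
        log_rows.append({"trace_id": tid, "score": np.nan,
                         "accepted": False,
                         **{f: np.nan for f in QC_FEATURES}})
    log = pd.DataFrame(log_rows)
    return accepted, log
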