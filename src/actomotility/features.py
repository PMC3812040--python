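"""Motility features of filament traces, resolved by filament length.

Each accepted filament trace — experimental or simulated — is reduced to a
:class:`MotilityRecord`-style row holding the four motility features used
throughout the package:

* ``v_mean`` — mean frame-to-frame sliding velocity (µm/s),
* ``f_mot`` — motile fraction, the fraction of frame-to-frame intervals
  classified as *running* rather than *stopped*,
* ``stop_time`` — mean duration of maximal stopped segments (s),
* ``run_time`` — mean duration of maximal running segments (s).

Stopped and running intervals are separated by a velocity cut obtained from a
two-component Gaussian mixture fitted to the pooled frame-to-frame velocity
distribution of a condition: the lower component is the apparent-velocity
noise floor of stationary filaments, the upper component the genuinely
sliding population.  Features are then resolved by filament length with
overlapping sliding windows and bootstrap-resampled at the filament level to
produce confidence bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "FEATURES",
    "TwoGaussianFit",
    "LengthCurveSet",
    "fit_two_gaussians",
    "segment_runs_stops",
    "trace_to_record",
    "records_from_series",
    "windowed_curves",
    "bootstrap_curves",
    "synthetic_records",
]

#: Canonical feature order used in curve sets and downstream statistics.
FEATURES = ("v_mean", "f_mot", "stop_time", "run_time")

#: Default length windowing: sliding window range (µm), width (µm), count.
DEFAULT_LENGTH_RANGE = (0.3, 3.25)
DEFAULT_WINDOW_WIDTH = 0.59
DEFAULT_N_WINDOWS = 50


# ---------------------------------------------------------------------------
# Two-Gaussian velocity mixture and run/stop segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoGaussianFit:
    """Two-component Gaussian mixture fitted to pooled v_f2f values.

    ``cut`` is the equal-posterior velocity between the two component means;
    intervals with v_f2f below the cut are classified as stopped.
    ``separable`` is False when the two components collapse onto each other
    (the low-time-resolution regime in which stopped and running populations
    cannot be distinguished).
    """

    mean_stop: float
    sd_stop: float
    mean_run: float
    sd_run: float
    weight_stop: float
    cut: float
    separable: bool


def fit_two_gaussians(v: np.ndarray, *, random_state: int = 0) -> TwoGaussianFit:
    """Fit a two-Gaussian mixture to pooled frame-to-frame velocities.

    Parameters
    ----------
    v:
        Pooled frame-to-frame velocity sample (µm/s), at least 100 values.

    Returns
    -------
    TwoGaussianFit
        Component parameters sorted so that ``mean_run >= mean_stop``, and
        the equal-posterior cut velocity.  The result is invariant to the
        labelling of the two components.
    """
    v = np.asarray(v, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 100:
        raise ValueError(f"need >= 100 velocity values, got {v.size}")
    # deterministic initialisation makes the fit label-invariant: the low
    # component starts on the apparent-velocity noise floor of stationary
    # filaments (lowest percentiles), the high one inside the sliding mode
    q02, q70 = np.quantile(v, [0.02, 0.70])
    gm = GaussianMixture(
        n_components=2,
        covariance_type="diag",
        means_init=np.array([[q02], [q70]]),
        precisions_init=np.array([[1.0 / max(q02, 1e-3) ** 2],
                                  [1.0 / max(q70 - q02, 1e-2) ** 2]]),
        weights_init=np.array([0.3, 0.7]),
        random_state=random_state,
        max_iter=500,
    )
    gm.fit(v[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    lo, hi = np.argsort(means)
    mean_stop, mean_run = means[lo], means[hi]
    sd_stop, sd_run = sds[lo], sds[hi]
    w_stop = weights[lo]

    separable = (mean_run - mean_stop) > 0.5 * (sd_stop + sd_run)
    cut = _equal_posterior_cut(mean_stop, sd_stop, w_stop,
                               mean_run, sd_run, 1.0 - w_stop)
    return TwoGaussianFit(mean_stop, sd_stop, mean_run, sd_run, w_stop,
                          cut, separable)


def _equal_posterior_cut(m1, s1, w1, m2, s2, w2) -> float:
    """Velocity between the component means where posteriors are equal."""
    if m2 <= m1:
        return 0.5 * (m1 + m2)
    x = np.linspace(m1, m2, 2001)
    log1 = np.log(w1 + 1e-300) - np.log(s1) - 0.5 * ((x - m1) / s1) ** 2
    log2 = np.log(w2 + 1e-300) - np.log(s2) - 0.5 * ((x - m2) / s2) ** 2
    return float(x[np.argmin(np.abs(log1 - log2))])


def segment_runs_stops(v_f2f: Sequence[float], cut: float, dt: float):
    """Segment a frame-to-frame velocity series into runs and stops.

    Maximal consecutive intervals with velocity above ``cut`` are runs,
    intervals below are stops.  Returns ``(run_times, stop_times, f_mot,
    running_mask)`` where the times are segment durations in seconds and
    ``f_mot`` is the fraction of intervals classified as running.
    """
    v = np.asarray(v_f2f, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one frame-to-frame interval")
    running = v > cut
    f_mot = float(np.mean(running))
    run_times, stop_times = [], []
    # run-length encode the boolean series
    edges = np.flatnonzero(np.diff(running.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [running.size]))
    for s, e in zip(starts, ends):
        duration = (e - s) * dt
        (run_times if running[s] else stop_times).append(duration)
    return run_times, stop_times, f_mot, running


# ---------------------------------------------------------------------------
# Per-filament records
# ---------------------------------------------------------------------------

#: Columns of the per-filament record table.
RECORD_COLUMNS = (
    "condition", "chamber", "video", "filament", "L_um",
    "v_trace_um_s", "v_f2f_mean_um_s", "f_mot",
    "n_intervals", "n_run_intervals",
    "run_time_sum_s", "n_runs", "stop_time_sum_s", "n_stops",
)


def trace_to_record(v_f2f, *, L_um, cut, dt, v_trace=None,
                    condition="", chamber="", video="", filament=0) -> dict:
    """Reduce one filament's v_f2f series to a feature record (dict row)."""
    run_times, stop_times, f_mot, running = segment_runs_stops(v_f2f, cut, dt)
    v = np.asarray(v_f2f, dtype=float)
    return {
        "condition": condition, "chamber": chamber, "video": video,
        "filament": filament, "L_um": float(L_um),
        "v_trace_um_s": float(v_trace) if v_trace is not None else float(np.mean(v)),
        "v_f2f_mean_um_s": float(np.mean(v)),
        "f_mot": f_mot,
        "n_intervals": int(v.size),
        "n_run_intervals": int(np.sum(running)),
        "run_time_sum_s": float(np.sum(run_times)), "n_runs": len(run_times),
        "stop_time_sum_s": float(np.sum(stop_times)), "n_stops": len(stop_times),
    }


def records_from_series(series, lengths, dt, *, cut=None, condition="",
                        v_traces=None, random_state: int = 0) -> pd.DataFrame:
    """Build a record table from many v_f2f series of one condition.

    If ``cut`` is None, a two-Gaussian mixture is fitted to the pooled
    velocities of the condition and its equal-posterior cut is used, as for
    experimental data.
    """
    if cut is None:
        pooled = np.concatenate([np.asarray(s, dtype=float) for s in series])
        cut = fit_two_gaussians(pooled, random_state=random_state).cut
    rows = []
    for i, (v, L) in enumerate(zip(series, lengths)):
        vt = None if v_traces is None else v_traces[i]
        rows.append(trace_to_record(v, L_um=L, cut=cut, dt=dt,
                                    v_trace=vt, condition=condition, filament=i))
    df = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    df.attrs["cut_um_s"] = float(cut)
    return df


# ---------------------------------------------------------------------------
# Length-windowed curves with bootstrap bands
# ---------------------------------------------------------------------------

@dataclass
class LengthCurveSet:
    """Length-resolved feature curves with optional bootstrap replicates.

    ``est`` holds the point-estimate curves (windows x features), ``counts``
    the number of filaments per window, ``replicates`` an optional
    (B, windows, features) array of bootstrap curves with percentile 95%
    bands in ``ci_low``/``ci_high``.
    """

    centers: np.ndarray
    width: float
    est: pd.DataFrame
    counts: np.ndarray
    replicates: np.ndarray | None = None
    ci_low: pd.DataFrame | None = None
    ci_high: pd.DataFrame | None = None
    condition: str = ""
    seed: int | None = None

    def to_json(self, path, *, include_replicates: bool = False) -> None:
        doc = {
            "condition": self.condition,
            "centers_um": self.centers.tolist(),
            "width_um": self.width,
            "features": list(FEATURES),
            "est": self.est.to_numpy().tolist(),
            "counts": self.counts.tolist(),
            "seed": self.seed,
        }
        if self.ci_low is not None:
            doc["ci_low"] = self.ci_low.to_numpy().tolist()
            doc["ci_high"] = self.ci_high.to_numpy().tolist()
        if include_replicates and self.replicates is not None:
            doc["replicates"] = self.replicates.tolist()
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "LengthCurveSet":
        with open(path) as fh:
            doc = json.load(fh)
        est = pd.DataFrame(doc["est"], columns=doc["features"])
        obj = cls(
            centers=np.asarray(doc["centers_um"]),
            width=doc["width_um"],
            est=est,
            counts=np.asarray(doc["counts"]),
            condition=doc.get("condition", ""),
            seed=doc.get("seed"),
        )
        if "ci_low" in doc:
            obj.ci_low = pd.DataFrame(doc["ci_low"], columns=doc["features"])
            obj.ci_high = pd.DataFrame(doc["ci_high"], columns=doc["features"])
        if "replicates" in doc:
            obj.replicates = np.asarray(doc["replicates"])
        return obj


def window_grid(length_range=DEFAULT_LENGTH_RANGE, width=DEFAULT_WINDOW_WIDTH,
                n_windows=DEFAULT_N_WINDOWS) -> np.ndarray:
    """Centers of equally spaced sliding length windows covering the range."""
    if width <= 0:
        raise ValueError("window width must be positive")
    lo, hi = length_range
    return np.linspace(lo + width / 2, hi - width / 2, n_windows)


def _stat_matrix(records: pd.DataFrame) -> np.ndarray:
    """Per-record sufficient statistics for the four windowed features."""
    return np.column_stack([
        records["v_f2f_mean_um_s"].to_numpy(float),
        np.ones(len(records)),
        records["n_run_intervals"].to_numpy(float),
        records["n_intervals"].to_numpy(float),
        records["stop_time_sum_s"].to_numpy(float),
        records["n_stops"].to_numpy(float),
        records["run_time_sum_s"].to_numpy(float),
        records["n_runs"].to_numpy(float),
    ])


def _curves_from_stats(masks: np.ndarray, S: np.ndarray,
                       weights: np.ndarray) -> np.ndarray:
    """Windowed feature curves from per-record statistics.

    masks: (W, n) window membership; S: (n, 8) statistics; weights: (n,)
    resampling multiplicities.  Returns (W, 4) curves with NaN where a
    window holds no filaments (or no stops / runs for the time features).
    """
    agg = masks @ (S * weights[:, None])  # (W, 8)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_mean = agg[:, 0] / agg[:, 1]
        f_mot = agg[:, 2] / agg[:, 3]
        stop_time = agg[:, 4] / agg[:, 5]
        run_time = agg[:, 6] / agg[:, 7]
    out = np.column_stack([v_mean, f_mot, stop_time, run_time])
    out[agg[:, 1] == 0] = np.nan
    return out


def windowed_curves(records: pd.DataFrame, *,
                    length_range=DEFAULT_LENGTH_RANGE,
                    width=DEFAULT_WINDOW_WIDTH,
                    n_windows=DEFAULT_N_WINDOWS,
                    condition: str | None = None) -> LengthCurveSet:
    """Length-windowed point estimates of the four motility features.

    Per window, ``v_mean`` is the mean over filaments of the per-filament
    mean v_f2f, ``f_mot`` is computed from the pooled run/stop intervals of
    all filaments in the window, and the run/stop times are means of the
    pooled segment durations.  Windows without filaments carry NaN.
    """
    if len(records) == 0:
        raise ValueError("empty record table")
    centers = window_grid(length_range, width, n_windows)
    L = records["L_um"].to_numpy(float)
    masks = (np.abs(L[None, :] - centers[:, None]) <= width / 2).astype(float)
    S = _stat_matrix(records)
    est = _curves_from_stats(masks, S, np.ones(len(records)))
    counts = masks.sum(axis=1).astype(int)
    cond = condition if condition is not None else _single_condition(records)
    return LengthCurveSet(centers=centers, width=width,
                          est=pd.DataFrame(est, columns=list(FEATURES)),
                          counts=counts, condition=cond)


def bootstrap_curves(records: pd.DataFrame, B: int = 500, seed: int = 0, *,
                     length_range=DEFAULT_LENGTH_RANGE,
                     width=DEFAULT_WINDOW_WIDTH,
                     n_windows=DEFAULT_N_WINDOWS,
                     resample_unit: str = "filament",
                     condition: str | None = None) -> LengthCurveSet:
    """Bootstrap the windowed curves by resampling whole filaments.

    ``B`` resamples with replacement are drawn at the level of
    ``resample_unit`` ("filament" or "chamber"); each yields one replicate
    curve per feature.  95% percentile bands are attached.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    cs = windowed_curves(records, length_range=length_range, width=width,
                         n_windows=n_windows, condition=condition)
    n = len(records)
    L = records["L_um"].to_numpy(float)
    masks = (np.abs(L[None, :] - cs.centers[:, None]) <= width / 2).astype(float)
    S = _stat_matrix(records)
    rng = np.random.default_rng(seed)

    if resample_unit == "filament":
        # multinomial draw of per-record multiplicities == iid resampling
        weights = rng.multinomial(n, np.full(n, 1.0 / n), size=B).astype(float)
    elif resample_unit == "chamber":
        chambers = records["chamber"].to_numpy()
        uniq = np.unique(chambers)
        weights = np.zeros((B, n))
        for b in range(B):
            picked = rng.choice(uniq, size=uniq.size, replace=True)
            for ch in picked:
                weights[b, chambers == ch] += 1.0
    else:
        raise ValueError(f"unknown resample unit {resample_unit!r}")

    reps = np.empty((B, n_windows, len(FEATURES)))
    for b in range(B):
        reps[b] = _curves_from_stats(masks, S, weights[b])
    cs.replicates = reps
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        lo = np.nanpercentile(reps, 2.5, axis=0)
        hi = np.nanpercentile(reps, 97.5, axis=0)
    cs.ci_low = pd.DataFrame(lo, columns=list(FEATURES))
    cs.ci_high = pd.DataFrame(hi, columns=list(FEATURES))
    cs.seed = seed
    return cs


def _single_condition(records: pd.DataFrame) -> str:
    vals = records["condition"].unique()
    return str(vals[0]) if len(vals) == 1 else ""


# ---------------------------------------------------------------------------
# Synthetic per-condition record tables
# ---------------------------------------------------------------------------

def synthetic_records(n_filaments: int = 500, seed: int = 0, *,
                      condition: str = "synthetic",
                      length_range=DEFAULT_LENGTH_RANGE,
                      v_at_1um: float = 0.5, v_slope: float = 0.05,
                      v_sd: float = 0.12,
                      f_mot_half_um: float = 0.45, f_mot_max: float = 0.95,
                      stop_time_mean: float = 0.9, run_time_mean: float = 3.0,
                      dt: float = 1 / 3, T: float = 25.0,
                      n_chambers: int = 20) -> pd.DataFrame:
    """Synthetic per-filament feature table with realistic structure.

    Emulates the statistical shape of an experimental condition: a few
    hundred filaments with lengths spread over the analysis range, mean
    velocity rising gently with length around ``v_at_1um``, a motile
    fraction that saturates with length, and exponential-like run/stop
    segment durations discretised to the analysis time step.  Used to
    validate the windowing/bootstrap statistics independently of the
    mechanistic simulator.
    """
    rng = np.random.default_rng(seed)
    rows = []
    lo, hi = length_range
    for i in range(n_filaments):
        L = rng.uniform(lo, hi)
        f_sat = f_mot_max * L / (f_mot_half_um + L)
        n_int = max(2, int(round(T / dt)) - 1)
        v_mean = max(0.02, v_at_1um + v_slope * (L - 1.0) + rng.normal(0, v_sd))
        # alternate run/stop segments with geometric (discretised
        # exponential) durations until the trace is exhausted
        p_run_end = min(0.95, dt / run_time_mean)
        p_stop_end = min(0.95, dt / stop_time_mean)
        running = rng.random() < f_sat
        intervals = []
        while len(intervals) < n_int:
            p = p_run_end if running else p_stop_end
            seg = 1 + rng.geometric(p)
            intervals.extend([running] * seg)
            running = not running
        mask = np.array(intervals[:n_int])
        run_times, stop_times, f_mot, _ = segment_runs_stops(
            mask.astype(float), 0.5, dt)
        rows.append({
            "condition": condition,
            "chamber": f"ch{rng.integers(n_chambers)}",
            "video": f"v{i % 60}", "filament": i, "L_um": L,
            "v_trace_um_s": v_mean, "v_f2f_mean_um_s": v_mean,
            "f_mot": f_mot, "n_intervals": n_int,
            "n_run_intervals": int(mask.sum()),
            "run_time_sum_s": float(np.sum(run_times)), "n_runs": len(run_times),
            "stop_time_sum_s": float(np.sum(stop_times)), "n_stops": len(stop_times),
        })
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
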