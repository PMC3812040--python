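"""End-to-end orchestration of the analysis chains.

Two chains are supported, selected by the stages named in the config:

* image chain: mock-video rendering -> video analysis -> trace QC ->
  feature records;
* simulation chain: coupled-myosin simulation per condition -> feature
  records -> windowed bootstrap curves -> condition statistics (PCA
  separation, clustering, fold changes).

A config is a plain nested dict (load it from YAML if convenient); every
stage logs its timing and record counts and persists its outputs into a
:class:`~actomotility.store.ResultStore`.
"""

from __future__ import annotations

import json
import logging
import time

import numpy as np
import pandas as pd

from . import features as ft
from . import motorsim, mockvideo, stats, traceqc, videoanalysis
from .store import ResultStore

__all__ = ["run_pipeline"]

log = logging.getLogger("actomotility.pipeline")


def run_pipeline(config: dict, store: ResultStore) -> list:
    """Execute the stages named in ``config["stages"]``; return documents.

    Recognised stages: ``render``, ``analyze``, ``qc``, ``simulate``,
    ``features``, ``stats``.  Each stage reads its inputs either from the
    config or from the outputs of earlier stages in the same run.  On a
    stage failure the documents written so far are kept and the error is
    re-raised after a failure marker document is stored.
    """
    docs = []
    ctx: dict = {}
    seed = int(config.get("seed", 0))
    try:
        for stage in config["stages"]:
            t0 = time.time()
            handler = _STAGES[stage]
            docs.extend(handler(config.get(stage, {}), ctx, store, seed))
            log.info("stage %s finished in %.1f s", stage, time.time() - t0)
    except Exception as exc:  # persist partial results, flag the failure
        d = store.new_payload_dir("failure")
        with open(d / "error.json", "w") as fh:
            json.dump({"error": repr(exc)}, fh)
        store.write("failure", {"run": str(config.get("name", "run")),
                                "failed_stage": stage},
                    {"error": d / "error.json"}, config=config)
        raise
    return docs


def _write_csv(store, stage, tags, frames: dict, config, seeds):
    d = store.new_payload_dir(stage)
    paths = {}
    for name, df in frames.items():
        p = d / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return [store.write(stage, tags, paths, config=config, seeds=seeds)]


def _stage_render(cfg, ctx, store, seed):
    n = int(cfg.get("n_scenarios", 3))
    truth = mockvideo.crossing_scenario(n, seed + 1)
    optics = mockvideo.OpticsNoiseSpec(**cfg.get("optics", {}),
                                       shape_px=(256, 256))
    stack, truth = mockvideo.render(truth, optics, seed=seed + 2)
    ctx["stack"] = stack
    ctx["optics"] = optics
    ctx["truth"] = truth
    return _write_csv(store, "render", {"kind": "mock-video"},
                      {"truth": truth}, cfg, {"seed": seed})


def _stage_analyze(cfg, ctx, store, seed):
    optics = ctx["optics"]
    tracked = videoanalysis.analyze_stack(
        ctx["stack"], optics.frame_rate, optics.pixel_size_um,
        target_dt=cfg.get("dt", 1 / 3),
        bw_threshold=cfg.get("bw_threshold", 0.5))
    ctx["tracked"] = tracked
    return _write_csv(store, "analyze", {"kind": "traces"},
                      {"traces": tracked}, cfg, {"seed": seed})


def _stage_qc(cfg, ctx, store, seed):
    tracked = ctx["tracked"]
    dt = tracked.attrs.get("dt", 1 / 3)
    model = ctx.get("qc_model")
    if model is None:
        # train on a disjoint scripted scenario set ("different day")
        truth = mockvideo.crossing_scenario(
            int(cfg.get("n_train", 6)), seed + 11)
        stack, _ = mockvideo.render(truth, ctx["optics"], seed=seed + 12)
        tr = videoanalysis.analyze_stack(
            stack, ctx["optics"].frame_rate, ctx["optics"].pixel_size_um)
        ids, X = traceqc.featurize_all(tr, dt)
        y = traceqc.label_traces_from_truth(tr, truth, ids, dt=dt)
        model = traceqc.train(X, y, seed=seed + 13)
        ctx["qc_model"] = model
    accepted, qc_log = traceqc.filter_traces(model, tracked, dt)
    ctx["accepted"] = tracked[tracked["trace_id"].isin(accepted)]
    return _write_csv(store, "qc", {"kind": "qc-report"},
                      {"report": qc_log}, cfg, {"seed": seed})


def _stage_simulate(cfg, ctx, store, seed):
    base = motorsim.baseline_params()
    conds = cfg.get("conditions", ["baseline"])
    n = int(cfg.get("n_filaments", 150))
    T = float(cfg.get("T_s", 25.0))
    docs = []
    records = {}
    cut = None
    for i, name in enumerate(conds):
        params = motorsim.condition_params(name, base)
        rec = motorsim.simulate_condition(
            params, n, T, seed + 1000 * (i + 1), condition=name, cut=cut)
        if cut is None:
            cut = rec.attrs["cut_um_s"]  # share the baseline's velocity cut
        records[name] = rec
        docs += _write_csv(store, "simulate",
                           {"kind": "records", "condition": name},
                           {"records": rec}, cfg,
                           {"seed": seed + 1000 * (i + 1)})
    ctx["records"] = records
    return docs


def _stage_features(cfg, ctx, store, seed):
    B = int(cfg.get("bootstrap", 500))
    curve_sets = {}
    docs = []
    for name, rec in ctx["records"].items():
        cs = ft.bootstrap_curves(rec, B=B, seed=seed + hash(name) % 10000,
                                 condition=name)
        curve_sets[name] = cs
        d = store.new_payload_dir("features")
        p = d / "curves.json"
        cs.to_json(p)
        docs.append(store.write("features",
                                {"kind": "curves", "condition": name},
                                {"curves": p}, cfg, {"seed": cs.seed}))
    ctx["curves"] = curve_sets
    return docs


def _stage_stats(cfg, ctx, store, seed):
    curves = ctx["curves"]
    matrix = stats.assemble(curves)
    emb = stats.pca3(matrix)
    min_pts = min(np.sum((emb.row_condition == c) & ~emb.row_is_main)
                  for c in curves)
    sig = stats.pairwise_separation(emb, min_points=min(100, min_pts))
    k, assign, profile, comp = stats.hcluster(emb)
    d = store.new_payload_dir("stats")
    sig.to_csv(d / "significance.csv")
    comp.to_csv(d / "composition.csv")
    scores = pd.DataFrame(emb.scores, columns=["PC1", "PC2", "PC3"])
    scores["condition"] = emb.row_condition
    scores["is_main"] = emb.row_is_main
    scores.to_csv(d / "scores.csv", index=False)
    doc = store.write(
        "stats", {"kind": "stats"},
        {"significance": d / "significance.csv",
         "composition": d / "composition.csv",
         "scores": d / "scores.csv"},
        cfg, {"seed": seed})
    ctx["significance"] = sig
    ctx["clusters"] = (k, comp)
    return [doc]


_STAGES = {
    "render": _stage_render,
    "analyze": _stage_analyze,
    "qc": _stage_qc,
    "simulate": _stage_simulate,
    "features": _stage_features,
    "stats": _stage_stats,
}
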