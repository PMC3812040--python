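"""Train and validate the trace quality-control classifier across 'days'.

Two mock recording sessions are generated with different seeds (the
cross-day design): scripted clean, crossing and irregular-motion
filaments are rendered, tracked, featurised and labelled from the truth
tables.  A 150-tree bagged ensemble is trained on day one and validated
on day two; the acceptance threshold minimises an asymmetric cost
(keeping a bad trace costs 5, losing a good one costs 1).
"""

from actomotility import mockvideo as mv
from actomotility import traceqc as qc
from actomotility import videoanalysis as va


def recording_day(seed):
    truth = mv.crossing_scenario(8, seed, duration_s=4.0,
                                 fov_um=(40.96, 40.96))
    optics = mv.OpticsNoiseSpec(background_sd=4.0,
                                brightness_fluctuation_sd=0.15,
                                brownian_sigma_um=0.01,
                                shape_px=(512, 512))
    stack, truth = mv.render(truth, optics, seed=seed + 1)
    tracked = va.analyze_stack(stack, optics.frame_rate,
                               optics.pixel_size_um)
    ids, X = qc.featurize_all(tracked, 1 / 3)
    y = qc.label_traces_from_truth(tracked, truth, ids)
    return tracked, ids, X, y


_, _, X1, y1 = recording_day(11)
tracked2, ids2, X2, y2 = recording_day(77)
print(f"day 1: {len(y1)} traces ({y1.sum()} clean), "
      f"day 2: {len(y2)} traces ({y2.sum()} clean)")

model = qc.train(X1, y1, seed=0)
print("\nout-of-bag error vs tree count:")
print(model.oob_curve.to_string(index=False))

threshold, roc = qc.choose_threshold(model, X2, y2)
print(f"\ncross-day ROC AUC: {roc.attrs['auc']:.3f}")
print(f"cost-optimal acceptance threshold: {threshold:.2f} "
      f"(total cost {roc.attrs['total_cost']:.2f})")

accepted, log = qc.filter_traces(model, tracked2, 1 / 3,
                                 threshold=threshold)
print(f"\nday-2 filtering: {len(accepted)} of {log.shape[0]} traces kept; "
      "rejected traces cross other filaments or move irregularly.")
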