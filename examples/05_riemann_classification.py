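"""Classify motor-imagery-like epochs with RMDM and tangent-space SVM.

Epoch covariance matrices live on the SPD manifold; RMDM assigns each to
the class with the nearest Fréchet mean under the affine-invariant metric.
Tangent-space projection turns the same covariances into vectors any
standard classifier can use.
"""

from eegflow.riemann import crossvalidate, epoch_covariance, tangent_project
from eegflow.paradigm import ERPParams, build_erp_schedule, total_duration
from eegflow.signal_model import segment_epochs
from eegflow.synthgen import SynthSpec, gen_dataset

p = ERPParams(1.0, 0.5, 2.0, ["left", "right"], 80, weights=[0.5, 0.5])
sched = build_erp_schedule(p, seed=11)
spec = SynthSpec(8, 250.0, total_duration(p) + 1.0, sigma_uv=10.0, seed=11)
effects = {
    "left": {"kind": "variance", "channels": [0, 1], "sigma_uv": 15.0,
             "duration_s": 1.0},
    "right": {"kind": "variance", "channels": [6, 7], "sigma_uv": 15.0,
              "duration_s": 1.0},
}
rec, events, _ = gen_dataset(sched, spec, effects)
epochs = segment_epochs(rec, events, (0.0, 1.0))
covs = epoch_covariance(epochs, shrinkage=0.05)

rep = crossvalidate(covs, epochs.labels, {"model": "rmdm"}, k=5, seed=0)
print(f"RMDM      5-fold accuracy: {rep.mean_accuracy:.1f} %  "
      f"MCC: {rep.mean_mcc:.3f}")

feats = tangent_project(covs)
for name in ("svm", "rf", "nb", "dt"):
    rep = crossvalidate(feats, epochs.labels, {"model": name}, k=5, seed=0)
    print(f"tangent+{name:3s} 5-fold accuracy: {rep.mean_accuracy:.1f} %  "
          f"MCC: {rep.mean_mcc:.3f}")
# Near-perfect accuracy is expected: the planted variance contrast is the
# exact second-order structure these classifiers exploit.
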