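"""Grad-CAM: which image regions drive a prediction.

Trains a small classifier on three species and computes the class-activation
heatmap for one test image.  Mass should concentrate on the melt-transition
region — the only class-discriminative part of the curve.
"""

import numpy as np

from meltid.classify import TrainConfig, gradcam
from meltid.classify.protocol import load_arrays
from meltid.pipeline import run_experiment

result = run_experiment(
    n_species=5, n_per_species=12, n_unseen=0, seed=7, weak_fraction=0.0,
    train_config=TrainConfig(seed=7, epochs=20,
                             learning_rates=(1e-3,), weight_decays=(0.0,)))

model = result.model
X, y, run_ids, _ = load_arrays(result.manifest, "melt", "test",
                               model.class_names, model.input_size)
heat = gradcam(model, X[0])
s = model.input_size


def band(t_lo, t_hi):   # temperature -> pixel columns of the axes box
    return slice(int(s * (0.16 + 0.8 * (t_lo - 60) / 30)),
                 int(s * (0.16 + 0.8 * (t_hi - 60) / 30)))


probs = model.predict_proba(X[:1])[0]
print(f"run {run_ids[0]}: predicted {model.class_names[int(np.argmax(probs))]} "
      f"(confidence {probs.max():.3f})")
print(f"heatmap range          : [{heat.min():.2f}, {heat.max():.2f}]")
print(f"mean mass, 69-83 degC  : {heat[:, band(69, 83)].mean():.3f}  (melt transitions)")
print(f"mean mass, 86-90 degC  : {heat[:, band(86, 90)].mean():.3f}  (flat baseline)")
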