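"""Diagnose what the uncertainty estimate does and does not track.

Builds the per-compound diagnostics table (error, similarity to training
set, uncertainty, measurement count and spread) and computes the
correlations one would inspect before trusting the estimator: does
uncertainty rise when compounds are structurally novel?  Is it explained
away by how many measurements a compound has, or how scattered they are?
"""

import numpy as np

from uqscreen.analysis import build_diagnostics, correlate, group_by_count
from uqscreen.data_prep import curate
from uqscreen.mc_model import MLPConfig, predict_mc, train
from uqscreen.synth import SynthConfig, make_dataset

ds = make_dataset(
    SynthConfig(n_compounds=600, n_bits=128, n_clusters=8, noise_sd=0.2,
                measurements_mean=2.5, measurement_sd=0.2, seed=6)
)
curated, _ = curate(ds.records)
pos = {cid: i for i, cid in enumerate(ds.compound_ids)}
fps = ds.fps.subset([pos[c.compound_id] for c in curated])
labels = np.array([c.label for c in curated])

rng = np.random.default_rng(6)
test = np.sort(rng.choice(len(fps), size=120, replace=False))
tr = np.setdiff1d(np.arange(len(fps)), test)
model = train(fps.bits[tr], labels[tr], MLPConfig(epochs=30, seed=6))
pred = predict_mc(model, fps.bits[test], T=50, seed=7,
                  compound_ids=[fps.compound_ids[i] for i in test])

table = build_diagnostics(pred, labels[test], fps.subset(test), fps.subset(tr),
                          [curated[i] for i in test])

for x, y in [
    ("max_train_similarity", "uncertainty"),
    ("max_train_similarity", "squared_error"),
    ("uncertainty", "squared_error"),
    ("n_values", "uncertainty"),
    ("std_log_activity", "uncertainty"),
]:
    coef, n = correlate(table, x, y, "spearman")
    print(f"spearman({x}, {y}) = {coef:+.3f}  (n={n})")

print("\nuncertainty by number of reported measurements:")
print(group_by_count(table).to_string(index=False))
# Typical outcome: similarity correlates negatively with both error and
# uncertainty, while measurement count and spread show no strong
# relationship with uncertainty — it is a model-side, not data-side, signal.
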