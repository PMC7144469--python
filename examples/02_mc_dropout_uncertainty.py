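"""Train the dropout MLP and estimate per-compound prediction uncertainty.

Generates a clustered synthetic dataset, trains the regressor on 80% of the
compounds, and pushes the held-out 20% through the network 50 times with
dropout active.  The spread of those passes is the uncertainty estimate:
compounds structurally far from the training set should tend to spread more.
"""

import numpy as np

from uqscreen.data_prep import curate
from uqscreen.featurize import tanimoto_matrix
from uqscreen.mc_model import MLPConfig, evaluate, predict_mc, train
from uqscreen.synth import SynthConfig, make_dataset

ds = make_dataset(
    SynthConfig(n_compounds=600, n_bits=128, n_clusters=10, noise_sd=0.2,
                measurements_mean=2.0, measurement_sd=0.1, seed=0)
)
curated, _ = curate(ds.records)
pos = {cid: i for i, cid in enumerate(ds.compound_ids)}
fps = ds.fps.subset([pos[c.compound_id] for c in curated])
labels = np.array([c.label for c in curated])

rng = np.random.default_rng(0)
test = rng.choice(len(fps), size=len(fps) // 5, replace=False)
train_idx = np.setdiff1d(np.arange(len(fps)), test)

model = train(
    fps.bits[train_idx], labels[train_idx],
    MLPConfig(hidden_sizes=[500, 500, 200], epochs=30, seed=0),
)
pred = predict_mc(model, fps.bits[test], T=50, seed=1,
                  compound_ids=[fps.compound_ids[i] for i in test])
summary = evaluate(pred, labels[test])

print(f"deterministic MSE : {summary.mse:.4f}")
print(f"MC-dropout MSE    : {summary.dropout_mse:.4f}  (committee average, usually lower)")
print(f"mean uncertainty  : {summary.mean_uncertainty:.4f}  (log-Ki units)")

sims = tanimoto_matrix(fps.bits[test], fps.bits[train_idx]).max(axis=1)
near = pred.uncertainty[sims >= np.median(sims)].mean()
far = pred.uncertainty[sims < np.median(sims)].mean()
print(f"mean uncertainty, structurally-near half: {near:.4f}, far half: {far:.4f}")
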