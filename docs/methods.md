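# Methods

## Problem and model

The task is numerical regression of ligand binding affinity against a single
protein target: given a binary fingerprint x ∈ {0,1}^d of a compound,
predict its log-activity y = log₁₀ K_i [nM], and attach to every prediction
an uncertainty estimate usable for ranking decisions and for auditing the
training data itself.

The regressor is a fully connected network with three ReLU hidden layers of
500, 500 and 200 units and a linear scalar output. A dropout layer with
drop probability p = 0.5 follows every hidden layer; no other regularization
is used. Training minimizes mean squared error with Adam (learning rate
10⁻³, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) on mini-batches of 100 for a fixed
number of epochs (200 by default; the bundled studies use 50, see *Problem
sizes*). Weights are He-normal initialized; biases start at zero. The
implementation is plain NumPy in float32, with exact reproducibility given a
seed.

Uncertainty is Monte-Carlo dropout: at inference the dropout masks stay
active and each compound is passed through the network T times (default
T = 50) with independent masks. The MC prediction ŷᵢ is the mean over
passes; the uncertainty uᵢ is the sample standard deviation (ddof = 1) over
passes, chosen over the variance so that uᵢ shares the prediction's
log-activity units. Dropout uses the inverted convention (activations
scaled by 1/(1−p) during stochastic passes), so the deterministic pass
needs no rescaling and the p = 0 limit is exactly deterministic: uᵢ ≡ 0 and
ŷᵢ equals the single-pass prediction. The committee mean is usually the
better predictor — the studies below consistently show MC-mean MSE below
single-pass MSE — so ŷᵢ (column `y_mc`) is the primary prediction
throughout; the deterministic pass is retained for comparison.

## Curation conventions

- **Whitelist**: parameters {Ki, logKi, pKi, IC50, logIC50, pIC50};
  relations "=" only in strict mode, {=, <, >, ≤, ≥, ~} in extended mode;
  units {M, mM, µM, nM, pM, fM} for concentration parameters (none for
  log/p forms). Records failing a stage are dropped and counted per stage,
  never raised on.
- **Scale**: everything standardizes to log₁₀ K_i in nM (1 nM ↦ 0).
  IC50-family values are halved first (K_i = IC50/2, the competitive
  Cheng–Prusoff shortcut). p-forms convert algebraically:
  pKi ↦ 9 − pKi, pIC50 ↦ 9 − pIC50 − log₁₀2. Plain log-forms (logKi,
  logIC50) are **rejected** rather than guessed: their base and unit are not
  standardized across database exports, and a silent misread shifts labels
  by orders of magnitude.
- **Aggregation**: one label per compound, the mean of its standardized
  log-activities. The standard deviation uses the population convention
  (divide by n) so a single measurement has spread exactly 0 without
  special-casing. The nM-scale arithmetic mean is also emitted because
  database summaries are customarily quoted in nM; the regression label is
  the log-scale mean (averaging in log space is averaging of free energies,
  and is robust to the heavy right tail of nM values). Duplicate identical
  values count as separate measurements.

## Splits

Random k-fold CV (k = 5) shuffles compounds into near-equal folds. The BAC
split first builds an average-linkage dendrogram on Tanimoto distance
(1 − |A∧B|/|A∨B|), then decomposes it into subtrees by recursive capacity
splitting: any subtree larger than ceil(n/k) is replaced by its two
children, so a structurally coherent cluster is split only when it cannot
fit into one fold. Chunks are packed largest-first onto the currently
smallest fold (ties to the lowest fold index), with a final guarantee that
no fold is empty for n ≥ k. The recursive-subtree rule was chosen over a
fixed dendrogram cut (e.g. "cut to 3k clusters") because a fixed cut
over-splits well-separated clusters and the size-greedy packer can then put
fragments of one cluster into different folds — exactly the
train/test-contamination BAC exists to prevent. Consequence: fold sizes can
deviate from n/k when the cluster structure is lumpy; balance is secondary
to purity.

## Ranking

Lower R means ranked higher (more worth purchasing). With ũ, ỹ the min-max
normalized uncertainty and prediction over the test set:
baseline R = ŷ; add R = ŷ + u; scale R = ũ·ŷ; add-scaled R = ũ + ŷ;
sum-scaled R = ũ + ỹ; comb R = λŷ + (1−λ)u with λ ∈ [0,1] (swept over
{0, 0.1, …, 1} by default). Two normalization modes exist because the two
published conventions disagree: `minmax_range` = (v−min)/(max−min), which
actually spans [0,1] and is the default, and `minmax_over_max` =
(v−min)/max as sometimes printed. A constant vector normalizes to zeros in
both. The scale strategy emits a warning when predictions span negative
values (multiplying a signed score by ũ ∈ [0,1] rewards uncertain
negatives); it is applied verbatim rather than silently repaired.

Precision at top f (default f = 0.1) takes m = ceil(f·n), forms the set of
the m truly most-active compounds (lowest true log-K_i) and the m best-ranked
by R, and returns their overlap fraction. Ties in either ordering break by
compound id, making the metric deterministic.

## Suspect-record detection

For each test compound the squared error of ŷᵢ against the curated label is
compared with the distribution over the test set. "In the p-th percentile
(and higher)" is evaluated without interpolation: the percentile rank of a
value is the share of the sample **strictly below** it, and the criterion
passes when that rank reaches p — on n distinct errors at p = 95 this is
exactly the top 5%, and with all errors tied nobody passes a positive p.
The uncertainty criterion is directional and must be chosen explicitly:
`at_least` (uncertainty rank ≥ p, the literal reading) or `at_most`
(uncertainty in the bottom p percent — the "confidently wrong" reading that
concentrates on probable label errors; the enrichment study uses
`at_most` at the median). Each flagged compound is reported with its
reported activities and its N = 10 most Tanimoto-similar training compounds
and their labels — the evidence a curator would inspect.

## Synthetic data generator

The generator emulates the structure of curated single-target binding
datasets. Chemical space is clustered: each of c clusters (default 20) has
a random prototype bit pattern (d = 256 bits) and members flip each bit
with probability 0.05, giving high within- and low between-cluster
Tanimoto. The latent activity is a linear map over 64 informative bits,
optionally with 64 random pairwise bit-interaction terms ("bilinear"),
plus Gaussian landscape noise, affinely rescaled to mean 1.5 and sd 1.0
log units — i.e. a typical potency of ~30 nM spanning sub-nM to ~µM, the
range single-target ChEMBL sets occupy. Each compound receives a geometric
number of measurements (mean 2), each perturbed by measurement noise
(sd 0.1 log units in the bundled studies) and emitted as a raw record in a
randomized parameter/unit form — Ki in any of the six units, IC50 emitted
as 2·K_i so standardization inverts it exactly, pKi, or pIC50 — which
exercises every curation branch and round-trips to the latent scale at
float precision. Label corruption adds a fixed offset (default 2.0 log
units, a hundred-fold potency error) to all measurements of a Bernoulli-5%
subset of compounds, with ground-truth flags returned.

What the generator does **not** emulate: real substructure-activity
relationships (bits are exchangeable, unlike pharmacophoric features),
activity cliffs, assay-dependent systematic shifts, censored values behind
inequality relations, or inter-target promiscuity. Tests passing on this
generator therefore demonstrate the pipeline's mechanics and the
qualitative uncertainty phenomenology (harder splits → higher error and
uncertainty; planted errors → flaggable disagreement), not predictive
performance on real chemistry.

## Problem sizes and numerical choices

The bundled studies (test suite and `scripts/acceptance.py`) use n = 2000
compounds for the split-hardness and recovery studies and n = 1000 for the
corruption study, with 50 training epochs — sizes chosen so a full
multi-seed study runs in minutes on one CPU while keeping fold sizes (400
test compounds) large enough for stable percentile thresholds and top-decile
precision. Quartiles in the measurement-count summaries use linear
interpolation (NumPy default). Tanimoto of two all-zero fingerprints is
defined as 0 with a warning. All stochastic components consume
`numpy.random.default_rng` seeds derived from a single study seed; per-fold
model seeds are `seed·1000 + fold` reduced mod 2³¹.

## Known limitations

- The correlation analyses (uncertainty vs. measurement count or spread)
  are computed and bounded but deliberately not sign-asserted: on both
  synthetic and real data these relationships are weak and unstable, and
  encoding a sign would overfit the test suite to one generator.
- MC-dropout estimates epistemic uncertainty only; aleatoric (measurement)
  noise is visible in `std_log_activity` but not propagated into uᵢ.
- The literal `at_least` uncertainty criterion excludes almost nothing at
  low percentiles; it is kept as the default for fidelity to the published
  criterion, with the discriminating `at_most` variant one flag away.
- Backend threading can introduce float non-determinism across BLAS builds;
  tests compare with tolerances rather than bit equality where training is
  involved.
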