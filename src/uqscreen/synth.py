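"""Synthetic bioactivity data generator.

Emulates the structure of curated ChEMBL-style binding datasets so every
pipeline stage is testable without database downloads:

* **clustered chemical space** — compounds belong to scaffold-like clusters,
  each defined by a prototype bit pattern; members are the prototype with a
  small per-bit flip probability, so within-cluster Tanimoto is high and
  between-cluster Tanimoto low;
* **smooth activity landscape** — the latent log-activity (log10 Ki in nM)
  is a linear map over a fixed subset of informative bits, optionally with
  pairwise bit-interaction terms (``bilinear``), plus Gaussian landscape
  noise, rescaled to a realistic potency range (mean ≈ 1.5, sd ≈ 1 log
  units, i.e. ~30 nM typical, spanning sub-nM to ~µM);
* **repeated measurements** — each compound receives a geometric number of
  measurements (mean configurable), each perturbed by Gaussian measurement
  noise and emitted as a raw activity record in a randomized parameter/unit
  form (Ki in any of the six concentration units, IC50 = 2·Ki, pKi or
  pIC50), all of which standardize back to the same latent scale;
* **label corruption** — a configurable fraction of compounds has a constant
  log-unit offset added to all of its measurements, with the ground-truth
  corruption flags returned, so error-detection can be validated against
  known planted errors.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_prep import ActivityRecord, UNIT_TO_NM, LOG10_2
from .featurize import FingerprintMatrix

__all__ = ["SynthConfig", "SynthDataset", "gen_fingerprints", "gen_activities", "make_dataset"]

_UNITS = ("M", "mM", "µM", "nM", "pM", "fM")
_FORMS = ("Ki", "IC50", "pKi", "pIC50")


@dataclass
class SynthConfig:
    n_compounds: int = 2000
    n_bits: int = 256
    n_clusters: int = 20
    within_cluster_flip_prob: float = 0.05
    activity_model: str = "linear"  # or "bilinear"
    n_informative_bits: int = 64
    n_interactions: int = 64  # bilinear only: number of bit-pair terms
    noise_sd: float = 0.0  # landscape noise, log-activity units
    activity_mean: float = 1.5  # target latent mean, log10 nM
    activity_sd: float = 1.0  # target latent sd, log10 nM
    measurements_mean: float = 2.0  # geometric distribution mean, >= 1
    measurement_sd: float = 0.0  # per-measurement noise, log units
    corruption_fraction: float = 0.0
    corruption_offset: float = 2.0  # log units added to corrupted compounds
    randomize_forms: bool = True  # emit Ki/IC50/pKi/pIC50 in random units
    relation_mode: str = "strict"  # relations emitted: '=' only, or extended mix
    target_id: str = "SYNTH_TARGET"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.within_cluster_flip_prob <= 1.0:
            raise ValueError("flip probability must lie in [0, 1]")
        if not 0.0 <= self.corruption_fraction <= 1.0:
            raise ValueError("corruption_fraction must lie in [0, 1]")
        if self.n_clusters > self.n_compounds:
            raise ValueError("n_clusters must not exceed n_compounds")
        if self.activity_model not in ("linear", "bilinear"):
            raise ValueError("activity_model must be 'linear' or 'bilinear'")
        if self.measurements_mean < 1.0:
            raise ValueError("measurements_mean must be >= 1")


@dataclass
class SynthDataset:
    fps: FingerprintMatrix
    cluster_labels: np.ndarray
    latent: np.ndarray  # true log10(Ki nM) per compound, pre-corruption
    records: list[ActivityRecord]
    corrupted: np.ndarray  # bool per compound
    config: SynthConfig = field(repr=False, default=None)

    @property
    def compound_ids(self) -> list[str]:
        return self.fps.compound_ids


def gen_fingerprints(config: SynthConfig) -> tuple[FingerprintMatrix, np.ndarray]:
    """Clustered binary fingerprints: prototype patterns plus bit flips.

    Cluster sizes are near-equal; each member copies its cluster prototype
    and flips every bit independently with ``within_cluster_flip_prob``.
    Returns the matrix and the integer cluster label per compound.
    """
    rng = np.random.default_rng(config.seed)
    n, d, c = config.n_compounds, config.n_bits, config.n_clusters
    prototypes = (rng.random((c, d)) < 0.5).astype(np.uint8)
    labels = np.sort(np.arange(n) % c)
    bits = prototypes[labels]
    if config.within_cluster_flip_prob > 0:
        flips = rng.random((n, d)) < config.within_cluster_flip_prob
        bits = np.where(flips, 1 - bits, bits).astype(np.uint8)
    ids = [f"SYN{i:06d}" for i in range(n)]
    return FingerprintMatrix(ids, bits, "synthetic"), labels


def _latent_activities(bits: np.ndarray, config: SynthConfig, rng) -> np.ndarray:
    d = bits.shape[1]
    n_inf = min(config.n_informative_bits, d)
    informative = rng.choice(d, size=n_inf, replace=False)
    w = rng.standard_normal(n_inf)
    raw = bits[:, informative].astype(np.float64) @ w
    if config.activity_model == "bilinear":
        pairs = rng.choice(d, size=(config.n_interactions, 2))
        v = rng.standard_normal(config.n_interactions)
        raw = raw + (bits[:, pairs[:, 0]] * bits[:, pairs[:, 1]]).astype(np.float64) @ v
    if config.noise_sd > 0:
        raw = raw + rng.normal(0.0, config.noise_sd, size=raw.shape)
    # rescale to a realistic potency range; landscape shape is preserved
    sd = raw.std()
    if sd > 0:
        raw = (raw - raw.mean()) / sd * config.activity_sd
    else:
        raw = raw - raw.mean()
    return raw + config.activity_mean


def _emit_record(rid, cid, target, log_nm, form, unit, relation) -> ActivityRecord:
    """One raw record in the requested parameter form; inverts exactly under
    standardization (IC50 is emitted as 2×Ki; p-forms as 9 − log10 nM)."""
    if form == "Ki":
        value = 10.0 ** log_nm / UNIT_TO_NM[unit]
        return ActivityRecord(rid, cid, target, "Ki", relation, value, unit)
    if form == "IC50":
        value = 2.0 * 10.0 ** log_nm / UNIT_TO_NM[unit]
        return ActivityRecord(rid, cid, target, "IC50", relation, value, unit)
    if form == "pKi":
        return ActivityRecord(rid, cid, target, "pKi", relation, 9.0 - log_nm, None)
    if form == "pIC50":
        return ActivityRecord(rid, cid, target, "pIC50", relation, 9.0 - log_nm - LOG10_2, None)
    raise ValueError(form)


def gen_activities(
    fps: FingerprintMatrix, config: SynthConfig
) -> tuple[np.ndarray, list[ActivityRecord], np.ndarray]:
    """Latent activities, raw measurement records and corruption flags.

    Each compound gets ≥1 measurement: latent + N(0, measurement_sd), in a
    randomized parameter/unit form when ``randomize_forms`` (otherwise Ki in
    nM).  Corrupted compounds have ``corruption_offset`` added to every
    measurement; the returned latent is the uncorrupted ground truth.
    """
    rng = np.random.default_rng(config.seed + 1)
    latent = _latent_activities(fps.bits, config, rng)
    n = len(fps)
    corrupted = rng.random(n) < config.corruption_fraction

    if config.measurements_mean == 1.0:
        counts = np.ones(n, dtype=np.int64)
    else:
        counts = rng.geometric(1.0 / config.measurements_mean, size=n)

    extended_relations = ("=", "<", ">", "≤", "≥", "~")
    records: list[ActivityRecord] = []
    rid = 0
    for i, cid in enumerate(fps.compound_ids):
        for _ in range(int(counts[i])):
            m = latent[i]
            if config.measurement_sd > 0:
                m += rng.normal(0.0, config.measurement_sd)
            if corrupted[i]:
                m += config.corruption_offset
            if config.randomize_forms:
                form = _FORMS[rng.integers(len(_FORMS))]
                unit = _UNITS[rng.integers(len(_UNITS))]
            else:
                form, unit = "Ki", "nM"
            if config.relation_mode == "extended":
                relation = extended_relations[rng.integers(len(extended_relations))]
            else:
                relation = "="
            records.append(
                _emit_record(f"R{rid:07d}", cid, config.target_id, m, form, unit, relation)
            )
            rid += 1
    return latent, records, corrupted


def make_dataset(config: SynthConfig | None = None) -> SynthDataset:
    """Generate fingerprints, activities and raw records in one call."""
    config = config or SynthConfig()
    fps, labels = gen_fingerprints(config)
    latent, records, corrupted = gen_activities(fps, config)
    return SynthDataset(fps, labels, latent, records, corrupted, config)
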