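"""Detection of suspect activity records by joint error/uncertainty percentiles.

A compound whose prediction error is extreme while its MC-dropout
uncertainty is informative may indicate a mislabeled database record rather
than a model failure.  A test compound is flagged when its squared error
(MC-mean prediction vs. curated label) reaches at least the ``error_pctl``
percentile of all test errors AND its uncertainty satisfies a directional
threshold at the ``unc_pctl`` percentile.

The literal criterion — uncertainty at or above the 5th percentile — keeps
nearly every compound, so the direction is an explicit, logged choice:
``at_least`` (the literal reading, the default) or ``at_most``
(low-uncertainty = confidently-wrong, the reading that concentrates on
probable label errors).

"In the p-th percentile (and higher)" is evaluated without interpolation: a
compound's percentile rank is the share of the sample *strictly below* its
value, and it passes when that rank reaches p.  On n distinct values at
p = 95 this selects exactly the top 5%.  The rule makes ties deterministic:
with all errors identical, every rank is 0, so no compound passes a
positive error percentile.

For each flagged compound a neighbor context is provided: the N most
Tanimoto-similar training compounds with their labels, the evidence a
curator would inspect.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_prep import CuratedCompound
from .featurize import FingerprintMatrix, tanimoto_matrix
from .mc_model import PredictionSet

__all__ = ["SuspectRecord", "SuspectReport", "flag_suspects", "neighbor_context"]


@dataclass
class SuspectRecord:
    compound_id: str
    squared_error: float
    uncertainty: float
    error_percentile: float
    uncertainty_percentile: float
    reported_activities: list[float] = field(default_factory=list)
    nearest_neighbors: list[dict] = field(default_factory=list)


@dataclass
class SuspectReport:
    flagged: list[SuspectRecord]
    error_pctl: float
    unc_pctl: float
    unc_direction: str
    n_test: int

    @property
    def flagged_ids(self) -> list[str]:
        return [r.compound_id for r in self.flagged]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.flagged],
                "squared_error": [r.squared_error for r in self.flagged],
                "uncertainty": [r.uncertainty for r in self.flagged],
                "error_percentile": [r.error_percentile for r in self.flagged],
                "uncertainty_percentile": [r.uncertainty_percentile for r in self.flagged],
            }
        )

    def to_json(self, path) -> None:
        payload = {
            "error_pctl": self.error_pctl,
            "unc_pctl": self.unc_pctl,
            "unc_direction": self.unc_direction,
            "n_test": self.n_test,
            "flagged": [
                {
                    "compound_id": r.compound_id,
                    "squared_error": r.squared_error,
                    "uncertainty": r.uncertainty,
                    "error_percentile": r.error_percentile,
                    "uncertainty_percentile": r.uncertainty_percentile,
                    "reported_activities": r.reported_activities,
                    "nearest_neighbors": r.nearest_neighbors,
                }
                for r in self.flagged
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def nearest_rank_percentile(values: np.ndarray, pctl: float) -> float:
    """Nearest-rank percentile: smallest value with cumulative share ≥ pctl."""
    values = np.sort(np.asarray(values, dtype=np.float64))
    n = values.size
    if n == 0:
        raise ValueError("empty sample")
    if pctl <= 0:
        return float(values[0])
    rank = int(np.ceil(pctl / 100.0 * n))
    return float(values[min(rank, n) - 1])


def _percentile_rank(values: np.ndarray) -> np.ndarray:
    """Percentile rank: share of the sample strictly below each value, in [0, 100]."""
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    counts_below = np.searchsorted(np.sort(values), values, side="left")
    return 100.0 * counts_below / n


def flag_suspects(
    pred: PredictionSet,
    y_true,
    error_pctl: float = 95.0,
    unc_pctl: float = 5.0,
    unc_direction: str = "at_least",
    curated: list[CuratedCompound] | None = None,
) -> SuspectReport:
    """Flag compounds with extreme error and threshold-passing uncertainty.

    A compound passes the error criterion when the share of squared errors
    strictly below its own reaches ``error_pctl``.  ``unc_direction=
    'at_least'`` (the literal criterion) requires the uncertainty percentile
    rank to reach ``unc_pctl``; ``'at_most'`` requires the share strictly
    above to reach ``100 − unc_pctl`` (i.e. uncertainty in the bottom
    ``unc_pctl`` percent).
    """
    if unc_direction not in ("at_least", "at_most"):
        raise ValueError("unc_direction must be 'at_least' or 'at_most'")
    if not (0 <= error_pctl <= 100 and 0 <= unc_pctl <= 100):
        raise ValueError("percentiles must lie in [0, 100]")
    y = np.asarray(y_true, dtype=np.float64)
    if y.shape != pred.y_mc.shape:
        raise ValueError("y_true must align with predictions")
    n = y.size
    if n < 20:
        warnings.warn(
            f"only {n} test compounds: percentile thresholds are unstable",
            stacklevel=2,
        )

    sq_err = (pred.y_mc - y) ** 2
    unc = pred.uncertainty
    err_ranks = _percentile_rank(sq_err)
    unc_ranks = _percentile_rank(unc)
    unc_above = 100.0 * np.searchsorted(np.sort(unc), unc, side="right") / n
    # unc_above is the share ≤ each value; strictly-above share is its complement
    unc_above = 100.0 - unc_above

    err_ok = err_ranks >= error_pctl
    if unc_direction == "at_least":
        unc_ok = unc_ranks >= unc_pctl
    else:
        unc_ok = unc_above >= 100.0 - unc_pctl
    mask = err_ok & unc_ok
    activities = {}
    if curated is not None:
        activities = {c.compound_id: list(c.log_activities) for c in curated}

    flagged = [
        SuspectRecord(
            compound_id=pred.compound_ids[i],
            squared_error=float(sq_err[i]),
            uncertainty=float(unc[i]),
            error_percentile=float(err_ranks[i]),
            uncertainty_percentile=float(unc_ranks[i]),
            reported_activities=activities.get(pred.compound_ids[i], []),
        )
        for i in np.flatnonzero(mask)
    ]
    return SuspectReport(flagged, error_pctl, unc_pctl, unc_direction, n)


def neighbor_context(
    flagged_ids: list[str],
    fps_flagged: FingerprintMatrix,
    fps_train: FingerprintMatrix,
    curated_train: list[CuratedCompound],
    N: int = 10,
) -> dict[str, list[dict]]:
    """Top-N Tanimoto-similar training compounds for each flagged compound.

    Returns {flagged_id: [{compound_id, tanimoto, label}, ...]} sorted by
    descending similarity (ties by compound_id).  When fewer than N training
    compounds exist, all are returned with a warning.
    """
    pos = {cid: i for i, cid in enumerate(fps_flagged.compound_ids)}
    missing = [cid for cid in flagged_ids if cid not in pos]
    if missing:
        raise ValueError(f"flagged compounds missing fingerprints: {missing}")
    labels = {c.compound_id: c.label for c in curated_train}
    n_train = len(fps_train)
    if N > n_train:
        warnings.warn(
            f"requested {N} neighbors but training set has {n_train}; returning all",
            stacklevel=2,
        )
    idx = np.array([pos[cid] for cid in flagged_ids], dtype=int)
    sims = tanimoto_matrix(fps_flagged.bits[idx], fps_train.bits)

    out: dict[str, list[dict]] = {}
    train_ids = np.asarray(fps_train.compound_ids)
    for row, cid in enumerate(flagged_ids):
        order = np.lexsort((train_ids, -sims[row]))[: min(N, n_train)]
        out[cid] = [
            {
                "compound_id": str(train_ids[j]),
                "tanimoto": float(sims[row, j]),
                "label": labels.get(str(train_ids[j])),
            }
            for j in order
        ]
    return out
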