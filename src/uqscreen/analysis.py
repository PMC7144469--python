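"""Uncertainty diagnostics: error vs. similarity vs. uncertainty tables.

Builds, per test compound, the quantities whose joint behaviour characterizes
an uncertainty estimator: squared prediction error, maximum Tanimoto
similarity to the training set (the applicability-domain signal), MC-dropout
uncertainty, and the measurement metadata of the compound's curated record
(number of reported activity values and their standard deviation).

Correlations between these columns, and per-measurement-count box-plot
summaries, are how one checks whether uncertainty tracks data spread or data
volume — findings that are empirical, not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_prep import CuratedCompound
from .featurize import FingerprintMatrix, tanimoto_matrix
from .mc_model import PredictionSet

__all__ = [
    "DiagnosticsTable",
    "UndefinedCorrelationError",
    "build_diagnostics",
    "correlate",
    "group_by_count",
    "plot_diagnostics",
]

COLUMNS = (
    "squared_error",
    "max_train_similarity",
    "uncertainty",
    "n_values",
    "std_log_activity",
)


class UndefinedCorrelationError(ValueError):
    """A correlation requested on a zero-variance column."""


@dataclass
class DiagnosticsTable:
    frame: pd.DataFrame  # one row per test compound, indexed by compound_id

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"diagnostics table missing columns: {missing}")
        sim = self.frame["max_train_similarity"]
        if ((sim < 0) | (sim > 1)).any():
            raise ValueError("similarity must lie in [0, 1]")
        if self.frame[list(COLUMNS)].isna().any().any():
            raise ValueError("diagnostics table must have no missing values")


def build_diagnostics(
    pred: PredictionSet,
    y_true,
    fps_test: FingerprintMatrix,
    fps_train: FingerprintMatrix,
    curated: list[CuratedCompound],
) -> DiagnosticsTable:
    """Assemble the per-test-compound diagnostics table.

    Every test compound must have a fingerprint row and a curated record;
    a missing fingerprint is an error naming the compound.
    """
    y = np.asarray(y_true, dtype=np.float64)
    fp_pos = {cid: i for i, cid in enumerate(fps_test.compound_ids)}
    meta = {c.compound_id: c for c in curated}
    missing_fp = [cid for cid in pred.compound_ids if cid not in fp_pos]
    if missing_fp:
        raise ValueError(f"compounds missing fingerprints: {missing_fp}")
    missing_meta = [cid for cid in pred.compound_ids if cid not in meta]
    if missing_meta:
        raise ValueError(f"compounds missing curated records: {missing_meta}")

    idx = np.array([fp_pos[cid] for cid in pred.compound_ids], dtype=int)
    sims = tanimoto_matrix(fps_test.bits[idx], fps_train.bits).max(axis=1)

    frame = pd.DataFrame(
        {
            "squared_error": (pred.y_mc - y) ** 2,
            "max_train_similarity": sims,
            "uncertainty": pred.uncertainty,
            "n_values": [meta[cid].n_values for cid in pred.compound_ids],
            "std_log_activity": [meta[cid].std_log_activity for cid in pred.compound_ids],
        },
        index=pd.Index(pred.compound_ids, name="compound_id"),
    )
    return DiagnosticsTable(frame)


def correlate(
    table: DiagnosticsTable, x: str, y: str, method: str = "pearson"
) -> tuple[float, int]:
    """Pearson or Spearman correlation between two diagnostics columns.

    Returns (coefficient, n).  A zero-variance column raises
    :class:`UndefinedCorrelationError` instead of propagating NaN.
    """
    if x not in COLUMNS or y not in COLUMNS:
        raise ValueError(f"columns must be among {COLUMNS}")
    xv = table.frame[x].to_numpy(dtype=np.float64)
    yv = table.frame[y].to_numpy(dtype=np.float64)
    n = xv.size
    if n < 3:
        raise ValueError("need at least 3 rows for a correlation")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedCorrelationError(
            f"correlation of {x!r} vs {y!r} undefined: zero variance"
        )
    if method == "pearson":
        coef = stats.pearsonr(xv, yv).statistic
    elif method == "spearman":
        coef = stats.spearmanr(xv, yv).statistic
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(coef), n


def group_by_count(table: DiagnosticsTable, value: str = "uncertainty") -> pd.DataFrame:
    """Box-plot summary of ``value`` per distinct measurement count.

    One row per distinct ``n_values``: group size, min, first quartile,
    median, third quartile, max.  Quartiles use linear interpolation.
    ``single_member`` marks groups of one compound (no box to draw).
    """
    rows = []
    for n_vals, grp in table.frame.groupby("n_values", sort=True):
        v = grp[value].to_numpy(dtype=np.float64)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            {
                "n_values": int(n_vals),
                "group_size": v.size,
                "min": float(v.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(v.max()),
                "single_member": v.size == 1,
            }
        )
    return pd.DataFrame(rows)


def plot_diagnostics(table: DiagnosticsTable, path=None):
    """Convenience scatter/box renderings of the diagnostics (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    f = table.frame
    axes[0].scatter(f["max_train_similarity"], f["squared_error"], s=8, alpha=0.5)
    axes[0].set_xlabel("max Tanimoto to training set")
    axes[0].set_ylabel("squared error")
    axes[1].scatter(f["max_train_similarity"], f["uncertainty"], s=8, alpha=0.5)
    axes[1].set_xlabel("max Tanimoto to training set")
    axes[1].set_ylabel("uncertainty")
    groups = [g["uncertainty"].to_numpy() for _, g in f.groupby("n_values")]
    labels = sorted(f["n_values"].unique())
    axes[2].boxplot(groups, tick_labels=[str(x) for x in labels])
    axes[2].set_xlabel("number of activity values")
    axes[2].set_ylabel("uncertainty")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
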