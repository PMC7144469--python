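"""Uncertainty-augmented compound ranking and precision-at-top-k evaluation.

Compounds are ranked for virtual screening by a score R(ŷ_i, u_i) built from
the predicted log-activity ŷ_i (lower = more potent) and the MC-dropout
uncertainty u_i; lower R means higher in the ranking.  Six strategies:

    baseline     R = ŷ
    add          R = ŷ + u
    scale        R = ũ · ŷ
    add_scaled   R = ũ + ŷ
    sum_scaled   R = ũ + ỹ
    comb         R = λ·ŷ + (1 − λ)·u

where ũ, ỹ are min-max-normalized over the test set.  Two normalization
conventions coexist in the source formulation: the stated intent, range
exactly [0, 1] via (v − min)/(max − min), and the formula as literally
printed, (v − min)/max.  Both are implemented; ``minmax_range`` is the
default.

Rankings are scored by precision at top 10%: the overlap fraction between
the truly most-active top decile and the predicted top decile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RankingInput",
    "RankingConfig",
    "RankingResult",
    "STRATEGIES",
    "normalize",
    "rank",
    "precision_at_top",
    "strategy_comparison",
]

STRATEGIES = ("baseline", "add", "scale", "add_scaled", "sum_scaled", "comb")
NORMALIZATIONS = ("minmax_range", "minmax_over_max")


@dataclass
class RankingInput:
    compound_ids: list[str]
    y_hat: np.ndarray  # predicted log-activity, lower = more active
    u: np.ndarray  # uncertainty, >= 0
    y_true: np.ndarray | None = None

    def __post_init__(self):
        self.y_hat = np.asarray(self.y_hat, dtype=np.float64)
        self.u = np.asarray(self.u, dtype=np.float64)
        n = len(self.compound_ids)
        if self.y_hat.shape != (n,) or self.u.shape != (n,):
            raise ValueError("y_hat and u must be aligned with compound_ids")
        if (self.u < 0).any():
            raise ValueError("uncertainties must be non-negative")
        if self.y_true is not None:
            self.y_true = np.asarray(self.y_true, dtype=np.float64)
            if self.y_true.shape != (n,):
                raise ValueError("y_true must be aligned with compound_ids")


@dataclass
class RankingConfig:
    strategy: str = "baseline"
    lam: float | None = None  # λ, comb only
    normalization: str = "minmax_range"

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.strategy == "comb":
            if self.lam is None or not 0.0 <= self.lam <= 1.0:
                raise ValueError("comb requires lambda in [0, 1]")
        elif self.lam is not None:
            raise ValueError("lambda only applies to the comb strategy")


@dataclass
class RankingResult:
    compound_ids: list[str]
    R: np.ndarray
    order: np.ndarray = field(init=False)  # indices sorting R ascending

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=np.float64)
        # ties broken by compound_id, then index, for determinism
        ids = np.asarray(self.compound_ids)
        self.order = np.lexsort((np.arange(len(ids)), ids, self.R))

    def top(self, m: int) -> list[str]:
        return [self.compound_ids[i] for i in self.order[:m]]


def normalize(v, mode: str = "minmax_range") -> np.ndarray:
    """Min-max normalize a vector.

    ``minmax_range``: (v − min)/(max − min), exact range [0, 1].
    ``minmax_over_max``: (v − min)/max — the literally-printed convention.
    A constant vector maps to all zeros in both modes.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.size < 1:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = v.min(), v.max()
    if mode == "minmax_range":
        if hi == lo:
            return np.zeros_like(v)
        return (v - lo) / (hi - lo)
    if mode == "minmax_over_max":
        if hi == 0:
            if lo != hi:
                warnings.warn(
                    "minmax_over_max with max == 0: returning zeros", stacklevel=2
                )
            return np.zeros_like(v)
        if hi == lo:
            return np.zeros_like(v)
        return (v - lo) / hi
    raise ValueError(f"unknown normalization mode {mode!r}")


def rank(inp: RankingInput, config: RankingConfig | None = None) -> RankingResult:
    """Score compounds with the configured strategy; lower R ranks higher."""
    config = config or RankingConfig()
    y, u = inp.y_hat, inp.u
    s = config.strategy
    if s == "baseline":
        R = y.copy()
    elif s == "add":
        R = y + u
    elif s == "scale":
        if (y < 0).any():
            warnings.warn(
                "scale strategy with negative predicted activities: the "
                "ũ·ŷ product rewards uncertain negatives",
                stacklevel=2,
            )
        R = normalize(u, config.normalization) * y
    elif s == "add_scaled":
        R = normalize(u, config.normalization) + y
    elif s == "sum_scaled":
        R = normalize(u, config.normalization) + normalize(y, config.normalization)
    elif s == "comb":
        R = config.lam * y + (1.0 - config.lam) * u
    else:  # pragma: no cover - guarded by RankingConfig
        raise ValueError(s)
    return RankingResult(list(inp.compound_ids), R)


def _top_set(values: np.ndarray, ids, m: int) -> set:
    """Indices of the m smallest values, ties broken by compound_id."""
    order = np.lexsort((np.arange(len(ids)), np.asarray(ids), values))
    return set(order[:m])


def precision_at_top(y_true, R, fraction: float = 0.1, compound_ids=None) -> float:
    """Overlap fraction between true and predicted top-m sets, m = ceil(f·n).

    The "true" top-m are the compounds with the lowest true log-activity
    (most potent); the predicted top-m are the lowest ranking scores R.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    n = y_true.size
    if n == 0:
        raise ValueError("empty input")
    if y_true.shape != R.shape:
        raise ValueError("y_true and R must be aligned")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if compound_ids is None:
        compound_ids = [str(i) for i in range(n)]
    m = int(np.ceil(fraction * n))
    top_true = _top_set(y_true, compound_ids, m)
    top_pred = _top_set(R, compound_ids, m)
    return len(top_true & top_pred) / m


def strategy_comparison(
    inp: RankingInput,
    fraction: float = 0.1,
    lam_grid=tuple(np.round(np.arange(0.0, 1.01, 0.1), 10)),
    normalization: str = "minmax_range",
) -> dict[str, float]:
    """Precision at top-``fraction`` for every strategy (comb over a λ grid).

    Requires ``y_true`` in the input.  Returns {strategy_name: precision},
    with comb entries keyed ``comb_λ=<value>``.
    """
    if inp.y_true is None:
        raise ValueError("strategy comparison requires true activities")
    out: dict[str, float] = {}
    for s in STRATEGIES:
        if s == "comb":
            for lam in lam_grid:
                cfg = RankingConfig(strategy="comb", lam=float(lam), normalization=normalization)
                res = rank(inp, cfg)
                out[f"comb_lam={lam:g}"] = precision_at_top(
                    inp.y_true, res.R, fraction, inp.compound_ids
                )
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = rank(inp, RankingConfig(strategy=s, normalization=normalization))
            out[s] = precision_at_top(inp.y_true, res.R, fraction, inp.compound_ids)
    return out
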