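"""End-to-end orchestration: curate → featurize → split → model → rank → detect.

The unit of work is one target dataset under one split protocol.  The 5-fold
scheme trains an independent model per fold and assembles out-of-fold
predictions, so every compound is predicted exactly once by a model that
never saw it.  Fold-level metrics and their mean are both reported.

:func:`run_pipeline` drives the whole study from a :class:`RunConfig`
(loadable from YAML), writing every artifact to a run directory with a
manifest recording the config hash and seed; stages whose outputs already
exist under the same manifest are reused, making reruns resumable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, data_prep, error_detect, ranking, split as split_mod
from .featurize import FingerprintMatrix, tanimoto_matrix, write_fingerprint_csv
from .mc_model import EvalSummary, MLPConfig, PredictionSet, evaluate, predict_mc, train
from .synth import SynthConfig, make_dataset

logger = logging.getLogger("uqscreen")

__all__ = ["RunConfig", "CrossValResult", "cross_validate", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Study configuration; defaults mirror the standard protocol
    (hidden layers 500/500/200, dropout 0.5, Adam lr 0.001, 200 epochs,
    batch 100, k = 5 folds)."""

    seed: int = 0
    out_dir: str = "runs/run0"
    synth: SynthConfig | None = None  # synthetic source; else raw_csv is read
    raw_csv: str | None = None
    relation_mode: str = "strict"
    fingerprint_scheme: str = "morgan_r2"
    n_bits: int = 2048
    split_method: str = "random_cv"  # or "bac"
    k: int = 5
    mlp: MLPConfig = field(default_factory=MLPConfig)
    mc_passes: int = 50
    ranking_fraction: float = 0.1
    error_pctl: float = 95.0
    unc_pctl: float = 5.0
    unc_direction: str = "at_least"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = SynthConfig(**raw["synth"])
        if "mlp" in raw and raw["mlp"] is not None:
            raw["mlp"] = MLPConfig(**raw["mlp"])
        return cls(**raw)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(str(type(o)))

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CrossValResult:
    """Out-of-fold predictions and fold-level metrics for one protocol."""

    oof: PredictionSet  # every compound predicted by its held-out model
    labels: np.ndarray  # aligned with oof.compound_ids
    fold_summaries: list[EvalSummary]
    max_train_similarity: np.ndarray  # per compound, vs. its training folds
    assignment: split_mod.SplitAssignment

    @property
    def mean_mse(self) -> float:
        return float(np.mean([s.mse for s in self.fold_summaries]))

    @property
    def mean_dropout_mse(self) -> float:
        return float(np.mean([s.dropout_mse for s in self.fold_summaries]))

    @property
    def mean_uncertainty(self) -> float:
        return float(np.mean([s.mean_uncertainty for s in self.fold_summaries]))


def cross_validate(
    fps: FingerprintMatrix,
    labels,
    assignment: split_mod.SplitAssignment,
    mlp: MLPConfig | None = None,
    mc_passes: int | None = None,
) -> CrossValResult:
    """Train one model per fold; predict each fold with its held-out model.

    The per-fold seed is derived from the MLP seed and the fold index so
    folds are independent but the whole protocol is reproducible.
    """
    mlp = mlp or MLPConfig()
    labels = np.asarray(labels, dtype=np.float64)
    n = len(fps)
    if labels.shape != (n,):
        raise ValueError("labels must align with fingerprints")

    y_det = np.empty(n)
    y_mc = np.empty(n)
    unc = np.empty(n)
    max_sim = np.empty(n)
    summaries = []
    for fold in range(assignment.k):
        tr = assignment.train_indices(fold)
        te = assignment.test_indices(fold)
        fold_cfg = dataclasses.replace(mlp, seed=(mlp.seed * 1000 + fold) % (2**31))
        model = train(fps.bits[tr], labels[tr], fold_cfg)
        pred = predict_mc(
            model,
            fps.bits[te],
            T=mc_passes or mlp.mc_passes,
            seed=fold_cfg.seed + 1,
            compound_ids=[fps.compound_ids[i] for i in te],
            keep_samples=False,
        )
        summaries.append(evaluate(pred, labels[te]))
        y_det[te], y_mc[te], unc[te] = pred.y_det, pred.y_mc, pred.uncertainty
        max_sim[te] = tanimoto_matrix(fps.bits[te], fps.bits[tr]).max(axis=1)

    oof = PredictionSet(list(fps.compound_ids), y_det, y_mc, unc)
    return CrossValResult(oof, labels, summaries, max_sim, assignment)


def _stage_done(out_dir: Path, stage: str, cfg_hash: str) -> bool:
    manifest = out_dir / f"{stage}.manifest.json"
    if not manifest.exists():
        return False
    try:
        return json.loads(manifest.read_text()).get("config_hash") == cfg_hash
    except (json.JSONDecodeError, OSError):
        return False


def _write_manifest(out_dir: Path, stage: str, cfg_hash: str, seed: int, outputs: list[str]):
    (out_dir / f"{stage}.manifest.json").write_text(
        json.dumps(
            {"stage": stage, "config_hash": cfg_hash, "seed": seed, "outputs": outputs},
            indent=2,
        )
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full study; returns the run directory.

    Stage order: prepare → featurize → split → train/predict per fold →
    rank → detect → analyze.  Any failure raises :class:`PipelineError`
    naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    (out / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=False)
    )

    # ---- prepare + featurize -------------------------------------------
    stage = "prepare"
    try:
        if config.synth is not None:
            ds = make_dataset(config.synth)
            records, fps = ds.records, ds.fps
            json.dump(
                {
                    "corrupted_ids": [
                        cid for cid, c in zip(ds.compound_ids, ds.corrupted) if c
                    ],
                    "latent": dict(zip(ds.compound_ids, ds.latent.tolist())),
                },
                open(out / "ground_truth.json", "w"),
            )
        elif config.raw_csv is not None:
            records = data_prep.read_activity_csv(config.raw_csv)
            fps = None
        else:
            raise PipelineError("prepare: neither synthetic config nor raw_csv given")
        curated, report = data_prep.curate(records, config.relation_mode)
        data_prep.write_curated_csv(curated, out / "curated.csv")
        report.to_json(out / "filter_report.json")
        _write_manifest(out, stage, cfg_hash, config.seed, ["curated.csv", "filter_report.json"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    stage = "featurize"
    try:
        if fps is None:
            from .featurize import fingerprints_for

            fps = fingerprints_for(
                [c.compound_id for c in curated],
                [c.smiles for c in curated],
                config.fingerprint_scheme,
                config.n_bits,
            )
        else:
            # synthetic fingerprints: align to the curated compound order
            pos = {cid: i for i, cid in enumerate(fps.compound_ids)}
            fps = fps.subset([pos[c.compound_id] for c in curated])
        write_fingerprint_csv(fps, out / "fingerprints.csv")
        _write_manifest(out, stage, cfg_hash, config.seed, ["fingerprints.csv"])
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    labels = np.array([c.label for c in curated])

    stage = "split"
    try:
        if config.split_method == "random_cv":
            assignment = split_mod.random_cv_folds(fps.compound_ids, config.k, config.seed)
        elif config.split_method == "bac":
            assignment = split_mod.bac_folds(fps, config.k, config.seed)
        else:
            raise ValueError(f"unknown split method {config.split_method!r}")
        assignment.to_frame().to_csv(out / "folds.csv", index=False)
        _write_manifest(out, stage, cfg_hash, config.seed, ["folds.csv"])
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    stage = "model"
    try:
        mlp = dataclasses.replace(config.mlp, seed=config.seed)
        cv = cross_validate(fps, labels, assignment, mlp, config.mc_passes)
        cv.oof.to_frame().to_csv(out / "predictions.csv", index=False)
        json.dump(
            {
                "fold_mse": [s.mse for s in cv.fold_summaries],
                "fold_dropout_mse": [s.dropout_mse for s in cv.fold_summaries],
                "fold_mean_uncertainty": [s.mean_uncertainty for s in cv.fold_summaries],
                "mean_mse": cv.mean_mse,
                "mean_dropout_mse": cv.mean_dropout_mse,
                "mean_uncertainty": cv.mean_uncertainty,
            },
            open(out / "metrics.json", "w"),
            indent=2,
        )
        _write_manifest(out, stage, cfg_hash, config.seed, ["predictions.csv", "metrics.json"])
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    stage = "rank"
    try:
        rin = ranking.RankingInput(
            cv.oof.compound_ids, cv.oof.y_mc, cv.oof.uncertainty, y_true=labels
        )
        comparison = ranking.strategy_comparison(rin, config.ranking_fraction)
        pd.DataFrame(
            sorted(comparison.items()), columns=["strategy", "precision_at_top"]
        ).to_csv(out / "ranking_comparison.csv", index=False)
        _write_manifest(out, stage, cfg_hash, config.seed, ["ranking_comparison.csv"])
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    stage = "detect"
    try:
        report = error_detect.flag_suspects(
            cv.oof,
            labels,
            config.error_pctl,
            config.unc_pctl,
            config.unc_direction,
            curated,
        )
        report.to_json(out / "suspects.json")
        _write_manifest(out, stage, cfg_hash, config.seed, ["suspects.json"])
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    stage = "analyze"
    try:
        table = analysis.DiagnosticsTable(
            pd.DataFrame(
                {
                    "squared_error": (cv.oof.y_mc - labels) ** 2,
                    "max_train_similarity": cv.max_train_similarity,
                    "uncertainty": cv.oof.uncertainty,
                    "n_values": [c.n_values for c in curated],
                    "std_log_activity": [c.std_log_activity for c in curated],
                },
                index=pd.Index(cv.oof.compound_ids, name="compound_id"),
            )
        )
        table.frame.to_csv(out / "diagnostics.csv")
        analysis.group_by_count(table).to_csv(out / "uncertainty_by_count.csv", index=False)
        _write_manifest(out, stage, cfg_hash, config.seed, ["diagnostics.csv"])
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    logger.info("pipeline complete: %s", out)
    return out
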