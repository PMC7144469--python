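"""Curation of raw bioactivity records into per-compound regression datasets.

Raw activity tables (ChEMBL-export-like) carry one measurement per row: a
compound, a target, an activity parameter (Ki, pKi, IC50, ...), a relation
symbol, a value and a concentration unit.  Curation filters the rows to the
binding-affinity whitelist, standardizes every surviving value onto a single
scale — log10 of Ki expressed in nM — and aggregates measurements per
compound into one regression label (the mean log-activity) together with the
count and spread of the underlying measurements.

IC50-family values are converted to Ki via the Cheng-Prusoff-style shortcut
Ki = IC50 / 2 before the log transform.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ActivityRecord",
    "CuratedCompound",
    "FilterReport",
    "EmptyDatasetError",
    "PARAMETER_WHITELIST",
    "STRICT_RELATIONS",
    "EXTENDED_RELATIONS",
    "UNIT_TO_NM",
    "filter_records",
    "standardize_value",
    "standardize_records",
    "aggregate_per_compound",
    "read_activity_csv",
    "curate",
    "curated_to_frame",
    "write_curated_csv",
]

PARAMETER_WHITELIST = frozenset({"Ki", "logKi", "pKi", "IC50", "logIC50", "pIC50"})
#: Parameters carrying a concentration in an explicit unit.
_CONCENTRATION_PARAMS = frozenset({"Ki", "IC50"})
#: IC50-family parameters: converted to Ki by halving the concentration.
_IC50_FAMILY = frozenset({"IC50", "logIC50", "pIC50"})

STRICT_RELATIONS = frozenset({"="})
EXTENDED_RELATIONS = frozenset({"=", "<", ">", "≤", "≥", "~", "<=", ">="})

#: Multiplier taking a value in the given unit to nM.
UNIT_TO_NM = {
    "M": 1e9,
    "mM": 1e6,
    "µM": 1e3,
    "uM": 1e3,  # ASCII alias
    "nM": 1.0,
    "pM": 1e-3,
    "fM": 1e-6,
}

LOG10_2 = math.log10(2.0)

#: Default ChEMBL-export-like column names for CSV ingestion.
DEFAULT_COLUMNS = {
    "record_id": "activity_id",
    "compound_id": "molecule_chembl_id",
    "smiles": "canonical_smiles",
    "target_id": "target_chembl_id",
    "parameter": "standard_type",
    "relation": "standard_relation",
    "value": "standard_value",
    "unit": "standard_units",
    "organism": "target_organism",
}


class EmptyDatasetError(ValueError):
    """Raised when filtering leaves no usable records."""


@dataclass(frozen=True)
class ActivityRecord:
    """One raw activity measurement row."""

    record_id: str
    compound_id: str
    target_id: str
    parameter: str
    relation: str
    value: float
    unit: str | None = None
    smiles: str | None = None
    organism: str | None = None


@dataclass
class CuratedCompound:
    """Per-compound aggregate of standardized log-activities.

    ``label`` is the regression target: the mean of ``log_activities``
    (log10 Ki in nM).  ``mean_activity_nm`` is the arithmetic mean on the nM
    scale, kept for reporting because database summaries are often quoted in
    nM.  ``std_log_activity`` uses the population convention (divide by n) so
    a single measurement has spread exactly 0.
    """

    compound_id: str
    smiles: str | None
    log_activities: list[float]
    n_values: int
    mean_log_activity: float
    std_log_activity: float
    mean_activity_nm: float
    label: float


@dataclass
class FilterReport:
    """Per-stage record counts of the filtering cascade, in protocol order."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: records_out {n_out} > records_in {n_in}")
        self.stages.append((name, n_in, n_out))

    @property
    def records_in(self) -> int:
        return self.stages[0][1] if self.stages else 0

    @property
    def records_out(self) -> int:
        return self.stages[-1][2] if self.stages else 0

    @property
    def dropped(self) -> int:
        return sum(n_in - n_out for _, n_in, n_out in self.stages)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"stage": s, "records_in": i, "records_out": o}
                for s, i, o in self.stages
            ],
            "records_in": self.records_in,
            "records_out": self.records_out,
            "dropped": self.dropped,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _relation_set(relation_mode: str) -> frozenset[str]:
    if relation_mode == "strict":
        return STRICT_RELATIONS
    if relation_mode == "extended":
        return EXTENDED_RELATIONS
    raise ValueError(f"unknown relation_mode {relation_mode!r}")


def filter_records(
    records: Sequence[ActivityRecord],
    relation_mode: str = "strict",
    organism: str | None = "Homo sapiens",
) -> tuple[list[ActivityRecord], FilterReport]:
    """Apply the curation cascade and count every stage.

    Stages, in order: organism filter (no-op for records without an organism
    annotation), parameter whitelist, relation filter (``=`` only under
    ``strict``; the six-symbol extended set under ``extended``), unit filter
    (concentration parameters must carry one of M/mM/µM/nM/pM/fM; log- and
    p-form parameters must carry none), finiteness of the value.

    Records failing a stage are dropped and counted, never raised on.
    Raises :class:`EmptyDatasetError` when nothing survives.
    """
    allowed_relations = _relation_set(relation_mode)
    report = FilterReport()
    current = list(records)

    n_in = len(current)
    if organism is not None:
        current = [r for r in current if r.organism is None or r.organism == organism]
    report.add("organism_filter", n_in, len(current))

    n_in = len(current)
    current = [r for r in current if r.parameter in PARAMETER_WHITELIST]
    report.add("parameter_filter", n_in, len(current))

    n_in = len(current)
    current = [r for r in current if r.relation in allowed_relations]
    report.add("relation_filter", n_in, len(current))

    n_in = len(current)
    kept = []
    for r in current:
        if r.parameter in _CONCENTRATION_PARAMS:
            if r.unit in UNIT_TO_NM:
                kept.append(r)
        else:
            if r.unit is None or r.unit == "":
                kept.append(r)
    current = kept
    report.add("unit_filter", n_in, len(current))

    n_in = len(current)
    current = [r for r in current if math.isfinite(r.value)]
    report.add("value_filter", n_in, len(current))

    if not current:
        raise EmptyDatasetError(
            f"no records survived filtering (started with {report.records_in})"
        )
    return current, report


def standardize_value(
    parameter: str,
    relation: str,
    value: float,
    unit: str | None = None,
) -> float:
    """Standardize one measurement to log10(Ki in nM).

    Concentration parameters are converted to nM; IC50-family values are
    halved (Ki = IC50/2) before the log.  p-forms are −log10 of the molar
    value, so pKi maps to ``9 − pKi`` and pIC50 additionally subtracts
    log10(2).  Plain log-forms (logKi, logIC50) are rejected: their base and
    unit are undefined in export conventions and silently guessing either
    would corrupt the scale.

    Raises ``ValueError`` for non-positive concentrations (log undefined)
    and for plain log-forms.
    """
    if parameter not in PARAMETER_WHITELIST:
        raise ValueError(f"parameter {parameter!r} not in whitelist")
    if parameter in ("logKi", "logIC50"):
        raise ValueError(
            f"plain log-form parameter {parameter!r} has no defined base/unit; "
            "convert to Ki/IC50 or pKi/pIC50 upstream"
        )
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {value!r}")

    if parameter in _CONCENTRATION_PARAMS:
        if unit not in UNIT_TO_NM:
            raise ValueError(f"unit {unit!r} not in allowed set for {parameter}")
        nm = value * UNIT_TO_NM[unit]
        if parameter in _IC50_FAMILY:
            nm /= 2.0
        if nm <= 0:
            raise ValueError(f"non-positive concentration {value!r} {unit}: log undefined")
        return math.log10(nm)

    # p-forms: pX = −log10(X in M)  ⇒  log10(X in nM) = 9 − pX
    log_nm = 9.0 - value
    if parameter == "pIC50":
        log_nm -= LOG10_2
    return log_nm


def standardize_records(
    records: Iterable[ActivityRecord],
) -> tuple[list[tuple[ActivityRecord, float]], list[tuple[ActivityRecord, str]]]:
    """Standardize each record; return (record, log_activity) pairs and rejects."""
    out: list[tuple[ActivityRecord, float]] = []
    rejected: list[tuple[ActivityRecord, str]] = []
    for r in records:
        try:
            out.append((r, standardize_value(r.parameter, r.relation, r.value, r.unit)))
        except ValueError as exc:
            rejected.append((r, str(exc)))
    return out, rejected


def aggregate_per_compound(
    standardized: Sequence[tuple[ActivityRecord, float]],
) -> list[CuratedCompound]:
    """Aggregate standardized measurements into one CuratedCompound each.

    Duplicate (compound, value) rows count as separate measurements.  The
    regression label is the log-scale mean.  Output is sorted by compound_id.
    Conflicting SMILES for a single compound_id is a hard error.
    """
    groups: dict[str, list[tuple[ActivityRecord, float]]] = {}
    for rec, log_act in standardized:
        groups.setdefault(rec.compound_id, []).append((rec, log_act))

    out: list[CuratedCompound] = []
    for cid in sorted(groups):
        members = groups[cid]
        smiles_set = {r.smiles for r, _ in members if r.smiles}
        if len(smiles_set) > 1:
            raise ValueError(f"conflicting SMILES for compound {cid}: {sorted(smiles_set)}")
        smiles = next(iter(smiles_set)) if smiles_set else None
        logs = [v for _, v in members]
        n = len(logs)
        mean = sum(logs) / n
        var = sum((v - mean) ** 2 for v in logs) / n  # population convention
        mean_nm = sum(10.0 ** v for v in logs) / n
        out.append(
            CuratedCompound(
                compound_id=cid,
                smiles=smiles,
                log_activities=logs,
                n_values=n,
                mean_log_activity=mean,
                std_log_activity=math.sqrt(var),
                mean_activity_nm=mean_nm,
                label=mean,
            )
        )
    return out


def read_activity_csv(path, columns: dict | None = None) -> list[ActivityRecord]:
    """Read a raw activity table (CSV/TSV by extension) into ActivityRecords.

    ``columns`` overrides the ChEMBL-export-like default header mapping.
    Rows with unparseable values become records with value NaN so they are
    dropped (and counted) by the value filter rather than crashing ingestion.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    def get(row, key):
        col = cols[key]
        if col in df.columns:
            val = row[col]
            return val if val != "" else None
        return None

    records = []
    for idx, row in df.iterrows():
        raw_value = get(row, "value")
        try:
            value = float(raw_value) if raw_value is not None else math.nan
        except ValueError:
            value = math.nan
        records.append(
            ActivityRecord(
                record_id=get(row, "record_id") or str(idx),
                compound_id=get(row, "compound_id") or f"ROW{idx}",
                target_id=get(row, "target_id") or "",
                parameter=get(row, "parameter") or "",
                relation=get(row, "relation") or "",
                value=value,
                unit=get(row, "unit"),
                smiles=get(row, "smiles"),
                organism=get(row, "organism"),
            )
        )
    return records


def curate(
    records: Sequence[ActivityRecord],
    relation_mode: str = "strict",
    organism: str | None = "Homo sapiens",
) -> tuple[list[CuratedCompound], FilterReport]:
    """Full curation: filter → standardize → aggregate.

    Standardization rejects (non-positive concentrations, undefined
    log-forms) are appended to the report as a ``standardize`` stage.
    """
    filtered, report = filter_records(records, relation_mode, organism)
    standardized, rejected = standardize_records(filtered)
    report.add("standardize", len(filtered), len(standardized))
    if not standardized:
        raise EmptyDatasetError("no records survived standardization")
    return aggregate_per_compound(standardized), report


def curated_to_frame(curated: Sequence[CuratedCompound]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in curated],
            "smiles": [c.smiles for c in curated],
            "n_values": [c.n_values for c in curated],
            "mean_log_activity": [c.mean_log_activity for c in curated],
            "std_log_activity": [c.std_log_activity for c in curated],
            "mean_activity_nm": [c.mean_activity_nm for c in curated],
            "label": [c.label for c in curated],
        }
    )


def write_curated_csv(curated: Sequence[CuratedCompound], path) -> None:
    curated_to_frame(curated).to_csv(path, index=False)
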