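"""Reading and writing lifespan datasets in the CSV and JSON dump dialects.

One row/object per cohort observation.  Canonical columns:

    organism, genes, alleles, intervention_types, lifespan_days,
    lifespan_metric, temperature_c, diet, study_id

``genes``, ``alleles`` and ``intervention_types`` are ";"-joined parallel
lists (empty for wild type); ";" is reserved as the in-field separator.
A column-mapping config adapts the loader to dumps with different column
names.  The SQL dump dialect is not supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import (
    ExperimentGroup,
    GeneIntervention,
    LifespanObservation,
    MutantModel,
    ORGANISMS,
    group_observations,
)

COLUMNS = [
    "organism",
    "genes",
    "alleles",
    "intervention_types",
    "lifespan_days",
    "lifespan_metric",
    "temperature_c",
    "diet",
    "study_id",
]
MANDATORY = ("organism", "genes", "lifespan_days", "study_id")


@dataclass
class LoadReport:
    """Row accounting for one load: read = kept + rejected."""

    rows_read: int = 0
    rows_kept: int = 0
    rejected: list[dict] = field(default_factory=list)

    @property
    def rows_rejected(self) -> int:
        return len(self.rejected)

    def to_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "rows_kept": self.rows_kept,
            "rows_rejected": self.rows_rejected,
            "rejected": self.rejected,
        }


def _infer_dialect(path, dialect: str | None) -> str:
    if dialect:
        return dialect
    suffix = Path(path).suffix.lower()
    return "json" if suffix == ".json" else "csv"


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or v == ""


def _parse_row(row: dict) -> LifespanObservation:
    organism = row.get("organism")
    if organism not in ORGANISMS:
        raise ValueError(f"unknown organism {organism!r}")
    genes_field = row.get("genes")
    genes = [] if _is_missing(genes_field) else str(genes_field).split(";")
    alleles_field = row.get("alleles")
    alleles = [] if _is_missing(alleles_field) else str(alleles_field).split(";")
    types_field = row.get("intervention_types")
    types = [] if _is_missing(types_field) else str(types_field).split(";")
    if alleles and len(alleles) != len(genes):
        raise ValueError("alleles/genes length mismatch")
    if genes and types and len(types) != len(genes):
        raise ValueError("intervention_types/genes length mismatch")
    if genes and not types:
        raise ValueError("missing intervention_types")

    interventions = frozenset(
        GeneIntervention(
            gene_symbol=g,
            intervention_type=t,
            allele=alleles[i] if alleles else "",
        )
        for i, (g, t) in enumerate(zip(genes, types))
    )
    try:
        lifespan = float(row["lifespan_days"])
    except (TypeError, ValueError):
        raise ValueError("unparseable lifespan") from None
    if not lifespan > 0:
        raise ValueError("non-positive lifespan")

    temperature = row.get("temperature_c")
    temperature = None if _is_missing(temperature) else float(temperature)
    diet = row.get("diet")
    diet = None if _is_missing(diet) else str(diet)
    metric = row.get("lifespan_metric")
    metric = "mean" if _is_missing(metric) else str(metric)

    return LifespanObservation(
        model=MutantModel(organism=organism, interventions=interventions),
        lifespan_days=lifespan,
        lifespan_metric=metric,
        temperature_c=temperature,
        diet=diet,
        study_id=str(row["study_id"]),
    )


def load_dataset(
    path,
    dialect: str | None = None,
    column_map: dict[str, str] | None = None,
) -> tuple[list[ExperimentGroup], LoadReport]:
    """Load a dump file into experiment groups plus a row-accounting report.

    ``column_map`` renames dump columns to the canonical schema, e.g.
    ``{"species": "organism"}`` for a dump whose organism column is named
    ``species``.  Rows violating row-level rules (unknown organism,
    non-positive lifespan, ragged gene/allele lists) are rejected
    individually with a reason; a missing mandatory column is a
    file-level error.
    """
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif dialect == "json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise ValueError("JSON dump must be an array of objects")
        df = pd.DataFrame(data, dtype=object)
        if data == []:
            df = pd.DataFrame(columns=COLUMNS)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    report = LoadReport(rows_read=len(df))
    observations = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            observations.append(_parse_row(row))
        except ValueError as exc:
            report.rejected.append({"row": i, "reason": str(exc)})
    report.rows_kept = len(observations)
    return group_observations(observations), report


def _obs_to_row(obs: LifespanObservation) -> dict:
    ivs = sorted(
        obs.model.interventions,
        key=lambda iv: (iv.gene_symbol.lower(), iv.gene_symbol),
    )
    return {
        "organism": obs.model.organism,
        "genes": ";".join(iv.gene_symbol for iv in ivs),
        "alleles": ";".join(iv.allele for iv in ivs),
        "intervention_types": ";".join(iv.intervention_type for iv in ivs),
        "lifespan_days": obs.lifespan_days,
        "lifespan_metric": obs.lifespan_metric,
        "temperature_c": "" if obs.temperature_c is None else obs.temperature_c,
        "diet": "" if obs.diet is None else obs.diet,
        "study_id": obs.study_id,
    }


def write_dataset(groups, path, dialect: str | None = None) -> None:
    """Serialize experiment groups back to a dump file.

    Rows are emitted in a fixed order (experiment key, then strain name,
    then lifespan) so output is byte-stable; ``load_dataset`` on the
    result reproduces the groups up to observation order.
    """
    dialect = _infer_dialect(path, dialect)
    rows = [
        (g.experiment_key, obs.model.canonical_name, obs.lifespan_days, _obs_to_row(obs))
        for g in sorted(groups, key=lambda g: g.experiment_key)
        for obs in g.observations
    ]
    rows.sort(key=lambda r: r[:3])
    records = [r[3] for r in rows]
    df = pd.DataFrame(records, columns=COLUMNS)
    if dialect == "csv":
        df.to_csv(path, index=False)
    elif dialect == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
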