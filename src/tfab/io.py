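"""Cohort CSV and normative-model JSON input/output.

Cohorts are flat per-participant CSV files with columns
``id,age,education,sex,<six task columns>[,group,...]``; any extra numeric
column is preserved as a companion score.  Normative models serialize to a
versioned JSON schema; reading validates transforms and band monotonicity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    TASKS,
    TRANSFORMS,
    AdjustmentEquation,
    EquivalentScoreTable,
    ModelError,
    NormativeModel,
    OutcomeNorm,
    ScoreRecord,
    Term,
    ToleranceLimits,
    ValidationError,
    round2,
    score_participant,
)

__all__ = [
    "MODEL_SCHEMA_VERSION",
    "CohortIssues",
    "read_cohort",
    "records_from_frame",
    "attach_derived_scores",
    "write_model",
    "read_model",
    "score_cohort",
]

MODEL_SCHEMA_VERSION = "1.0"

MANDATORY_COLUMNS = ("id", "age", "education", "sex")


@dataclass
class CohortIssues:
    """Per-row validation findings; rows are flagged, not dropped."""

    rows: list[tuple[object, str]] = field(default_factory=list)

    def add(self, row_id: object, message: str) -> None:
        self.rows.append((row_id, message))

    def __bool__(self) -> bool:
        return bool(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def read_cohort(path, strict: bool = False) -> tuple[pd.DataFrame, CohortIssues]:
    """Read and validate a cohort CSV.

    Returns the typed DataFrame plus an issue report.  Rows with invalid
    demographics get ``valid_demographics = False`` (they are excluded from
    adjustment-dependent analyses); out-of-range task scores are set to NA
    and flagged.  With ``strict=True`` any issue raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file missing mandatory column(s): {missing}")
    issues = CohortIssues()
    for col in ("age", "education"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    valid = pd.Series(True, index=df.index)
    for i, row in df.iterrows():
        rid = row["id"]
        if not (np.isfinite(row["age"]) and np.isfinite(row["education"])):
            issues.add(rid, "non-numeric or missing age/education")
            valid[i] = False
        elif row["education"] <= 0:
            issues.add(rid, f"education = {row['education']} (must be > 0)")
            valid[i] = False
        if row["sex"] not in ("M", "F"):
            issues.add(rid, f"sex = {row['sex']!r} (must be M or F)")
            valid[i] = False
    for t in TASKS:
        if t not in df.columns:
            continue
        df[t] = pd.to_numeric(df[t], errors="coerce")
        bad = df[t].notna() & ~df[t].isin([0, 1, 2, 3])
        for rid in df.loc[bad, "id"]:
            issues.add(rid, f"task {t} out of range {{0..3}}")
        df.loc[bad, t] = np.nan
    df["valid_demographics"] = valid
    if strict and issues:
        raise ValidationError(
            "cohort validation failed: "
            + "; ".join(f"{rid}: {msg}" for rid, msg in issues.rows)
        )
    return df, issues


def records_from_frame(df: pd.DataFrame) -> list[ScoreRecord]:
    """Typed records from a cohort frame; companion columns preserved."""
    known = set(MANDATORY_COLUMNS) | set(TASKS) | {"group", "valid_demographics"}
    extra = [c for c in df.columns if c not in known]
    records = []
    for _, row in df.iterrows():
        tasks = {
            t: (int(row[t]) if t in df.columns and pd.notna(row[t]) else None)
            for t in TASKS
        }
        companions = {
            c: float(row[c])
            for c in extra
            if isinstance(row[c], (int, float, np.floating, np.integer))
            and not (isinstance(row[c], float) and math.isnan(row[c]))
        }
        records.append(
            ScoreRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                education=float(row["education"]),
                sex=str(row["sex"]),
                group=row.get("group"),
                companion_scores=companions,
                **tasks,
            )
        )
    return records


def attach_derived_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Add tFAB_1/2M/2V and totals columns wherever the tasks allow."""
    df = df.copy()
    pairs = {
        "tFAB_1": ("conceptualization", "mental_flexibility"),
        "tFAB_2M": ("interference_M", "inhibition_M"),
        "tFAB_2V": ("interference_V", "inhibition_V"),
    }
    for name, (a, b) in pairs.items():
        if name not in df.columns and a in df.columns and b in df.columns:
            df[name] = df[a] + df[b]
    if "tFAB_M" not in df.columns and {"tFAB_1", "tFAB_2M"} <= set(df.columns):
        df["tFAB_M"] = df["tFAB_1"] + df["tFAB_2M"]
    if "tFAB_V" not in df.columns and {"tFAB_1", "tFAB_2V"} <= set(df.columns):
        df["tFAB_V"] = df["tFAB_1"] + df["tFAB_2V"]
    return df


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------


def _model_to_dict(model: NormativeModel) -> dict:
    out = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "version": model.version,
        "n": model.n,
        "ranges": {
            "age": list(model.age_range),
            "education": list(model.education_range),
        },
        "metadata": dict(model.metadata),
        "outcomes": {},
    }
    for name, norm in model.outcomes.items():
        tl = norm.tolerance
        out["outcomes"][name] = {
            "terms": [
                {
                    "transform": t.transform,
                    "variable": t.variable,
                    "coefficient": t.coefficient,
                    "center": t.center,
                }
                for t in norm.equation.terms
            ],
            "otl": tl.oTL if tl else None,
            "itl": tl.iTL if tl else None,
            "rank_outer": tl.rank_outer if tl else None,
            "rank_inner": tl.rank_inner if tl else None,
            "es_boundaries": list(norm.es_table.boundaries) if norm.es_table else None,
            "flags": list(norm.flags),
        }
    return out


def write_model(model: NormativeModel, path) -> None:
    """Serialize to JSON at full float precision (round-trips losslessly)."""
    Path(path).write_text(
        json.dumps(_model_to_dict(model), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_model(path) -> NormativeModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelError(
            f"model schema version {version!r} != supported {MODEL_SCHEMA_VERSION!r}: "
            "migrate the file before loading"
        )
    outcomes = {}
    for name, spec in doc["outcomes"].items():
        terms = []
        for t in spec["terms"]:
            if t["transform"] not in TRANSFORMS:
                raise ModelError(f"{name}: unknown transform {t['transform']!r}")
            terms.append(
                Term(t["transform"], t["variable"], t["coefficient"], t["center"])
            )
        tol = None
        if spec.get("rank_outer") is not None or spec.get("rank_inner") is not None:
            tol = ToleranceLimits(
                oTL=spec.get("otl"),
                iTL=spec.get("itl"),
                rank_outer=spec.get("rank_outer"),
                rank_inner=spec.get("rank_inner"),
                n=doc["n"],
            )
        table = (
            EquivalentScoreTable(tuple(spec["es_boundaries"]))
            if spec.get("es_boundaries")
            else None
        )
        outcomes[name] = OutcomeNorm(
            equation=AdjustmentEquation(name, tuple(terms)),
            tolerance=tol,
            es_table=table,
            flags=tuple(spec.get("flags", ())),
        )
    return NormativeModel(
        outcomes=outcomes,
        n=doc["n"],
        age_range=tuple(doc["ranges"]["age"]),
        education_range=tuple(doc["ranges"]["education"]),
        version=doc.get("version", "user"),
        metadata=doc.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# scored report
# ---------------------------------------------------------------------------


def score_cohort(
    df: pd.DataFrame, model: NormativeModel
) -> tuple[pd.DataFrame, dict[str, dict[int, int]]]:
    """Per-participant raw/AS/ES report plus ES band counts per outcome.

    Functional equivalent of the study's automated correction sheet.  Rows
    whose demographics failed validation are skipped.
    """
    rows = []
    counts: dict[str, dict[int, int]] = {}
    usable = df[df["valid_demographics"]] if "valid_demographics" in df.columns else df
    for rec in records_from_frame(usable):
        result = score_participant(model, rec)
        row: dict[str, object] = {"id": rec.id}
        for outcome, entry in result.items():
            row[f"{outcome}_raw"] = entry["raw"]
            row[f"{outcome}_AS"] = entry["adjusted"]
            row[f"{outcome}_ES"] = entry["es"]
            row[f"{outcome}_label"] = entry["label"]
            row["extrapolated"] = entry["extrapolated"]
            if entry["es"] is not None:
                counts.setdefault(outcome, {}).setdefault(entry["es"], 0)
                counts[outcome][entry["es"]] += 1
        rows.append(row)
    return pd.DataFrame(rows), counts
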