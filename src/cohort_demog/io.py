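"""CSV readers/writers, configuration loading, and run reports.

CSV dialect: UTF-8, comma-separated, mandatory header row, ``.`` decimal.
Ages and durations are days (reals); widths are um unless a ``*_mm`` column
declares millimetres, in which case values are converted on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .demography import (
    DemographicParameters,
    IndividualRecord,
    LifeTableSchedule,
)
from .exceptions import ValidationError
from .morphometrics import HeadCapsuleSample, InstarClassification

__all__ = [
    "SCHEMA_VERSION",
    "RunReport",
    "read_head_capsules",
    "read_records",
    "write_head_capsules",
    "write_records",
    "write_life_table",
    "write_report",
    "load_config",
    "instar_report_payload",
    "demography_report_payload",
]

SCHEMA_VERSION = 1

CAPSULE_COLUMNS = {"larva_id", "width_um", "width_mm", "length_um", "length_mm",
                   "collection_day"}
RECORD_COLUMNS = {"individual_id", "sex", "treatment", "egg_days", "l1_days",
                  "l2_days", "l3_days", "pupa_days", "died_in_stage",
                  "adult_longevity_days"}
FECUNDITY_COLUMNS = {"individual_id", "adult_day", "eggs"}

_STAGE_COLS = {"egg": "egg_days", "L1": "l1_days", "L2": "l2_days",
               "L3": "l3_days", "pupa": "pupa_days"}


def _require_columns(df: pd.DataFrame, required: set[str], path: Path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")


def read_head_capsules(path: str | Path) -> HeadCapsuleSample:
    """Read ``head_capsules.csv`` (header ``larva_id,width_um,length_um,
    collection_day``; a ``width_mm``/``length_mm`` column is converted to um).
    Malformed rows are reported with 1-based data-row numbers."""
    path = Path(path)
    df = pd.read_csv(path)
    unknown = set(df.columns) - CAPSULE_COLUMNS
    if unknown:
        raise ValidationError(f"{path}: unknown column(s) {sorted(unknown)}")
    if "width_um" in df.columns:
        width, w_scale = df["width_um"], 1.0
    elif "width_mm" in df.columns:
        width, w_scale = df["width_mm"], 1000.0
    else:
        raise ValidationError(f"{path}: missing column(s) ['width_um']")
    width_num = pd.to_numeric(width, errors="coerce")
    bad = df.index[width_num.isna()].tolist()
    if bad:
        raise ValidationError(
            f"{path}: non-numeric width in data row(s) {[i + 1 for i in bad]}")
    nonpos = df.index[width_num <= 0].tolist()
    if nonpos:
        raise ValidationError(
            f"{path}: non-positive width in data row(s) {[i + 1 for i in nonpos]}")
    widths = width_num.to_numpy(dtype=float) * w_scale
    lengths = None
    for col, scale in (("length_um", 1.0), ("length_mm", 1000.0)):
        if col in df.columns and df[col].notna().any():
            lengths = pd.to_numeric(df[col], errors="coerce").to_numpy(float) * scale
            break
    ids = df["larva_id"].astype(str).tolist() if "larva_id" in df.columns else None
    day = None
    if "collection_day" in df.columns and df["collection_day"].notna().any():
        day = pd.to_numeric(df["collection_day"], errors="coerce").to_numpy()
    return HeadCapsuleSample(widths=widths, lengths=lengths, larva_id=ids,
                             collection_day=day)


def read_records(records_path: str | Path,
                 fecundity_path: str | Path) -> list[IndividualRecord]:
    """Join ``records.csv`` with long-format ``fecundity.csv``.

    Orphan fecundity rows, duplicate (individual_id, adult_day) pairs, days
    beyond the recorded lifespan and fecundity for males are errors; a female
    with no fecundity rows gets a zero trajectory with a warning.
    """
    records_path, fecundity_path = Path(records_path), Path(fecundity_path)
    rec = pd.read_csv(records_path)
    _require_columns(rec, {"individual_id", "sex", "adult_longevity_days"},
                     records_path)
    fec = pd.read_csv(fecundity_path)
    _require_columns(fec, FECUNDITY_COLUMNS, fecundity_path)

    dup = fec.duplicated(subset=["individual_id", "adult_day"])
    if dup.any():
        rows = [i + 1 for i in fec.index[dup].tolist()]
        raise ValidationError(
            f"{fecundity_path}: duplicate (individual_id, adult_day) in "
            f"data row(s) {rows}")
    known_ids = set(rec["individual_id"].astype(str))
    orphan = ~fec["individual_id"].astype(str).isin(known_ids)
    if orphan.any():
        rows = [i + 1 for i in fec.index[orphan].tolist()]
        raise ValidationError(
            f"{fecundity_path}: fecundity for unknown individual(s) in "
            f"data row(s) {rows}")

    fec_by_id: dict[str, pd.DataFrame] = {
        str(k): v for k, v in fec.groupby(fec["individual_id"].astype(str))
    }
    records: list[IndividualRecord] = []
    for i, row in rec.iterrows():
        ident = str(row["individual_id"])
        sex = str(row["sex"]).strip().lower()
        durations: dict[str, float] = {}
        for stage, col in _STAGE_COLS.items():
            if col in rec.columns and pd.notna(row.get(col)):
                durations[stage] = float(row[col])
        died = row.get("died_in_stage")
        died = str(died) if pd.notna(died) and str(died).strip() else None
        longevity = row.get("adult_longevity_days")
        longevity = float(longevity) if pd.notna(longevity) else 0.0
        if sex == "female" and died is None:
            daily = np.zeros(max(math.ceil(longevity), 0), dtype=int)
        else:
            daily = np.zeros(0, dtype=int)
        if ident in fec_by_id:
            if sex == "male":
                raise ValidationError(
                    f"{fecundity_path}: fecundity rows for male {ident!r}")
            sub = fec_by_id[ident]
            for j, frow in sub.iterrows():
                d = int(frow["adult_day"])
                if d < 1 or d > daily.size:
                    raise ValidationError(
                        f"{fecundity_path}: adult_day {d} outside lifespan of "
                        f"{ident!r} (data row {j + 1})")
                daily[d - 1] = int(frow["eggs"])
        elif sex == "female" and died is None:
            warnings.warn(f"female {ident!r} has no fecundity rows; assuming "
                          "zero eggs", stacklevel=2)
        treatment = row.get("treatment")
        treatment = str(treatment) if pd.notna(treatment) else None
        records.append(IndividualRecord(
            individual_id=ident, sex=sex, stage_durations=durations,
            died_in_stage=died, adult_longevity=longevity, daily_eggs=daily,
            treatment=treatment,
        ))
    return records


def write_head_capsules(sample: HeadCapsuleSample, path: str | Path) -> None:
    df = pd.DataFrame({
        "larva_id": sample.larva_id or [f"larva_{i + 1:03d}"
                                        for i in range(sample.n)],
        "width_um": sample.widths,
        "length_um": sample.lengths if sample.lengths is not None
        else [""] * sample.n,
        "collection_day": sample.collection_day if sample.collection_day is not None
        else [""] * sample.n,
    })
    df.to_csv(path, index=False)


def write_records(records: Sequence[IndividualRecord], records_path: str | Path,
                  fecundity_path: str | Path) -> None:
    rows, fec_rows = [], []
    for r in records:
        rows.append({
            "individual_id": r.individual_id,
            "sex": r.sex,
            "treatment": r.treatment if r.treatment is not None else "",
            **{col: r.stage_durations.get(stage, "")
               for stage, col in _STAGE_COLS.items()},
            "died_in_stage": r.died_in_stage or "",
            "adult_longevity_days": r.adult_longevity,
        })
        for d, eggs in enumerate(r.daily_eggs, start=1):
            if eggs > 0:
                fec_rows.append({"individual_id": r.individual_id,
                                 "adult_day": d, "eggs": int(eggs)})
    pd.DataFrame(rows).to_csv(records_path, index=False)
    pd.DataFrame(fec_rows, columns=["individual_id", "adult_day", "eggs"]
                 ).to_csv(fecundity_path, index=False)


def write_life_table(schedule: LifeTableSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration and reports
# ---------------------------------------------------------------------------

def load_config(path: str | Path, allowed: dict[str, set[str]]) -> dict[str, Any]:
    """Load a YAML/JSON config with section -> allowed-keys validation;
    unknown sections or keys are rejected."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    for section, value in cfg.items():
        if section not in allowed:
            raise ValidationError(f"{path}: unknown config section {section!r}")
        if not isinstance(value, dict):
            raise ValidationError(f"{path}: section {section!r} must be a mapping")
        unknown = set(value) - allowed[section]
        if unknown:
            raise ValidationError(
                f"{path}: unknown key(s) {sorted(unknown)} in section "
                f"{section!r}")
    return cfg


def file_checksum(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not math.isfinite(obj):
        return None if math.isnan(obj) else ("Infinity" if obj > 0 else "-Infinity")
    return obj


@dataclass
class RunReport:
    """Serialisable record of one pipeline run."""

    command: str
    config: dict[str, Any]
    input_checksums: dict[str, str] = field(default_factory=dict)
    results: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    version: str = __version__
    schema_version: int = SCHEMA_VERSION

    def to_dict(self, with_timestamp: bool = True) -> dict[str, Any]:
        out = {
            "schema_version": self.schema_version,
            "tool_version": self.version,
            "command": self.command,
            "config": _jsonable(self.config),
            "input_checksums": dict(self.input_checksums),
            "results": _jsonable(self.results),
            "warnings": list(self.warnings),
        }
        if with_timestamp:
            out["created_at"] = datetime.now(timezone.utc).isoformat()
        return out


def instar_report_payload(classification: InstarClassification,
                          n: int) -> dict[str, Any]:
    return {
        "n": n,
        "mode_tests": [
            {"k": t.k_null, "statistic": t.statistic, "p_value": t.p_value,
             "n_boot": t.n_boot}
            for t in classification.mode_tests
        ],
        "n_instars": classification.n_instars,
        "saturated": classification.saturated,
        "boundaries_um": list(classification.boundaries),
        "per_instar": [dataclasses.asdict(g) for g in classification.per_instar],
        "dyar_ratios": list(classification.dyar.ratios) if classification.dyar else [],
        "dyar_constant": classification.dyar.constant if classification.dyar else None,
        "regression": dataclasses.asdict(classification.regression)
        if classification.regression else None,
    }


def demography_report_payload(params: DemographicParameters) -> dict[str, Any]:
    # printed precision: 2 dp for R0/T/DT, 4 dp for r and lambda
    payload = {
        "R0": round(params.r0, 2),
        "T": round(params.t, 2),
        "r_m": round(params.r_m, 4),
        "DT": round(params.dt, 2) if math.isfinite(params.dt) else None,
        "lambda": round(params.lam, 4),
        "r_method": params.r_method,
        "n_females": params.n_females,
        "unrounded": params.as_dict(),
    }
    if params.ci_95 is not None:
        payload["ci_95"] = {k: list(v) for k, v in params.ci_95.items()}
    return payload


def _summary_lines(results: dict[str, Any]) -> list[str]:
    lines: list[str] = []
    if "per_instar" in results:
        lines.append("Instar    n   Width (um, mean +/- SE)   Range            Growth ratio")
        ratios = [None] + list(results.get("dyar_ratios", []))
        for g, ratio in zip(results["per_instar"], ratios):
            rng = f"{g['min']:.2f}-{g['max']:.2f}"
            rat = f"{ratio:.4f}" if ratio else "-"
            lines.append(f"{g['instar']:<8}{g['n']:>4}   "
                         f"{g['mean']:.2f} +/- {g['se']:.2f}      {rng:<17}{rat}")
    p = results.get("parameters", {})
    if all(k in p for k in ("R0", "r_m", "T", "DT", "lambda")):
        lines.append("R0       r_m      T        DT       lambda")
        dt = f"{p['DT']:.2f}" if p["DT"] is not None else "inf"
        lines.append(f"{p['R0']:<9.2f}{p['r_m']:<9.4f}{p['T']:<9.2f}"
                     f"{dt:<9}{p['lambda']:.4f}")
    return lines


def write_report(report: RunReport, out_dir: str | Path,
                 backup: bool = False) -> dict[str, Path]:
    """Write ``report.json`` plus a plain-text summary; numeric content is
    reproducible byte-for-byte, the timestamp lives only in ``report.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    report_path = out_dir / "report.json"
    if backup and report_path.exists():
        report_path.rename(out_dir / "report.json.bak")
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(with_timestamp=True), fh, indent=2,
                  sort_keys=True)
        fh.write("\n")
    written["report"] = report_path
    if "parameters" in report.results:
        params_path = out_dir / "parameters.json"
        with open(params_path, "w", encoding="utf-8") as fh:
            json.dump(_jsonable({"schema_version": SCHEMA_VERSION,
                                 "config": report.config,
                                 "parameters": report.results["parameters"],
                                 "warnings": report.warnings}),
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
        written["parameters"] = params_path
    summary = _summary_lines(report.results)
    if summary:
        summary_path = out_dir / "summary.txt"
        summary_path.write_text("\n".join(summary) + "\n", encoding="utf-8")
        written["summary"] = summary_path
    return written
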