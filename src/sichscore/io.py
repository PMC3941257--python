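"""CSV readers/writers and report rendering.

All tabular interchange is comma-separated UTF-8 with a mandatory header
and "." decimals.  Row-level validation problems are collected and raised
together as a :class:`~sichscore.errors.SchemaError` naming the offending
lines.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from typing import Any

import pandas as pd

from .errors import SchemaError, ValidationError
from .evalstats import ComparisonReport
from .ocsp import OCSPCategory
from .outcomes import FollowUpRecord, ICHType, ImagingFinding
from .riskscore import Antiplatelet, GlucoseUnit, PatientProfile

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "profiles_from_frame",
    "read_followup",
    "render_report",
]

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "nihss_baseline",
    "glucose",
    "glucose_unit",
    "sbp",
    "weight_kg",
    "ott_min",
    "htn_history",
    "antiplatelet",
    "ocsp",
]

FOLLOWUP_COLUMNS = ["patient_id", "event_type", "hours", "value"]


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; returns the validated frame.

    Every row is checked (numeric fields parse, enum tokens are known,
    glucose carries a unit tag); all offending rows are reported at once
    with their line numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing columns: {missing}")

    problems: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            _profile_from_strings(row)
        except (ValidationError, ValueError) as exc:
            problems.append((line, str(exc)))
    if problems:
        raise SchemaError("cohort file failed validation", problems)

    out = df.copy()
    for col in ("age", "nihss_baseline", "glucose", "sbp", "weight_kg",
                "ott_min", "htn_history"):
        out[col] = pd.to_numeric(out[col])
    return out


def _profile_from_strings(row) -> PatientProfile:
    unit_token = str(row["glucose_unit"]).strip()
    if str(row["glucose"]).strip() and not unit_token:
        raise ValidationError("glucose column without a unit tag")
    return PatientProfile(
        age=float(row["age"]),
        nihss_baseline=int(float(row["nihss_baseline"])),
        glucose=float(row["glucose"]),
        glucose_unit=GlucoseUnit.from_string(unit_token),
        sbp=float(row["sbp"]),
        weight=float(row["weight_kg"]),
        ott_minutes=float(row["ott_min"]),
        hypertension_history=bool(int(float(row["htn_history"]))),
        antiplatelet=Antiplatelet(str(row["antiplatelet"]).strip()),
        ocsp=OCSPCategory.from_string(str(row["ocsp"])),
    )


def profiles_from_frame(df: pd.DataFrame) -> list[tuple[str, PatientProfile]]:
    """(patient_id, PatientProfile) pairs from a validated cohort frame."""
    return [
        (str(row["patient_id"]), _profile_from_strings(row))
        for _, row in df.astype(str).iterrows()
    ]


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_followup(path, cohort: pd.DataFrame) -> dict[str, FollowUpRecord]:
    """Assemble per-patient follow-up records from a long-format event CSV
    (columns patient_id, event_type {nihss|scan|death}, hours, value),
    joining baseline NIHSS from the cohort frame."""
    ev = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in FOLLOWUP_COLUMNS if c not in ev.columns]
    if missing:
        raise SchemaError(f"follow-up file missing columns: {missing}")

    baselines = dict(
        zip(cohort["patient_id"].astype(str),
            pd.to_numeric(cohort["nihss_baseline"]).astype(int))
    )
    problems: list[tuple[int, str]] = []
    series: dict[str, list] = {pid: [] for pid in baselines}
    scans: dict[str, list] = {pid: [] for pid in baselines}
    death: dict[str, bool] = {pid: False for pid in baselines}

    for i, row in ev.iterrows():
        line = i + 2
        pid = str(row["patient_id"])
        if pid not in baselines:
            problems.append((line, f"unknown patient_id {pid!r}"))
            continue
        kind = str(row["event_type"]).strip().lower()
        try:
            hours = float(row["hours"])
            if kind == "nihss":
                series[pid].append((hours, int(float(row["value"]))))
            elif kind == "scan":
                scans[pid].append(ImagingFinding(hours, ICHType.from_string(row["value"])))
            elif kind == "death":
                death[pid] = True
            else:
                problems.append((line, f"unknown event_type {kind!r}"))
        except (ValidationError, ValueError) as exc:
            problems.append((line, str(exc)))
    if problems:
        raise SchemaError("follow-up file failed validation", problems)

    return {
        pid: FollowUpRecord(
            nihss_baseline=baselines[pid],
            nihss_series=tuple(sorted(series[pid])),
            death_within_7d=death[pid],
            scans=tuple(scans[pid]),
        )
        for pid in baselines
    }


# ---------------------------------------------------------------------------
# report rendering

def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def _fmt_p(p: float) -> str:
    return f"{p:.3f}"


def _render_text(report: ComparisonReport) -> str:
    lines = []
    lines.append(f"SICH per {report.definition.upper()}  "
                 f"(n={report.n}, events={report.n_events})")
    lines.append("-" * 72)
    header = (f"{'score':<10}{'OR/point (95% CI)':<24}{'HL stat':>8}{'P':>7}"
              f"{'AUC (95% CI)':>26}")
    lines.append(header)
    for name, perf in (("SITS", report.sits), ("extended", report.extended)):
        fit, cal, auc = perf.logistic, perf.calibration, perf.auc
        or_txt = f"{fit.odds_ratio_per_point:.2f} ({fit.ci95[0]:.2f}-{fit.ci95[1]:.2f})"
        auc_txt = f"{auc.auc:.3f} ({auc.ci95[0]:.3f}-{auc.ci95[1]:.3f})"
        lines.append(f"{name:<10}{or_txt:<24}{cal.hl_statistic:>8.2f}"
                     f"{_fmt_p(cal.p_value):>7}{auc_txt:>26}")
    cmp_ = report.auc_comparison
    lines.append(f"AUC difference: {cmp_.difference:.3f}  "
                 f"(z={cmp_.z:.3f}, P={_fmt_p(cmp_.p_value)})")
    n = report.nri
    lines.append(f"NRI: {100 * n.nri:.1f}%  (z={n.z:.3f}, P={_fmt_p(n.p_value)})")
    lines.append("")
    strata = ("LOW", "AVERAGE", "ELEVATED")
    for title, mat in (("events", report.reclassification.events),
                       ("nonevents", report.reclassification.nonevents)):
        lines.append(f"reclassification ({title}); rows=SITS stratum, "
                     "cols=extended stratum")
        lines.append(f"{'':<10}" + "".join(f"{s:>10}" for s in strata))
        for s, rowvals in zip(strata, mat):
            lines.append(f"{s:<10}" + "".join(f"{v:>10d}" for v in rowvals))
        lines.append("")
    return "\n".join(lines)


def render_report(report: ComparisonReport | list[ComparisonReport],
                  format: str = "text") -> str:
    """Render one or several comparison reports as deterministic text or
    lossless JSON."""
    reports = report if isinstance(report, list) else [report]
    fmt = format.lower()
    if fmt == "json":
        payload = [_to_jsonable(r) for r in reports]
        return json.dumps(payload if isinstance(report, list) else payload[0],
                          indent=2, sort_keys=True)
    if fmt == "text":
        return "\n".join(_render_text(r) for r in reports)
    raise ValidationError(f"unknown report format {format!r}")
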