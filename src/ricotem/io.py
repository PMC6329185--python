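"""CSV/JSON/YAML interchange for traces, cohorts, panels and reports.

Dialect: comma separator, dot decimal, UTF-8, header row required. Floats
are written with 12 significant digits so that a write/read round trip is
faithful to well below 1e-9 relative.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError, SchemaError
from .labs import LabPanel
from .records import PatientRecord
from .scores import CutoffConfig, RicotemPanel
from .simulate import CohortSpec
from .trace import RotemTrace

__all__ = [
    "SCHEMA_VERSION",
    "TRACE_COLUMNS",
    "COHORT_COLUMNS",
    "PANEL_COLUMNS",
    "read_trace_csv",
    "write_trace_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_panel_csv",
    "write_panel_csv",
    "write_report",
    "RunConfig",
    "load_config",
]

SCHEMA_VERSION = "1.0"
_FLOAT_FMT = "%.12g"

TRACE_COLUMNS = ["time_s", "amplitude_mm"]  # optional extra column: channel
COHORT_COLUMNS = [
    "patient_id", "sex", "age_y", "abo",
    "pt_pct", "aptt_s", "fibrinogen_gL", "platelets_per_nL", "fviii_pct",
    "vwf_ag_pct", "vwf_rco_pct", "vwf_cb_pct",
    "bleeding_history", "multimer_abnormal",
]
PANEL_COLUMNS = ["patient_id", "auc_extem", "auc_rico", "auc_rico_haemate"]

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}
_UNKNOWN = {"", "unknown", "na", "n/a", "none", "nan"}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _read_csv(path: Union[str, os.PathLike]) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc


def _to_float(value: str, path: str, line: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise SchemaError(
            f"{path}, line {line}: column {column!r} has non-numeric value {value!r}"
        ) from None


def _to_bool(value: str, path: str, line: int, column: str,
             allow_unknown: bool = False) -> Optional[bool]:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    if allow_unknown and v in _UNKNOWN:
        return None
    raise SchemaError(
        f"{path}, line {line}: column {column!r} has non-boolean value {value!r}"
    )


# ---------------------------------------------------------------------------
# traces

def read_trace_csv(
    path: Union[str, os.PathLike], default_channel: str = "extem"
) -> Dict[str, RotemTrace]:
    """Read one or several channel traces from a trace CSV.

    A file without a ``channel`` column yields a single trace labelled
    ``default_channel``. Non-monotone timestamps raise a
    :class:`SchemaError` naming the offending line.
    """
    df = _read_csv(path)
    _require_columns(df, TRACE_COLUMNS, str(path))
    has_channel = "channel" in df.columns
    out: Dict[str, RotemTrace] = {}
    channels = df["channel"] if has_channel else pd.Series([default_channel] * len(df))
    for channel, sub in df.groupby(channels, sort=False):
        # header is line 1, first data row line 2
        lines = sub.index.to_numpy() + 2
        t = np.array([
            _to_float(v, str(path), ln, "time_s")
            for v, ln in zip(sub["time_s"], lines)
        ])
        a = np.array([
            _to_float(v, str(path), ln, "amplitude_mm")
            for v, ln in zip(sub["amplitude_mm"], lines)
        ])
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise SchemaError(
                f"{path}, line {lines[bad[0] + 1]}: time_s not strictly increasing "
                f"for channel {channel!r}"
            )
        out[str(channel)] = RotemTrace(str(channel), t, a)
    if not out:
        raise SchemaError(f"{path}: no trace samples found")
    return out


def write_trace_csv(
    traces: Union[RotemTrace, Dict[str, RotemTrace]],
    path: Union[str, os.PathLike],
    force: bool = False,
) -> None:
    """Write one trace (two columns) or several (with a ``channel`` column)."""
    _guard_overwrite(path, force)
    if isinstance(traces, RotemTrace):
        df = pd.DataFrame({
            "time_s": traces.times_s, "amplitude_mm": traces.amplitudes_mm,
        })
    else:
        frames = [
            pd.DataFrame({
                "time_s": tr.times_s, "amplitude_mm": tr.amplitudes_mm,
                "channel": label,
            })
            for label, tr in traces.items()
        ]
        df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# cohort tables

def read_cohort_csv(path: Union[str, os.PathLike]) -> List[PatientRecord]:
    """Read a cohort laboratory table into patient records (labs only)."""
    df = _read_csv(path)
    _require_columns(df, COHORT_COLUMNS, str(path))
    records: List[PatientRecord] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        num = {
            c: _to_float(row[c], str(path), line, c)
            for c in ("pt_pct", "aptt_s", "fibrinogen_gL", "platelets_per_nL",
                      "fviii_pct", "vwf_ag_pct", "vwf_rco_pct", "vwf_cb_pct")
        }
        lab = LabPanel(
            vwf_ag_pct=num["vwf_ag_pct"],
            vwf_rco_pct=num["vwf_rco_pct"],
            vwf_cb_pct=num["vwf_cb_pct"],
            fviii_pct=num["fviii_pct"],
            pt_pct=num["pt_pct"],
            aptt_s=num["aptt_s"],
            fibrinogen_gL=num["fibrinogen_gL"],
            platelets_per_nL=num["platelets_per_nL"],
            bleeding_history=bool(_to_bool(row["bleeding_history"], str(path), line,
                                           "bleeding_history")),
            multimer_abnormal=_to_bool(row["multimer_abnormal"], str(path), line,
                                       "multimer_abnormal", allow_unknown=True),
        )
        age = row["age_y"].strip()
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            lab=lab,
            sex=str(row["sex"]) or None,
            age_y=_to_float(age, str(path), line, "age_y") if age else None,
            abo=str(row["abo"]) or None,
        ))
    return records


def write_cohort_csv(
    records: Sequence[PatientRecord],
    path: Union[str, os.PathLike],
    force: bool = False,
) -> None:
    """Write patient labs to the cohort CSV dialect."""
    _guard_overwrite(path, force)
    rows = []
    for rec in records:
        lab = rec.lab
        rows.append({
            "patient_id": rec.patient_id,
            "sex": rec.sex or "",
            "age_y": rec.age_y if rec.age_y is not None else "",
            "abo": rec.abo or "",
            "pt_pct": lab.pt_pct,
            "aptt_s": lab.aptt_s,
            "fibrinogen_gL": lab.fibrinogen_gL,
            "platelets_per_nL": lab.platelets_per_nL,
            "fviii_pct": lab.fviii_pct,
            "vwf_ag_pct": lab.vwf_ag_pct,
            "vwf_rco_pct": lab.vwf_rco_pct,
            "vwf_cb_pct": lab.vwf_cb_pct,
            "bleeding_history": str(lab.bleeding_history).lower(),
            "multimer_abnormal": (
                "unknown" if lab.multimer_abnormal is None
                else str(lab.multimer_abnormal).lower()
            ),
        })
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# assay panels

def read_panel_csv(path: Union[str, os.PathLike]) -> List[RicotemPanel]:
    """Read per-patient AUC triplets; an empty ``auc_rico_haemate`` is allowed."""
    df = _read_csv(path)
    _require_columns(df, PANEL_COLUMNS, str(path))
    panels: List[RicotemPanel] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        haemate_raw = row["auc_rico_haemate"].strip()
        panels.append(RicotemPanel(
            patient_id=str(row["patient_id"]),
            auc_extem=_to_float(row["auc_extem"], str(path), line, "auc_extem"),
            auc_rico=_to_float(row["auc_rico"], str(path), line, "auc_rico"),
            auc_rico_haemate=(
                None if haemate_raw.lower() in _UNKNOWN
                else _to_float(haemate_raw, str(path), line, "auc_rico_haemate")
            ),
        ))
    return panels


def write_panel_csv(
    panels: Sequence[RicotemPanel],
    path: Union[str, os.PathLike],
    force: bool = False,
) -> None:
    _guard_overwrite(path, force)
    rows = [{
        "patient_id": p.patient_id or "",
        "auc_extem": p.auc_extem,
        "auc_rico": p.auc_rico,
        "auc_rico_haemate": "" if p.auc_rico_haemate is None else p.auc_rico_haemate,
    } for p in panels]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def attach_panels(
    records: Sequence[PatientRecord], panels: Sequence[RicotemPanel]
) -> List[PatientRecord]:
    """Join panels onto records by patient id (records without a panel keep none)."""
    by_id = {p.patient_id: p for p in panels}
    for rec in records:
        if rec.patient_id in by_id:
            rec.panel = by_id[rec.patient_id]
    return list(records)


# ---------------------------------------------------------------------------
# reports and configuration

def _guard_overwrite(path: Union[str, os.PathLike], force: bool) -> None:
    if not force and os.path.exists(path):
        raise FileExistsError(f"{path} exists; pass force=True / --force to overwrite")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "value") and obj.__class__.__module__.endswith("labs"):
        return obj.value  # VwdPhenotype
    return obj


def write_report(
    report: dict,
    path: Optional[Union[str, os.PathLike]] = None,
    force: bool = False,
) -> str:
    """Serialize a report dict to versioned JSON; return the JSON string.

    Writes to ``path`` when given (refusing to overwrite without ``force``),
    otherwise the caller prints the returned string.
    """
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update(_jsonable(report))
    text = json.dumps(payload, indent=2, sort_keys=False)
    if path is not None:
        _guard_overwrite(path, force)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


@dataclass(frozen=True)
class RunConfig:
    """Validated end-to-end run configuration."""

    seed: int = 42
    auc_scale: float = 100.0
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.auc_scale <= 0:
            raise InvalidParameterError("auc_scale must be positive")
        if self.verbosity not in ("debug", "info", "warning", "error"):
            raise InvalidParameterError(
                f"verbosity must be debug|info|warning|error, got {self.verbosity!r}"
            )


def load_config(path: Union[str, os.PathLike]) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    known = {"seed", "auc_scale", "cutoffs", "cohort", "verbosity"}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(
            f"{path}: unknown config key(s) {sorted(unknown)}; known keys: {sorted(known)}"
        )
    kwargs: dict = {k: raw[k] for k in ("seed", "auc_scale", "verbosity") if k in raw}
    if "cutoffs" in raw:
        if not isinstance(raw["cutoffs"], dict):
            raise SchemaError(f"{path}: 'cutoffs' must be a mapping")
        try:
            kwargs["cutoffs"] = CutoffConfig(**raw["cutoffs"])
        except TypeError as exc:
            raise SchemaError(f"{path}: bad cutoffs section ({exc})") from exc
    if "cohort" in raw:
        if not isinstance(raw["cohort"], dict):
            raise SchemaError(f"{path}: 'cohort' must be a mapping")
        kwargs["cohort"] = CohortSpec.from_dict(raw["cohort"])
    return RunConfig(**kwargs)
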