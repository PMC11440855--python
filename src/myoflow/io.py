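"""File formats: TAC CSV, polar-map CSV, cohort CSV, YAML config, JSON reports.

All CSVs are UTF-8, comma-separated, '.' decimal, header row mandatory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from .cohort import ARTERIES, TERRITORIES, PatientRecord
from .flowmodel import compute_flow_metrics
from .frames import FrameSchedule, SampledCurve
from .scoring import N_SEGMENTS, PolarMap, SummedScores
from .synthesis import CohortConfig, TruthRecord

__all__ = [
    "RunConfig",
    "load_run_config",
    "read_tac_csv",
    "write_tac_csv",
    "read_polar_map_csv",
    "write_polar_map_csv",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_truth_json",
    "write_report_json",
    "config_hash",
]

TAC_COLUMNS = ["frame_start_s", "frame_duration_s", "value_kbq_ml", "region"]
POLAR_COLUMNS = ["segment", "uptake_pct", "state"]


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    variant: str = "NAC"
    weighting: str = "duration"
    thresholds: tuple[float, float, float, float] = (70.0, 50.0, 30.0, 10.0)
    schedule: dict[str, float] = field(default_factory=dict)
    cohort: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.variant not in ("NAC", "AC"):
            raise ValueError("variant must be 'NAC' or 'AC'")
        if self.weighting not in ("duration", "uniform"):
            raise ValueError("weighting must be 'duration' or 'uniform'")
        allowed_sched = {"n_short", "short_s", "n_long", "long_s", "pre_injection_offset_s"}
        unknown = set(self.schedule) - allowed_sched
        if unknown:
            raise ValueError(f"unknown schedule keys: {sorted(unknown)}")
        allowed_cohort = {f.name for f in dataclasses.fields(CohortConfig)}
        unknown = set(self.cohort) - allowed_cohort
        if unknown:
            raise ValueError(f"unknown cohort keys: {sorted(unknown)}")

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(**self.cohort)


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "thresholds" in raw:
        raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the configuration for output provenance."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# TAC files


def write_tac_csv(path: str | Path, curves: Iterable[SampledCurve]) -> None:
    rows = []
    for curve in curves:
        for (start, dur), value in zip(curve.schedule.frames, curve.values):
            rows.append(
                {
                    "frame_start_s": start,
                    "frame_duration_s": dur,
                    "value_kbq_ml": value,
                    "region": curve.region_label,
                }
            )
    pd.DataFrame(rows, columns=TAC_COLUMNS).to_csv(path, index=False)


def read_tac_csv(
    path: str | Path, pre_injection_offset_s: float = 10.0
) -> dict[str, SampledCurve]:
    """Read one or more region curves from a TAC CSV, keyed by region."""
    df = pd.read_csv(path)
    missing = set(TAC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TAC file missing columns: {sorted(missing)}")
    out: dict[str, SampledCurve] = {}
    for region, grp in df.groupby("region", sort=False):
        grp = grp.sort_values("frame_start_s")
        schedule = FrameSchedule(
            tuple(zip(grp["frame_start_s"], grp["frame_duration_s"])),
            pre_injection_offset_s=pre_injection_offset_s,
        )
        out[str(region)] = SampledCurve(
            schedule, grp["value_kbq_ml"].to_numpy(), region_label=str(region)
        )
    return out


# ---------------------------------------------------------------------------
# polar maps


def write_polar_map_csv(path: str | Path, maps: Iterable[PolarMap]) -> None:
    rows = [
        {"segment": seg + 1, "uptake_pct": up, "state": pm.state}
        for pm in maps
        for seg, up in enumerate(pm.uptake)
    ]
    pd.DataFrame(rows, columns=POLAR_COLUMNS).to_csv(path, index=False)


def read_polar_map_csv(path: str | Path) -> dict[str, PolarMap]:
    df = pd.read_csv(path)
    missing = set(POLAR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"polar-map file missing columns: {sorted(missing)}")
    out: dict[str, PolarMap] = {}
    for state, grp in df.groupby("state", sort=False):
        grp = grp.sort_values("segment")
        if list(grp["segment"]) != list(range(1, N_SEGMENTS + 1)):
            raise ValueError(f"state {state!r} must carry segments 1..{N_SEGMENTS}")
        out[str(state)] = PolarMap(grp["uptake_pct"].to_numpy(), state=str(state))
    return out


# ---------------------------------------------------------------------------
# cohort tables

_PATIENT_COLS = [
    "troponin_24h",
    "troponin_d4",
    "troponin_d7",
    "is_pct",
    "mvo_pct",
    "edema_pct",
    "sss",
    "srs",
    "lm_stenosis_pct",
]
_TERRITORY_COLS = [
    "patient_id",
    "territory",
    "stenosis_pct",
    "lge",
    "edema",
    "rest_mbf_nac",
    "stress_mbf_nac",
    "rest_mbf_ac",
    "stress_mbf_ac",
    "global_rest_mbf_nac",
    "global_stress_mbf_nac",
    "global_rest_mbf_ac",
    "global_stress_mbf_ac",
]
COHORT_COLUMNS = _TERRITORY_COLS + _PATIENT_COLS


def cohort_to_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    """One row per patient-territory, patient-level columns repeated."""
    rows = []
    for p in patients:
        for terr in TERRITORIES:
            lge, edema = p.territory_flags[terr]
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "territory": terr,
                    "stenosis_pct": p.stenosis_pct[terr],
                    "lge": bool(lge),
                    "edema": bool(edema),
                    "rest_mbf_nac": p.flow["NAC"][terr].rest_mbf,
                    "stress_mbf_nac": p.flow["NAC"][terr].stress_mbf,
                    "rest_mbf_ac": p.flow["AC"][terr].rest_mbf,
                    "stress_mbf_ac": p.flow["AC"][terr].stress_mbf,
                    "global_rest_mbf_nac": p.flow["NAC"]["global"].rest_mbf,
                    "global_stress_mbf_nac": p.flow["NAC"]["global"].stress_mbf,
                    "global_rest_mbf_ac": p.flow["AC"]["global"].rest_mbf,
                    "global_stress_mbf_ac": p.flow["AC"]["global"].stress_mbf,
                    "troponin_24h": p.troponin_ng_ml[0],
                    "troponin_d4": p.troponin_ng_ml[1],
                    "troponin_d7": p.troponin_ng_ml[2],
                    "is_pct": p.cmr["infarct_size_pct_lv"],
                    "mvo_pct": p.cmr["mvo_pct_lv"],
                    "edema_pct": p.cmr["edema_pct_lv"],
                    "sss": p.summed.sss,
                    "srs": p.summed.srs,
                    "lm_stenosis_pct": p.stenosis_pct["LM"],
                }
            )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    """Rebuild patient records from a cohort table (strict schema)."""
    unknown = set(df.columns) - set(COHORT_COLUMNS)
    if unknown:
        raise ValueError(f"unknown cohort columns: {sorted(unknown)}")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    patients = []
    for pid, grp in df.groupby("patient_id", sort=False):
        if sorted(grp["territory"]) != sorted(TERRITORIES):
            raise ValueError(f"patient {pid} must have exactly territories {TERRITORIES}")
        grp = grp.set_index("territory")
        first = grp.iloc[0]
        stenoses = {t: float(grp.loc[t, "stenosis_pct"]) for t in TERRITORIES}
        stenoses["LM"] = float(first["lm_stenosis_pct"])
        flow = {}
        for variant in ("NAC", "AC"):
            v = variant.lower()
            flow[variant] = {
                "global": compute_flow_metrics(
                    float(first[f"global_rest_mbf_{v}"]),
                    float(first[f"global_stress_mbf_{v}"]),
                    variant=variant,
                    region_label="global",
                )
            }
            for t in TERRITORIES:
                flow[variant][t] = compute_flow_metrics(
                    float(grp.loc[t, f"rest_mbf_{v}"]),
                    float(grp.loc[t, f"stress_mbf_{v}"]),
                    variant=variant,
                    region_label=t,
                )
        sss, srs = int(first["sss"]), int(first["srs"])
        patients.append(
            PatientRecord(
                patient_id=str(pid),
                stenosis_pct=stenoses,
                flow=flow,
                summed=SummedScores(sss=sss, srs=srs, sds=sss - srs),
                troponin_ng_ml=(
                    float(first["troponin_24h"]),
                    float(first["troponin_d4"]),
                    float(first["troponin_d7"]),
                ),
                cmr={
                    "infarct_size_pct_lv": float(first["is_pct"]),
                    "mvo_pct_lv": float(first["mvo_pct"]),
                    "edema_pct_lv": float(first["edema_pct"]),
                },
                territory_flags={
                    t: (bool(grp.loc[t, "lge"]), bool(grp.loc[t, "edema"]))
                    for t in TERRITORIES
                },
            )
        )
    return patients


def write_cohort_csv(path: str | Path, patients: Iterable[PatientRecord]) -> None:
    cohort_to_frame(patients).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    return frame_to_cohort(pd.read_csv(path))


# ---------------------------------------------------------------------------
# JSON outputs


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report_json(path: str | Path, report: Any, meta: dict | None = None) -> None:
    payload = _jsonify(report)
    if meta:
        payload = {"meta": _jsonify(meta), **payload} if isinstance(payload, dict) else {
            "meta": _jsonify(meta),
            "report": payload,
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def write_truth_json(path: str | Path, truths: Iterable[TruthRecord], meta: dict | None = None) -> None:
    payload = {"meta": _jsonify(meta or {}), "truth": [_jsonify(t) for t in truths]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
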