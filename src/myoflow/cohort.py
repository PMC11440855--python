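"""Patient/territory classification and the study-level statistical report.

Patients presenting with acute myocardial infarction are split by invasive
angiography into MINOCA (no coronary stenosis >= 50%) and MICAD (at least
one obstructive lesion).  Vessel territories are called "injured" when CMR
shows both late gadolinium enhancement and edema.  The report mirrors the
study tables: per-group median (IQR) with Mann-Whitney U comparisons,
Spearman correlations of flow against troponin and CMR burden, per-territory
injured-vs-not comparisons, and exact count summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .flowmodel import FlowMetrics
from .scoring import SummedScores, classify_abnormal
from .stats import fisher_exact, mann_whitney, median_iqr, spearman

__all__ = [
    "ARTERIES",
    "TERRITORIES",
    "PatientRecord",
    "GroupComparison",
    "CorrelationResult",
    "classify_patient",
    "classify_territory",
    "vessel_summary",
    "run_study_analysis",
]

ARTERIES = ("LAD", "LCx", "RCA", "LM")
TERRITORIES = ("LAD", "LCx", "RCA")
OBSTRUCTIVE_THRESHOLD_PCT = 50.0


def classify_patient(stenoses: Mapping[str, float]) -> str:
    """MICAD iff any artery has stenosis >= 50% (inclusive), else MINOCA."""
    missing = [a for a in ARTERIES if a not in stenoses]
    if missing:
        raise ValueError(f"missing stenosis values for arteries: {missing}")
    vals = [float(stenoses[a]) for a in ARTERIES]
    if any(not 0 <= v <= 100 for v in vals):
        raise ValueError("stenosis percentages must be in [0, 100]")
    return "MICAD" if max(vals) >= OBSTRUCTIVE_THRESHOLD_PCT else "MINOCA"


def classify_territory(lge_present: bool, edema_present: bool) -> str:
    """Acute myocardial injury requires both LGE and edema on CMR."""
    return "injured" if (lge_present and edema_present) else "not_injured"


@dataclass
class PatientRecord:
    """One patient: angiography, flow quantification, scores, biomarkers, CMR."""

    patient_id: str
    stenosis_pct: dict[str, float]  # per artery, ARTERIES keys
    #: variant -> region -> FlowMetrics; regions "global" plus TERRITORIES
    flow: dict[str, dict[str, FlowMetrics]]
    summed: SummedScores
    troponin_ng_ml: tuple[float, float, float]  # 24 h, day 4, day 7
    cmr: dict[str, float]  # infarct_size_pct_lv, mvo_pct_lv, edema_pct_lv
    #: territory -> (lge_present, edema_present)
    territory_flags: dict[str, tuple[bool, bool]]
    group: str = field(init=False)

    def __post_init__(self) -> None:
        self.group = classify_patient(self.stenosis_pct)
        if any(t < 0 for t in self.troponin_ng_ml):
            raise ValueError("troponin values must be >= 0")
        for key in ("infarct_size_pct_lv", "mvo_pct_lv", "edema_pct_lv"):
            v = self.cmr.get(key)
            if v is None or not 0 <= v <= 100:
                raise ValueError(f"CMR field {key} must be present and in [0, 100]")
        if sorted(self.territory_flags) != sorted(TERRITORIES):
            raise ValueError("exactly the 3 coronary territories must carry flags")

    def territory_injury(self, territory: str) -> str:
        return classify_territory(*self.territory_flags[territory])


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    groups: tuple[str, str]
    medians: tuple[float, float]
    iqrs: tuple[tuple[float, float], tuple[float, float]]
    u: float
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    rho: float
    p_value: float


def vessel_summary(cohort: Iterable[PatientRecord]) -> dict:
    """Exact per-vessel and per-patient count tallies.

    Counts total/injured/non-injured territories (3 per patient), obstructive
    vessels (stenosis >= 50%) per artery, and the distribution of patients by
    number of diseased vessels.
    """
    patients = list(cohort)
    injured_by_group: dict[str, int] = {"MINOCA": 0, "MICAD": 0}
    not_injured_by_group: dict[str, int] = {"MINOCA": 0, "MICAD": 0}
    obstructed_by_artery: dict[str, int] = {a: 0 for a in ARTERIES}
    multiplicity: dict[int, int] = {}
    group_sizes: dict[str, int] = {"MINOCA": 0, "MICAD": 0}

    for p in patients:
        if sorted(p.territory_flags) != sorted(TERRITORIES):
            raise ValueError(f"patient {p.patient_id} must carry 3 territories")
        group_sizes[p.group] += 1
        n_obstructed = 0
        for a in ARTERIES:
            if p.stenosis_pct[a] >= OBSTRUCTIVE_THRESHOLD_PCT:
                obstructed_by_artery[a] += 1
                n_obstructed += 1
        multiplicity[n_obstructed] = multiplicity.get(n_obstructed, 0) + 1
        for t in TERRITORIES:
            if p.territory_injury(t) == "injured":
                injured_by_group[p.group] += 1
            else:
                not_injured_by_group[p.group] += 1

    injured_total = sum(injured_by_group.values())
    not_injured_total = sum(not_injured_by_group.values())
    return {
        "n_patients": len(patients),
        "group_sizes": group_sizes,
        "territories_total": 3 * len(patients),
        "injured_total": injured_total,
        "injured_by_group": injured_by_group,
        "not_injured_total": not_injured_total,
        "not_injured_by_group": not_injured_by_group,
        "obstructed_vessels_by_artery": obstructed_by_artery,
        "obstructed_vessels_total": sum(obstructed_by_artery.values()),
        "patients_by_vessel_multiplicity": multiplicity,
    }


def _patient_variables(p: PatientRecord, variant: str) -> dict[str, float]:
    g = p.flow[variant]["global"]
    return {
        "stress_mbf": g.stress_mbf,
        "rest_mbf": g.rest_mbf,
        "mfr": g.mfr,
        "fd": g.fd,
        "sss": float(p.summed.sss),
        "srs": float(p.summed.srs),
        "sds": float(p.summed.sds),
        "troponin_24h": p.troponin_ng_ml[0],
        "troponin_d4": p.troponin_ng_ml[1],
        "troponin_d7": p.troponin_ng_ml[2],
        "infarct_size_pct_lv": p.cmr["infarct_size_pct_lv"],
        "mvo_pct_lv": p.cmr["mvo_pct_lv"],
        "edema_pct_lv": p.cmr["edema_pct_lv"],
    }


_FLOW_VARS = ("stress_mbf", "rest_mbf", "mfr", "fd")
_CORR_TARGETS = (
    "troponin_24h",
    "troponin_d4",
    "troponin_d7",
    "infarct_size_pct_lv",
    "mvo_pct_lv",
    "edema_pct_lv",
)


def run_study_analysis(cohort: Iterable[PatientRecord], variant: str = "NAC") -> dict:
    """Full study report for one reconstruction variant.

    Sections: ``group_comparisons`` (MINOCA vs MICAD medians/IQR with
    Mann-Whitney U), ``correlations`` (Spearman, global flow vs troponin and
    CMR variables), ``territory_comparisons`` (injured vs non-injured
    territory flows) and ``counts``.  Degenerate comparisons (a group with
    < 2 patients, constant vectors) are skipped with a warning; counts are
    always emitted.
    """
    patients = list(cohort)
    table = {p.patient_id: _patient_variables(p, variant) for p in patients}
    by_group: dict[str, list[PatientRecord]] = {"MINOCA": [], "MICAD": []}
    for p in patients:
        by_group[p.group].append(p)

    report: dict = {
        "variant": variant,
        "group_comparisons": [],
        "correlations": [],
        "territory_comparisons": [],
        "counts": vessel_summary(patients),
        "warnings": [],
    }

    n_abnormal = {
        g: sum(classify_abnormal(p.summed) for p in ps) for g, ps in by_group.items()
    }
    report["counts"]["abnormal_perfusion_by_group"] = n_abnormal
    report["counts"]["abnormal_perfusion_total"] = sum(n_abnormal.values())

    groups_ok = all(len(ps) >= 2 for ps in by_group.values())
    all_vars = list(table[patients[0].patient_id]) if patients else []

    if groups_ok:
        for var in all_vars:
            a = np.array([table[p.patient_id][var] for p in by_group["MINOCA"]])
            b = np.array([table[p.patient_id][var] for p in by_group["MICAD"]])
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                # identical constant groups: no difference by construction
                med, q25, q75 = median_iqr(a)
                report["group_comparisons"].append(
                    GroupComparison(
                        var, ("MINOCA", "MICAD"), (med, med),
                        ((q25, q75), (q25, q75)), float(a.size * b.size) / 2, 1.0,
                    )
                )
                continue
            mw = mann_whitney(a, b)
            med_a, q25a, q75a = median_iqr(a)
            med_b, q25b, q75b = median_iqr(b)
            report["group_comparisons"].append(
                GroupComparison(
                    variable=var,
                    groups=("MINOCA", "MICAD"),
                    medians=(med_a, med_b),
                    iqrs=((q25a, q75a), (q25b, q75b)),
                    u=mw.u,
                    p_value=mw.p_value,
                )
            )
        # injured-territory frequency: MINOCA vs MICAD Fisher exact
        c = report["counts"]
        ct = [
            [c["injured_by_group"]["MINOCA"], c["not_injured_by_group"]["MINOCA"]],
            [c["injured_by_group"]["MICAD"], c["not_injured_by_group"]["MICAD"]],
        ]
        report["counts"]["injury_fisher_p"] = fisher_exact(np.array(ct, dtype=int))
    else:
        msg = "a group has < 2 patients; group comparisons skipped"
        warnings.warn(msg, stacklevel=2)
        report["warnings"].append(msg)

    for flow_var in _FLOW_VARS:
        x = np.array([table[p.patient_id][flow_var] for p in patients])
        for target in _CORR_TARGETS:
            y = np.array([table[p.patient_id][target] for p in patients])
            try:
                sp = spearman(x, y)
            except ValueError as err:
                msg = f"correlation {flow_var} vs {target} undefined: {err}"
                report["warnings"].append(msg)
                continue
            report["correlations"].append(
                CorrelationResult(pair=f"{flow_var}~{target}", rho=sp.rho, p_value=sp.p_value)
            )

    # per-territory injured vs non-injured flow comparisons
    for flow_var in _FLOW_VARS:
        injured, healthy = [], []
        for p in patients:
            for t in TERRITORIES:
                fm = p.flow[variant][t]
                val = getattr(fm, {"stress_mbf": "stress_mbf", "rest_mbf": "rest_mbf",
                                   "mfr": "mfr", "fd": "fd"}[flow_var])
                (injured if p.territory_injury(t) == "injured" else healthy).append(val)
        if len(injured) < 2 or len(healthy) < 2:
            msg = f"territory comparison for {flow_var} skipped (degenerate split)"
            report["warnings"].append(msg)
            continue
        a, b = np.array(healthy), np.array(injured)
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            report["warnings"].append(
                f"territory comparison for {flow_var} degenerate (all equal)"
            )
            continue
        mw = mann_whitney(a, b)
        med_a, q25a, q75a = median_iqr(a)
        med_b, q25b, q75b = median_iqr(b)
        report["territory_comparisons"].append(
            GroupComparison(
                variable=flow_var,
                groups=("not_injured", "injured"),
                medians=(med_a, med_b),
                iqrs=((q25a, q75a), (q25b, q75b)),
                u=mw.u,
                p_value=mw.p_value,
            )
        )
    return report
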