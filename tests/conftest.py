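import numpy as np
import pytest

from myoflow import (
    InputFunctionModel,
    PatientRecord,
    SummedScores,
    compute_flow_metrics,
    default_frame_schedule,
    simulate_input_function,
)


@pytest.fixture(scope="session")
def schedule():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def input_model():
    return InputFunctionModel()


@pytest.fixture(scope="session")
def input_curve(input_model, schedule):
    return simulate_input_function(input_model, schedule)


def make_patient(
    pid="P001",
    stenoses=None,
    injured=(),
    rest=0.7,
    stress=2.0,
    sss=0,
    srs=0,
    troponin=(1.0, 0.5, 0.1),
    cmr=None,
):
    """Minimal hand-built patient for count/classification tests."""
    stenoses = dict(stenoses or {"LAD": 0.0, "LCx": 0.0, "RCA": 0.0, "LM": 0.0})
    flow = {
        variant: {
            region: compute_flow_metrics(rest, stress, variant=variant, region_label=region)
            for region in ("global", "LAD", "LCx", "RCA")
        }
        for variant in ("NAC", "AC")
    }
    return PatientRecord(
        patient_id=pid,
        stenosis_pct=stenoses,
        flow=flow,
        summed=SummedScores(sss=sss, srs=srs, sds=sss - srs),
        troponin_ng_ml=troponin,
        cmr=cmr
        or {"infarct_size_pct_lv": 5.0, "mvo_pct_lv": 0.0, "edema_pct_lv": 5.0},
        territory_flags={
            t: ((True, True) if t in injured else (False, False))
            for t in ("LAD", "LCx", "RCA")
        },
    )


def build_published_counts_cohort():
    """Cohort reproducing the printed study tallies exactly.

    31 patients (10 MINOCA / 21 MICAD); obstructed vessels 14 LAD, 4 LCx,
    11 RCA distributed as 14 one-vessel, 6 two-vessel and 1 three-vessel
    patients; 5 injured territories in MINOCA and 34 in MICAD.
    """
    patients = []
    # MICAD vessel-disease layout: 1x3-vessel, 6x2-vessel, 14x1-vessel
    # column sums: LAD 14, LCx 4, RCA 11  (total 29)
    layouts = (
        [("LAD", "LCx", "RCA")]
        + [("LAD", "RCA")] * 3
        + [("LAD", "LCx")] * 2
        + [("LAD", "RCA")] * 1
        + [("LAD",)] * 7
        + [("LCx",)] * 1
        + [("RCA",)] * 6
    )
    assert len(layouts) == 21
    # injured territories: 34 across 21 MICAD patients (63 territories)
    micad_injured = [2] * 13 + [1] * 8  # 26 + 8 = 34
    terrs = ("LAD", "LCx", "RCA")
    for i, (layout, n_inj) in enumerate(zip(layouts, micad_injured)):
        stenoses = {a: (70.0 if a in layout else 20.0) for a in terrs}
        stenoses["LM"] = 0.0
        patients.append(
            make_patient(
                pid=f"D{i:03d}", stenoses=stenoses, injured=terrs[:n_inj],
                stress=0.9, sss=8, srs=5,
            )
        )
    minoca_injured = [1] * 5 + [0] * 5  # 5 injured of 30
    for i, n_inj in enumerate(minoca_injured):
        patients.append(
            make_patient(pid=f"N{i:03d}", injured=terrs[:n_inj], stress=2.0, sss=4, srs=2)
        )
    return patients
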