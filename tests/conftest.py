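from datetime import datetime

import pytest
from hypothesis import HealthCheck, settings

from wardpath import Event, PatientPathway, Stage, Trace
from wardpath.model import COMPLETE, START
from wardpath.synth import default_registry, fixture_ghbs_mini

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_stage(unit, start, end, resp=None, label=None, case="C", patient="P"):
    return Stage(
        activity=unit,
        start_ts=start,
        end_ts=end,
        events=(
            Event(case, patient, unit, START, start, resp, label),
            Event(case, patient, unit, COMPLETE, end, resp, label),
        ),
        responsible_unit=resp,
        transfer_label=label,
    )


def make_pathway(stage_specs, case="C1", fit=None, ref=None, dispo="home"):
    """stage_specs: list of (unit, start, end[, resp[, label]])."""
    stages = []
    for spec in stage_specs:
        unit, start, end = spec[0], spec[1], spec[2]
        resp = spec[3] if len(spec) > 3 else None
        label = spec[4] if len(spec) > 4 else None
        stages.append(make_stage(unit, start, end, resp, label, case))
    return PatientPathway(
        patient_id="P" + case,
        stay_id=case,
        trace=Trace(case_id=case, stages=stages),
        discharge_disposition=dispo,
        fit_for_discharge_ts=fit,
        reference_los_days=ref,
    )


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def mini_fixture():
    return fixture_ghbs_mini()


FIG2_FIT = datetime(2021, 1, 10, 14, 0)


@pytest.fixture
def fig2_pathway():
    """The canonical worked pathway: ED -> OU (awaiting bed) -> geriatrics
    with an inter-site transfer gap, fit for discharge before the actual
    discharge."""
    return make_pathway(
        [
            ("ED", datetime(2021, 1, 4, 5, 36), datetime(2021, 1, 4, 10, 13)),
            ("OU", datetime(2021, 1, 4, 10, 13), datetime(2021, 1, 5, 9, 45),
             None, "awaiting bed"),
            ("GERIATRICS", datetime(2021, 1, 5, 10, 15), datetime(2021, 1, 12, 13, 30),
             "GERIATRICS", None),
        ],
        case="00000056098",
        fit=FIG2_FIT,
        ref=9.0,
    )
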