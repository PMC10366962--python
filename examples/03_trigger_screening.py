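"""Screen laboratory values against adverse-drug-event triggers.

A patient on parenteral furosemide with a latest serum glucose of
130 mg/dL (expected range 0-110) and a potassium of 2.8 mEq/L (low
bound 2.9): both trigger rules fire, each flagging a possible adverse
drug event for review. Only the most recent value of each test counts.
"""

import datetime as dt

from medscreen import screen_triggers
from medscreen.demo import (
    FUROSEMIDE, ONCE_DAILY, ORAL_TABLET, POTASSIUM, SERUM_GLUCOSE, build_demo_kb,
)
from medscreen.kb import ConceptRef
from medscreen.patient import LabResult, MedicationOrder, PatientCase

kb = build_demo_kb()
UTC = dt.timezone.utc

case = PatientCase(
    patient_id="example-3", age_years=79,
    orders=[MedicationOrder(
        order_id="o1",
        vmp=ConceptRef(id="demo:vmp/plainol-10mg-tablet", label="Plainol 10mg tablet (demo)"),
        ingredient=FUROSEMIDE, form_route=ORAL_TABLET,
        dose=40.0, dose_unit="mg", frequency=ONCE_DAILY, prn=False, route="parenteral")],
    labs=[
        # an older, normal glucose superseded by an abnormal one
        LabResult(test=SERUM_GLUCOSE, value=98.0, unit="mg/dL",
                  observed_at=dt.datetime(2022, 7, 1, 8, 0, tzinfo=UTC)),
        LabResult(test=SERUM_GLUCOSE, value=130.0, unit="mg/dL",
                  observed_at=dt.datetime(2022, 7, 2, 8, 0, tzinfo=UTC)),
        LabResult(test=POTASSIUM, value=2.8, unit="mEq/L",
                  observed_at=dt.datetime(2022, 7, 2, 8, 0, tzinfo=UTC)),
    ])

for hit in screen_triggers(case, kb):
    e = hit.entry
    print(f"{e.lab_test.label}: {hit.observed_value} {hit.observed_unit} "
          f"is {hit.direction} of [{e.low:g}, {e.high:g}] under {e.ingredient.label}")
print("Each hit flags a possible adverse drug event; dose plays no role in trigger rules.")
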