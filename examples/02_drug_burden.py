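"""Compute the anticholinergic/sedative drug burden of a regimen.

Each burden-listed drug contributes D/(δ+D), where D is the daily dose
and δ the minimum effective daily dose: alprazolam 0.5 mg once daily
sits exactly at its δ of 0.5 mg and contributes 0.5; a second listed
drug at its own δ pushes the total to 1.0, the alerting cut-off.
"""

from medscreen import score_dbi
from medscreen.demo import ALPRAZOLAM, DEMO_SEDANOL, ONCE_DAILY, ORAL_TABLET, build_demo_kb
from medscreen.kb import ConceptRef
from medscreen.patient import MedicationOrder, PatientCase

kb = build_demo_kb()


def order(oid, ingredient, dose):
    return MedicationOrder(
        order_id=oid,
        vmp=ConceptRef(id="demo:vmp/sedanol-5mg-tablet", label="Sedanol 5mg tablet (demo)"),
        ingredient=ingredient, form_route=ORAL_TABLET,
        dose=dose, dose_unit="mg", frequency=ONCE_DAILY, prn=False, route="oral")


case = PatientCase(patient_id="example-2", age_years=86, orders=[
    order("o1", ALPRAZOLAM, 0.5),       # at its minimum effective daily dose
    order("o2", DEMO_SEDANOL, 10.0),    # at its (synthetic) minimum dose
])

score = score_dbi(case, kb)
for t in score.terms:
    print(f"{t.ingredient.label:35s} D={t.daily_dose:g} mg, delta={t.delta:g} mg -> term {t.term:.3f}")
print(f"total drug burden: {score.total:.3f}")
print("A total of 1.0 or more marks a high cumulative sedative/anticholinergic exposure.")
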