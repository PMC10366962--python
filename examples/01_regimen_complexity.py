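"""Score the complexity of a small regimen.

Three oral-tablet products taken once daily: section A counts the
oral-tablet form once (weight 1), section B adds 1 per once-daily order,
and no product carries extra-instruction weights.
"""

from medscreen import score_mrci
from medscreen.demo import ONCE_DAILY, ORAL_TABLET, build_demo_kb
from medscreen.kb import ConceptRef
from medscreen.patient import MedicationOrder, PatientCase

kb = build_demo_kb()

orders = [
    MedicationOrder(
        order_id=f"o{i}",
        vmp=ConceptRef(id="demo:vmp/plainol-10mg-tablet", label="Plainol 10mg tablet (demo)"),
        ingredient=ConceptRef(id="demo:ing/plainol", label="Plainol (demo, burden-free)"),
        form_route=ORAL_TABLET, dose=10.0, dose_unit="mg",
        frequency=ONCE_DAILY, prn=False, route="oral")
    for i in range(3)
]
case = PatientCase(patient_id="example-1", age_years=83, orders=orders)

score = score_mrci(case, kb)
print(f"section A (distinct forms) : {score.section_a}")
print(f"section B (frequencies)    : {score.section_b}")
print(f"section C (instructions)   : {score.section_c}")
print(f"total complexity           : {score.total}")
print("Three oral tablets count as ONE form/route combination, so A is 1, not 3;")
print("each once-daily order adds the baseline frequency weight of 1.")
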