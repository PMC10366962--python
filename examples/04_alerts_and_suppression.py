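"""Full evaluation with soft-stop alert suppression.

A JSON request for an 86-year-old on two burden-listed drugs crosses the
burden threshold and raises one blue (risk-minimization) alert listing
both drugs. The clinician ignores it; on re-evaluation the alert is
suppressed — the ignore-once rule against alert fatigue. Accepted alerts
would keep reappearing while the condition persists.
"""

import json

from medscreen import SuppressionRegistry, handle_request, record_response
from medscreen.demo import build_demo_kb

kb = build_demo_kb()
registry = SuppressionRegistry()

request = json.dumps({
    "patient": {"id": "ward-12", "age": 86},
    "orders": [
        {"id": "o1", "vmp": {"id": "demo:vmp/sedanol-5mg-tablet", "label": "Sedanol 5mg tablet (demo)"},
         "ingredient": {"id": "ing:alprazolam", "label": "Alprazolam"},
         "form_route": {"code": "LOC-TAB-ORAL", "vocabulary": "demo"},
         "dose": 0.5, "unit": "mg",
         "frequency": {"code": "LOC-FREQ-QD", "vocabulary": "demo"},
         "prn": False, "route": "oral"},
        {"id": "o2", "vmp": {"id": "demo:vmp/sedanol-5mg-tablet", "label": "Sedanol 5mg tablet (demo)"},
         "ingredient": {"id": "demo:ing/sedanol", "label": "Sedanol (demo sedative)"},
         "form_route": {"id": "form:oral-tablet", "label": "Oral tablet"},
         "dose": 10.0, "unit": "mg",
         "frequency": {"id": "freq:once-daily", "label": "Once daily"},
         "prn": False, "route": "oral"},
    ],
    "labs": [],
})

first = handle_request(request, kb, registry)
print(f"drug burden total: {first.scores.dbi_total:.2f}")
for a in first.alerts:
    print(f"alert [{a.color}] {a.description}: {a.text}")

record_response(registry, "ward-12", first.alerts[0].alert_id, "ignored")
second = handle_request(request, kb, registry)
print(f"after ignoring once: {len(second.alerts)} alert(s) shown, "
      f"{len(second.suppressed)} suppressed")
print("An alert ignored once is never re-displayed for that patient.")
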