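"""Evaluate a synthetic ward and summarise the alerts raised.

Generates a seeded cohort shaped like a polypharmacy internal-medicine
ward (ages 66-95, 8-20 concurrent medications), screens every patient,
and tabulates the emitted alerts per use case — the structure of a
deployment activity report.
"""

from medscreen import FixtureSpec, evaluate, summarize
from medscreen.demo import build_demo_kb, generate_cases

kb = build_demo_kb()
cases = generate_cases(FixtureSpec(seed=42, n_patients=50), kb)
results = [evaluate(case, kb) for case in cases]

alerted = sum(1 for r in results if r.alerts)
print(f"patients evaluated: {len(results)}; with at least one alert: {alerted}")
print(summarize(results).round(1))
print("share_pct is each use case's share of all emitted alerts.")
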