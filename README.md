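# medscreen

Medication-appropriateness screening for older adults with
multimorbidity. `medscreen` is the decision-support engine a hospital
pharmacy would sit behind its prescribing system: on every prescribing
event it screens the patient's regimen and laboratory results against a
knowledge base of drug-appropriateness facts and raises suppressible,
color-coded soft-stop alerts. It is aimed at clinical pharmacists and
medical-informatics developers who need the scoring rules as a testable
library rather than as logic buried in an EHR integration.

## What it computes

**Medication Regimen Complexity Index (MRCI).** A weighted sum over
three sections: section A weights the *distinct* dosage-form /
administration-route combinations in the regimen (an oral tablet is the
reference, weight 1 — a regimen of three oral tablets scores A = 1, not
3), section B adds a per-order dosing-frequency weight (once daily is
the baseline, weight 1), and section C adds per-product
extra-instruction weights. Higher totals mean harder-to-manage
regimens; the engine alerts at MRCI ≥ 40.

**Drug Burden Index (DBI).** Cumulative anticholinergic and sedative
exposure,

```
DBI = Σ D / (δ + D)
```

summed over every prescribed drug on the burden list, where *D* is the
patient's daily dose (derived from dose, dose unit and frequency, with
unit conversion) and *δ* the drug's minimum effective daily dose. A
drug at its minimum effective dose contributes exactly 0.5; the engine
alerts at DBI ≥ 1.

**Laboratory triggers.** Each trigger pairs a high-alert ingredient
with a laboratory test and its in-range interval; the most recent value
of the test strictly outside the interval flags a possible adverse drug
event (for example potassium < 2.9 mEq/L under a loop diuretic),
regardless of dose.

Screening applies to patients aged ≥ 65 (configurable). "As needed"
(PRN) orders are excluded from all three computations by default.
Alerts are soft stops with deterministic identifiers: an alert a
clinician ignores once is never re-displayed for that patient, while an
accepted alert reappears as long as its condition persists. Display
colors encode clinical relevance (red = contraindicated, orange =
moderate, yellow = low, blue = risk minimization).

The knowledge base is a typed model with three interchangeable
serialisations — RDF/Turtle (SPARQL-queryable), a JSON document, and a
directory of CSV tables — plus local-to-canonical concept mapping
tables for prescribing-system vocabularies. A packaged demo KB carries
the documented exemplar facts plus clearly marked `demo:` synthetic
entries, and a seeded generator produces ward-like synthetic patients,
so everything is testable offline.

## Worked example

```python
from medscreen import score_dbi
from medscreen.demo import build_demo_kb, ALPRAZOLAM, DEMO_SEDANOL
# ... two once-daily oral orders: alprazolam 0.5 mg, sedanol 10 mg
```

Running `python examples/02_drug_burden.py` prints:

```
Alprazolam                          D=0.5 mg, delta=0.5 mg -> term 0.500
Sedanol (demo sedative)             D=10 mg, delta=10 mg -> term 0.500
total drug burden: 1.000
```

Both drugs sit exactly at their minimum effective daily dose, so each
contributes 0.5 and the total of 1.0 reaches the alerting cut-off: a
full evaluation (`examples/04_alerts_and_suppression.py`) turns this
into one blue risk-minimization alert naming both drugs, which a single
"ignore" then suppresses on re-evaluation.

The other examples cover regimen complexity
(`01_regimen_complexity.py`), trigger screening
(`03_trigger_screening.py`), KB serialisation dialects and SPARQL
(`05_kb_dialects_and_sparql.py`), and a synthetic ward with an alert
summary table (`06_synthetic_ward.py`).

A thin CLI wraps the same library:

```bash
medscreen demo-kb --out kb.json
medscreen evaluate case.json --kb kb.json --registry registry.json
medscreen kb-convert --kb kb.json --out kb.ttl --out-dialect turtle
```

## Layout

- `src/medscreen/kb.py` — knowledge-base types, dialects, SPARQL, mapping
- `src/medscreen/patient.py` — request model, validation, parsing
- `src/medscreen/mrci.py`, `dbi.py`, `triggers.py` — the three scores
- `src/medscreen/alerts.py` — alerting rules, suppression, summaries
- `src/medscreen/api.py`, `cli.py` — JSON facade and command line
- `src/medscreen/demo.py` — demo KB and synthetic patient generator
- `src/medscreen/schemas/` — JSON-schema files for KB, request, response
- `docs/methods.md` — model descriptions, parameter choices, limitations
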