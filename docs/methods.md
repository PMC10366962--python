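# Methods

## Scope and model

`medscreen` evaluates one patient at a time: demographics, active
medication orders and timestamped laboratory results against a
knowledge base (KB) of appropriateness facts. Three measures drive the
alerting rules.

### Regimen complexity (MRCI)

The index is the sum of three sections. Section A sums the weights of
the *distinct* dosage-form/route combinations present in the regimen —
repeating a form the patient already manages adds no complexity, so
three oral tablets contribute the oral-tablet weight (1) once. Section
B sums a frequency weight per order; once-daily scheduled dosing is the
baseline weight 1, and each frequency concept carries separate weights
for scheduled and "as needed" use. Frequency qualifiers that the
original instrument scores as extra instructions (specific times,
relation to meals, less-often-than-daily schedules) are folded into the
frequency concept's B weight, so no separate frequency-derived C term
exists. Section C sums a per-product instruction weight; products
without an entry contribute 0, because instruction weights are defined
only for a subset of products. A missing A or B weight, by contrast, is
a knowledge gap — every prescribable order has a form and a frequency —
and is either raised or, inside a full evaluation, recorded in the
trace with the order skipped for that section.

PRN orders are removed before any counting (including section A's
distinct-form set) unless `include_prn=True`. The exclusion-first
reading is the stricter of the two possible conventions when a PRN
order shares a form with a scheduled one; the scheduled order still
carries the form, so totals differ only for forms used exclusively PRN.

### Drug burden (DBI)

DBI = Σ D/(δ+D) over every non-PRN order whose (ingredient, route,
age) matches a burden-list entry. D is dose × administrations-per-day ×
unit-conversion factor; δ is the entry's minimum effective daily dose.
Each term lies in [0, 1), equals 0.5 exactly at D = δ, increases in D
and decreases in δ. Entries whose base period is not 24 h have D
rescaled to that period before the formula. Matching requires the
route to be listed explicitly for the ingredient; an ingredient
prescribed by an unlisted route contributes nothing and is logged,
since burden lists enumerate routes deliberately. When overlapping
entries match, the narrowest age range wins and ties go to the lowest
δ — the conservative choice, as it yields the larger exposure term.
Unit conversion uses an explicit (from, to, factor) table with identity
implied; a missing pair is an error, never a silent factor of 1.

### Laboratory triggers

A trigger entry is (ingredient, route-or-wildcard, age range, lab
test, unit, [low, high]). For each non-PRN order and matching entry,
the *most recent* value of the test is compared with the range; a hit
fires only strictly outside it — boundary values are in range, so
"potassium < 2.9" fires below 2.9 and not at it. Ties on the lab
timestamp resolve by document order, last wins. Lab units are compared
by normalized string equality (trim, case-fold, µ→mc); no lab unit
conversion is attempted, and a mismatch yields no hit plus a trace
record. Dose never affects trigger output. At most one hit per entry
is emitted per evaluation, however many orders share the ingredient.

### Alerting rules

Patients below the minimum age (65 by default; the age gate is
inclusive, matching the 65–999 age ranges knowledge entries use) are
scored but never alerted. For eligible patients: one
regimen-complexity alert iff MRCI total ≥ 40, a global-drug
intervention displayed as "Review total treatment"; one aggregated
drug-burden alert iff DBI total ≥ 1, listing every contributing drug
(the DBI is a regimen-level measure, so one alert carries all drugs
rather than one alert per drug); one alert per trigger hit naming the
drug. Both thresholds are inclusive and live in the KB, not in code.
Alert levels map to display colors (contraindicated→red,
moderate→orange, low→yellow, risk minimization→blue); the packaged
templates use risk minimization for the two score alerts and low for
trigger alerts, and templates are editable data.

Alert identifiers are a SHA-256 hash (truncated) of use case, template
and sorted target concepts, so the same clinical situation always
produces the same id. Suppression is the ignore-once rule: an
(patient, alert) pair a clinician ignored is moved to the suppressed
list on every later evaluation; accepted alerts are only logged and
reappear while their condition persists. The registry is a JSON file
whose lifetime is the operator's choice; nothing else about evaluation
is stateful. Every emitted or suppressed alert and every knowledge gap
appears in the ordered trace of the result.

## Knowledge base

The typed model (pydantic) is the source of truth; RDF/Turtle, JSON
and CSV-directory serialisations are interchangeable dialects of it,
and `save → load` is the identity on structural content for each.
SPARQL queries run against an rdflib materialisation of the same
content (concept nodes carry their id and label; numeric literals are
`xsd:double`, which round-trips floats exactly). OWL reasoning is out
of scope. Referential integrity — template references resolve, one
weight per concept, consistent concept labels, unique local mappings
into known concepts — is checked at load time and on demand. Local
(code, vocabulary) pairs map to canonical concepts; an unmapped code
raises a dedicated error, or inside an evaluation is recorded in the
trace with the affected order dropped, so one mapping gap cannot void
a whole screening.

## Demo KB and synthetic data

The demo KB carries the documented exemplar facts — oral tablet A
weight 1; once-daily B weight 1; alprazolam, oral, ages 65–999,
δ = 0.5 mg per 24 h; parenteral furosemide with serum glucose 0–110
mg/dL; the loop-diuretic potassium rule with low bound 2.9 mEq/L — plus
synthetic entries whose concept ids carry a `demo:` prefix and whose
drug names are invented, so no invented weight can read as clinically
validated. Two demo choices deserve note: the potassium rule needs a
high bound, set at 5.0 mEq/L (a routine upper reference limit), and
the omeprazole product's instruction weight of 1 is a demo value for a
take-before-food instruction.

The generator emulates a polypharmacy internal-medicine ward: ages
66–95, 8–20 concurrent orders per patient, 15% PRN, 30% of orders from
the burden list (dosed at 0.5×, 1× or 2× δ, a quarter of them
prescribed in micrograms to exercise unit conversion), 20% trigger
drugs with an accompanying lab value abnormal 30% of the time, the
rest burden-free. Trigger-branch drugs are drawn only from ingredients
not on the burden list, so burden exposure comes solely from the
burden fraction and `fraction_dbi_drugs=0` guarantees a zero DBI. All
randomness flows from one integer seed through one `random.Random`.
What passing on this population shows is that the engine's arithmetic,
matching and alerting rules are correct; it says nothing about the
clinical coverage of a production KB (the full complexity, burden and
trigger source tables are licensed external publications and are not
shipped), nor about real prescribing patterns, missing data, or local
vocabulary drift, all of which are tamer here than in an EHR.

## Numerical and interface choices

Scores are IEEE doubles; section sums are plain left-to-right
additions over at most tens of orders, so the `total = A + B + C`
invariant holds to well below 1e-9. Threshold comparisons are `>=` on
the computed double — the acceptance tests construct regimens that hit
40 and 1.0 exactly in binary floating point. Timestamps must be
timezone-aware ISO-8601; naive timestamps are rejected at validation.
JSON request validation reports JSON-pointer locations. The facade
(`handle_request`) never raises on user input: malformed documents
yield an `invalid_request` response, and partial knowledge yields a
completed evaluation whose trace documents what was skipped.

Problem sizes in the shipped tests and acceptance checks — 500
synthetic regimens for oracle equivalence, 1000 random pairs for the
burden-formula property, cohorts of tens for the summary examples —
are the package's chosen verification scale; each check runs in
seconds and the arithmetic involved does not change with scale.

## Known limitations

- Scores quantify regimens; they do not judge indications, and the
  engine has no notion of diagnoses, renal function or interactions.
- Complexity instructions for taking multiple units at once or
  crushing tablets are not modelled; non-laboratory trigger categories
  (antidotes, care-module events, drug concentrations) are not either.
- No anticholinergic/sedative sub-scores: the alert uses the total.
- Lab values are never unit-converted; a mismatched unit is treated as
  missing evidence, visibly, rather than guessed at.
- Suppression is keyed by deterministic alert id; a change in the KB
  template or the contributing drug set produces a new id and the
  alert reappears, which is intended behaviour.
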