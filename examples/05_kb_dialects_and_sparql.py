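"""Serialise the knowledge base and query it with SPARQL.

The same typed KB round-trips through RDF/Turtle, a JSON document and a
directory of CSV tables; the Turtle graph is also directly queryable.
"""

import tempfile
from pathlib import Path

from medscreen import load_kb, query_kb, save_kb
from medscreen.demo import build_demo_kb

kb = build_demo_kb()
tmp = Path(tempfile.mkdtemp())

for dialect, name in [("turtle", "kb.ttl"), ("json", "kb.json"), ("csv-dir", "kb_tables")]:
    save_kb(kb, tmp / name, dialect)
    reloaded = load_kb(tmp / name, dialect)
    print(f"{dialect:8s} round-trip structurally equal: {reloaded.canonical() == kb.canonical()}")

rows = query_kb(kb, """
    PREFIX ms: <https://medscreen.example/kb#>
    PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
    SELECT ?drug ?delta WHERE {
      ?e a ms:DBIEntry ; ms:ingredient ?i ; ms:minEffectiveDailyDose ?delta .
      ?i rdfs:label ?drug .
    } ORDER BY ?drug""")
print("burden-listed drugs and their minimum effective daily doses (mg):")
for r in rows:
    print(f"  {r['drug']:35s} delta = {r['delta']}")
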