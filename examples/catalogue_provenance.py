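"""Inspect the criteria catalogue and its modification provenance.

The 80 UK criteria descend from 105 original French propositions; the
provenance ledger records each proposition's fate.  This prints the count
arithmetic (which validation requires to close exactly) and shows one
amended and one omitted proposition in full.
"""

from popiuk import load_catalog, provenance_summary

catalog = load_catalog()
s = provenance_summary(catalog)

print(f"criteria: {s['n_criteria']}   original propositions: {s['n_original']}")
print(f"unchanged {s['unchanged']} + amended {s['amended']} + combined {s['combined']} "
      f"(-> {s['combined_resulting_criteria']}) + omitted {s['omitted']} = "
      f"{s['unchanged'] + s['amended'] + s['combined'] + s['omitted']}")
print("omitted reasons:", s["omitted_reasons"])

amended = next(p for p in catalog.provenance if p.status == "amended")
print(f"\nexample amended proposition ({amended.original_id}, {amended.category}):")
print(f"  original: {amended.original_text}")
print(f"  became {amended.modified_ids[0]}: "
      f"{catalog.criterion(amended.modified_ids[0]).text}")
print(f"  guidance: {', '.join(amended.guideline_refs)}")

omitted = next(p for p in catalog.provenance if p.reason == "conflicting_uk_guideline")
print(f"\nexample omitted proposition ({omitted.original_id}, {omitted.category}):")
print(f"  {omitted.original_text}")
print(f"  conflicting guidance: {', '.join(omitted.guideline_refs)}")
# The checksum printed below is recomputed from content on every load, so a
# tampered catalogue file refuses to load.
print(f"\ncatalogue v{catalog.version}, checksum {catalog.checksum[:16]}…")
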