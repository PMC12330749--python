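"""Parse a BEL statement, print its canonical form, validate against an allow-list.

The statement says: the kinase activity of AKT1 directly increases the
amount of HSF1 phosphorylated at Ser 326.
"""

from beltograph import NamespaceId, parse_bel, serialize_bel, validate_statement

stmt = parse_bel(
    'act(p(HGNC:AKT1), ma(GO:"kinase activity")) directlyIncreases '
    "p(HGNC:HSF1, pmod(Ph, Ser, 326))"
)
print("relation:   ", stmt.relation)
print("subject:    ", stmt.subject.to_bel())
print("object:     ", stmt.object.to_bel())
print("canonical:  ", serialize_bel(stmt))

allowed = {
    NamespaceId("HGNC", "AKT1"),
    NamespaceId("HGNC", "HSF1"),
    NamespaceId("GO", "kinase activity"),
}
print("violations: ", validate_statement(stmt, allowed) or "none")

# an entity outside the allow-list is flagged, not dropped
bad = parse_bel("p(HGNC:FAKE1) increases p(HGNC:HSF1)")
for v in validate_statement(bad, allowed):
    print("flagged:    ", v.to_dict())
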