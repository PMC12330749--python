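"""Component-comparison scoring between two statement sets.

Each matching component earns its weight (subject 0.3, relation 0.4,
object 0.3): identical statements score 1.0, relation-only agreement
scores 0.4, fully disjoint statements score 0.0.
"""

from beltograph import aggregate_agreement, compare_statements, parse_bel
from beltograph.synthetic import make_agreement_corpus

a = parse_bel("p(HGNC:AKT1) increases p(HGNC:HSF1)")
b = parse_bel("p(HGNC:TP53) increases p(HGNC:MDM2)")
c = parse_bel("p(HGNC:TP53) decreases p(HGNC:MDM2)")

print("identical:      ", compare_statements(a, a).total_score)
print("relation only:  ", compare_statements(a, b).total_score)
print("nothing shared: ", compare_statements(a, c).total_score)

# aggregate agreement over a synthetic corpus engineered to known counts
pairs = [compare_statements(x, y) for x, y in make_agreement_corpus(29, 6, 11, 8)]
report = aggregate_agreement(pairs)
print(f"\n{report.n_pairs} pairs:")
for comp in ("subject", "relation", "object"):
    count = getattr(report, f"{comp}_matches")
    print(f"  {comp:8s} agreement: {count:2d}/{report.n_pairs} = {report.percent(comp)}%")
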