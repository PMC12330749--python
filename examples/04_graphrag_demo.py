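"""GraphRAG demonstration: seven variations of one question.

Two toy knowledge graphs (DNA-damage-themed and metabolism-themed,
sharing NAD and SIRT1 bridge nodes) are queried individually and merged,
each with and without permission to use the model's internal knowledge,
plus a no-graph baseline.  A scripted backend stands in for the LLM, so
the printed transcript shows the retrieval machinery, not live answers.
"""

from beltograph.graphrag import run_demo
from beltograph.llm import ScriptedBackend
from beltograph.synthetic import make_dna_damage_graph, make_metabolism_graph

entries = run_demo(
    (make_dna_damage_graph(), make_metabolism_graph()),
    "How does metabolism affect DNA damage response?",
    ScriptedBackend(default="(model answer would appear here)"),
    seeds=("NAD", "SIRT1", "TP53"),
)

for e in entries:
    n_statements = e.prompt.count('"interaction"')
    print(f"{e.variation:28s} graph statements in context: {n_statements}")
print(f"\n{len(entries)} variations; the merged cases carry the union of both graphs,")
print("so bridge-node relationships appear that neither graph shows alone.")
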