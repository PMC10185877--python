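"""Disease semantic similarity on a toy ontology.

Builds a four-term diamond DAG, computes each disease's semantic-value
profile under the information-content scheme, and prints the pairwise
similarity matrix.
"""

import tlsea as T

# R is a root category; A and B are sibling diseases; C descends from both.
onto = T.load_ontology([("R", "A"), ("R", "B"), ("A", "C"), ("B", "C")])
universe = ["A", "B", "C"]

stats = T.term_stats(onto, universe)
for term in sorted(stats.dag_counts):
    print(f"term {term}: appears in {stats.dag_counts[term]} of "
          f"{stats.total_diseases} disease DAGs, P(t) = {stats.p(term):.3f}")

matrix = T.dss_matrix(onto, universe, scheme="IDSSIM", delta=0.5)
print("\nsemantic similarity (IDSSIM):")
print(matrix.to_frame().round(3))

# A and B share only the root, so their similarity is low; C shares its
# whole ancestry with each parent disease, so DSS(A,C) and DSS(B,C) are high.
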