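"""Hierarchical EC label sets and the overlap-coefficient similarity.

Builds the prefix sets of two transferase EC numbers and prints their
overlap coefficient — the quantity the contrastive loss trains pairwise
cosine similarities to match.
"""

from ecknn import hierarchical_set, overlap_coefficient, parse_ec, protein_label_set

a = parse_ec("2.3.2.27")  # RING-type E3 ubiquitin transferase
b = parse_ec("2.3.2.31")  # a sibling transferase, same first three levels

print("set(2.3.2.27) =", sorted(hierarchical_set(a)))
print("set(2.3.2.31) =", sorted(hierarchical_set(b)))

y = overlap_coefficient(protein_label_set([a]), protein_label_set([b]))
print(f"overlap coefficient = {y}")
# 0.75: three of the four hierarchy levels agree, so a trained model
# should place these proteins at cosine similarity ~0.75.
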