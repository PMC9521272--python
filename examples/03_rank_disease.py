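"""Rank candidate circRNAs for one disease.

After fitting on all known associations, the per-disease ranking lists
circRNAs by descending ensemble score.  Known partners are flagged; the
interesting candidates are high-ranked circRNAs not yet linked to the
disease.
"""

from cda_netfuse import HyperParams, generate, predict_scores, rank_for_disease, small_preset

Y, sem, held_out = generate(small_preset(seed=17))
scores = predict_scores(Y, sem, HyperParams(), model="ensemble")

disease = Y.disease_ids[0]
print(f"top 10 circRNAs for {disease} (known partners flagged):")
for r, (circ, score, known) in enumerate(rank_for_disease(scores, Y, disease, top=10), 1):
    tag = "known" if known else ("held-out link!" if (circ, disease) in held_out else "")
    print(f"  {r:2d}. {circ}  {score:.4f}  {tag}")
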