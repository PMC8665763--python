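"""Read the three input resources and align them into one consistent dataset.

Builds a tiny PPI network, DTI table and feature tables in the standard TSV
dialects, then shows the confidence filtering and entity-intersection rules.
"""

import io

from graphdti import align_entities, read_dti_table, read_feature_table, read_interaction_network

ppi = io.StringIO(
    "protein1\tprotein2\tcombined_score\n"
    "9606.P1\t9606.P2\t900\n"   # high confidence: kept
    "9606.P2\t9606.P3\t710\n"   # kept at the 700 threshold
    "9606.P3\t9606.P4\t350\n"   # low confidence: dropped
)
dti = io.StringIO(
    "chemical\tprotein\tcombined_score\n"
    "CID1\t9606.P1\t820\n"
    "CID1\t9606.P3\t900\n"
    "CID2\t9606.P2\t400\n"      # below threshold: dropped
)
prot_feat = io.StringIO(
    "9606.P1\t0.1\t0.2\n9606.P2\t0.0\t1.0\n9606.P3\t0.5\t0.5\n"
)
drug_feat = io.StringIO("CID1\t1.0\t0.0\t2.0\nCID2\t0.0\t1.0\t0.0\n")

graph = read_interaction_network(ppi, score_threshold=700)
interactions = read_dti_table(dti, score_threshold=700)
pf = read_feature_table(prot_feat)
df = read_feature_table(drug_feat)

graph, interactions, pf, df, index = align_entities(graph, interactions, pf, df)

print(f"proteins retained : {index.n_proteins} ({', '.join(index.protein_ids)})")
print(f"drugs retained    : {index.n_drugs} ({', '.join(index.drug_ids)})")
print(f"PPI edges >= 700  : {graph.n_edges}")
print(f"DTI positives     : {sorted(interactions.positives)}")
# P4 survives through its (sub-threshold-free) edges? No - its only edge was
# dropped at 350 and it has no feature row, so it is gone; CID2 keeps its
# feature row and stays in the drug universe even with zero interactions.
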