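"""Full pipeline on a synthetic paired panel with planted co-expression.

Generates an 11-subject, 120-miRNA paired dataset in which three 6-miRNA
modules are coupled through a shared latent factor and shifted by 2 log2
units after exposure in responder subjects, then runs: missingness filter →
feature-mean imputation → paired differential expression → all-pairs
combined z scan → FDR selection → hub graph, and scores the selection
against the planted truth.
"""

from coexpair import (
    ModuleSpec,
    SyntheticConfig,
    build_graph,
    default_modules,
    evaluate_recovery,
    filter_missing,
    generate_paired,
    hub_report,
    impute_feature_mean,
    pair_scan,
    select_pairs,
)

modules = tuple(
    ModuleSpec(members=m.members, loading=1.0, factor_sd=1.0, shift=2.0)
    for m in default_modules(120)
)
cfg = SyntheticConfig(seed=1, modules=modules, responder_fraction=0.8)
matrix, meta, truth = generate_paired(cfg)
print(f"simulated {matrix.n_features} miRNAs x {matrix.n_samples} samples "
      f"({cfg.n_subjects} subjects x 2 timepoints), "
      f"{matrix.missing_mask.mean():.1%} cells missing")
print(f"planted: {len(truth.coupled_pairs)} coupled pairs in 3 modules, "
      f"{len(truth.responders)} responder subjects")

filtered = filter_missing(matrix)       # drop miRNAs missing in > 12/22 samples
complete = impute_feature_mean(filtered)
scan = pair_scan(complete, meta)        # C(m, 2) combined z-scores
selected = select_pairs(scan)           # FDR < 0.01 and min p_DE < 0.05
print(f"scanned {len(scan)} pairs, selected {len(selected)}")

metrics = evaluate_recovery(truth, selected)
print(f"power on planted shifted pairs: {metrics.power:.2f}; "
      f"false discovery proportion: {metrics.fdp:.2f}")
print("(power counts planted same-module pairs recovered; the FDP here "
      "counts cross-module pairs of shifted miRNAs, which genuinely move "
      "together through the shared exposure response even though no latent "
      "factor couples them)")

if selected:
    print()
    print(hub_report(build_graph(selected)).summary())
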