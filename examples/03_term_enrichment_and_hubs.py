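"""Term enrichment (EASE) and interaction-degree hub analysis.

A planted annotation term is overrepresented among the hyperphosphorylated
proteins; one planted hub exceeds the degree-7 threshold in the edge list.
"""

from phosphodelta import enrich, simulate

config = simulate.SimulationConfig(seed=11)
experiment = simulate.gen_phospho_experiment(config)
fg = sorted(experiment.truth_hyper_proteins)
annotations, edges, truth = simulate.gen_annotation_and_edges(
    sorted(experiment.proteome), fg, config
)

rows = enrich.term_enrichment(fg, annotations, ease=True)
print("term          count  fold   EASE p      Benjamini")
for r in rows[:5]:
    print(f"{r.term_id:12s} {r.count:5d} {r.fold_enrichment:6.2f} "
          f"{r.p_value:.3e} {r.adjusted_p:.3e}")
print(f"planted term: {truth.planted_term} "
      f"(rank {[r.term_id for r in rows].index(truth.planted_term) + 1})")

score = enrich.cluster_score([r.p_value for r in rows[:3]])
print(f"enrichment score of the top-3 term group: {score:.2f} "
      f"(clusters above 1.5 count as enriched)")

hubs = [r for r in enrich.degree_analysis(edges, hub_threshold=7) if r.is_hub]
print(f"hubs (degree > 7): {[(h.node, h.degree) for h in hubs]} "
      f"(planted: {truth.hub_node})")
print()
print("The EASE p decrements the foreground hit count by one before the")
print("one-tailed Fisher tail, the conservative convention of DAVID-style")
print("annotation enrichment tools.")
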