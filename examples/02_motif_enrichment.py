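"""Phosphomotif enrichment: iterative extraction against a proteome background.

Builds 13-residue windows centred on the phosphosites of planted
hyperphosphorylated peptides (40% of serine sites carry a +1 proline by
construction) and extracts enriched motifs by greedy binomial selection.
"""

from phosphodelta import motifs, simulate

experiment = simulate.gen_phospho_experiment(simulate.SimulationConfig(seed=7))
sites = experiment.planted_sites()
windows = motifs.build_windows(sites, experiment.proteome)
background = motifs.windows_from_proteome(experiment.proteome, "ST")

comp = motifs.residue_composition(sites)
print(f"{len(sites)} phosphosites: "
      f"{100 * comp['S']:.1f}% pS, {100 * comp['T']:.1f}% pT")
print(f"+1 proline fraction: {100 * motifs.stp_fraction(windows):.1f}%")
print()
print("motif          matches  coverage%  fold   score")
for center in "ST":
    for m in motifs.motifx_extract(windows, background, center):
        print(f"{m.pattern():14s} {m.fg_matches:6d} "
              f"{100 * m.fg_matches / len(windows):9.2f} "
              f"{m.fold_increase:6.1f} {m.score:7.1f}")

w = windows[0]
print()
print(f"example window {w.window}: kinase consensus classes "
      f"{sorted(motifs.kinase_annotate(w).classes) or 'none'}")
print()
print("'fold' is the foreground/background match-rate ratio of the motif;")
print("'score' sums -log10 of the binomial tail at each selection step.")
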