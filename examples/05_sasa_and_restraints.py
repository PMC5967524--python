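"""Solvent accessibility and docking-restraint residue selection.

Computes Shrake-Rupley SASA on the toy receptor and selects the residues a
data-driven docking run would restrain: solvent accessible (main- or
side-chain relative accessibility >= 15%) and within 10 A of a seed patch
(here the catalytic residue, standing in for a known binding region).
"""

from phosphodelta import dockpost, simulate

config = simulate.SimulationConfig(seed=1, n_poses=1, fraction_near_site=1.0)
poses, truth = simulate.gen_poses(config)
receptor = poses[0].subset(poses[0].mask("A"))

result = dockpost.sasa(receptor, probe=1.4, n_points=960)
print("receptor per-residue SASA (first 5 residues):")
print(result.table.head(5).to_string(index=False,
      float_format=lambda v: f"{v:.1f}"))

selected = dockpost.restraint_selection(
    receptor, "A", seed_residues=[truth.catalytic_residue],
    radius=10.0, min_rel_sasa=0.15, sasa_result=result,
)
print(f"\nrestraint residues within 10 A of residue "
      f"{truth.catalytic_residue}: {selected}")
print()
print("Relative SASA divides the residue's area by a per-residue-type")
print("reference maximum; residues above 15% on either main or side chain")
print("count as solvent accessible and eligible as docking restraints.")
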