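"""Binding-site contacts, hydrogen bonds, and water bridges on a toy
complex.

Generates a small random protein/ligand/water system, lists the protein
residues within 3.5 A of the ligand, detects and classifies hydrogen
bonds (regular vs bifurcated), and looks for water molecules bridging
protein and ligand.
"""

import surfbind as sb

system, frame = sb.gen_toy_complex(
    sb.ToyComplexSpec(n_protein=40, n_ligand=8, n_water=12, box=16.0, seed=19)
)
cfg = sb.AnalysisConfig()

contacts = sb.binding_site_residues(frame, system, cfg.contact_cutoff)
print(f"binding-site residues within {cfg.contact_cutoff} A: {len(contacts)}")
for c in contacts:
    print(f"  {c.residue_name} {c.residue_index}  min dist "
          f"{c.min_distance:.2f} A (closest ligand atom {c.ligand_atom})")

bonds = sb.detect_hbonds(frame, system, cfg)
summary = sb.hbond_summary(bonds)
print(f"\nhydrogen bonds: {summary['n_total']} "
      f"({summary['n_bifurcated']} bifurcated hub(s), "
      f"{summary['n_regular']} regular)")
print("a bifurcated interaction counts as two bonds: totals(b=3, r=1) ->",
      sb.hbond_totals(3, 1))

bridges = sb.water_bridges(frame, system, cfg)
print(f"\nwater bridges (protein-water-ligand): {len(bridges)}")
for b in bridges:
    print(f"  protein atom {b.protein_atom} <- water {b.water_residue} "
          f"-> ligand atom {b.ligand_atom}")
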