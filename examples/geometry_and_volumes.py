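"""Chain shape classification and grid-based pocket volume overlap.

Characterises a synthetic chain (radius of gyration, enclosing sphere,
volume ratio, shape class) and compares the grid volumes of a predicted
pocket against the observed site on the shared 1 Å lattice.
"""
import pocketeval as pe

spec = pe.FixtureSpec(seed=11)
chain, sites, _ = pe.make_chain_with_sites(spec)

d = pe.characterise_chain(chain)
print(f"chain: {len(chain)} residues, Rg {d.rg:.1f} Å, "
      f"enclosing sphere R {d.sphere_radius:.1f} Å")
print(f"volume ratio {d.volume_ratio:.3f} -> {d.shape_class}")
# A long thin helix occupies a small fraction of its enclosing sphere, so
# the volume ratio falls at or below the 0.08 elongation threshold.

by_up = chain.by_uniprot()
site = sites[0]
site_atoms = [a for r in sorted(site.residues) for a in by_up[r].heavy_atoms()]
# clash removal against receptor atoms carves the cavity out of the grid;
# the two-atom-per-residue toy chain has no interior, so the volumes here
# are computed for the bare pocket envelopes to keep the numbers non-trivial
obs_volume = pe.pocket_volume([], site_atoms, centroid=site.centroid)

# a prediction covering the first half of the site's residues
pred_residues = sorted(site.residues)[: len(site.residues) // 2]
pred_atoms = [a for r in pred_residues for a in by_up[r].heavy_atoms()]
pred_volume = pe.pocket_volume([], pred_atoms)

rvo = pe.relative_volume_overlap(pred_volume, obs_volume)
rro, _ = pe.shape_overlap(frozenset(pred_residues), site.residues)
print(f"observed site volume {obs_volume.volume:.0f} Å³, "
      f"predicted {pred_volume.volume:.0f} Å³")
print(f"relative residue overlap {rro:.2f}, relative volume overlap {rvo:.2f}")
# RRO is the fraction of observed binding residues the prediction covers;
# RVO the fraction of the observed grid volume the predicted volume covers.
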