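"""Generate a synthetic chemical-genetic screen with planted signal.

Builds a modular genetic interaction network (queries in a module share a
latent per-strain signature), module-level gene-set annotations, and a
screen in which 50 "active" compounds are noisy copies of query profiles
while inactive compounds and solvent controls are pure noise.
"""

from chemgen import synthetic

gi, ann = synthetic.generate_genetic_network(seed=1)
cg, truth = synthetic.generate_screen(gi, ann, seed=2)

print(f"genetic network: {gi.scores.shape[0]} strains x "
      f"{gi.scores.shape[1]} query genes")
print(f"annotations: {len(ann.term_ids)} terms, sizes "
      f"{sorted(ann.term_sizes.tolist())}")
print(f"screen: {cg.n_conditions('treatment')} treatments "
      f"({int(truth.table['active'].sum())} active) and "
      f"{cg.n_conditions('control')} solvent controls")
print(truth.table.head(3).to_string(index=False))
# Each active row names the query profile the compound copies and the
# module term it should therefore be predicted to perturb.
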