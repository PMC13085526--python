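"""Generate a synthetic split-root experiment and inspect its design.

Shoots are sampled under three nitrogen conditions (C.NO3, Split, C.Cl) and
roots under four (C.NO3, Sp.NO3, Sp.Cl, C.Cl) at 0/2/4/8 h with three
replicates; genes belong to planted regulation classes with known condition
effects, which is the ground truth every later stage is scored against.
"""

from collections import Counter

from splitroot import SimulationConfig, generate_splitroot_experiment

config = SimulationConfig(n_genes=500, n_planted_pairs=25, seed=1)
shoot, root, truth = generate_splitroot_experiment(config)

print(f"shoot matrix: {shoot.n_genes} genes x {shoot.n_samples} samples "
      f"({shoot.conditions()} x {shoot.time_points()} h x 3 replicates)")
print(f"root matrix:  {root.n_genes} genes x {root.n_samples} samples "
      f"({root.conditions()})")
print("planted classes:", dict(Counter(truth.gene_class.values())))
print(f"planted inter-organ pairs: {len(truth.planted_pairs)} "
      f"(first: {truth.planted_pairs[0]})")
print(f"mobile transcripts: {len(truth.mobile_set)}")
# The two root halves of one split plant share a plant pool with one Split
# shoot replicate; that linkage is what inter-organ correlation exploits.
pools = root.samples.loc[root.samples.condition == "Sp.NO3", "plant_pool_id"]
print("example plant pool ids:", sorted(pools)[:3])
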