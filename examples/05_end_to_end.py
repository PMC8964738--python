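"""Full pipeline on a synthetic benchmark with known planted drivers.

Simulates every input (screens, knowledge graph, corpus, cohort, RNA-seq),
assembles the hybrid feature table, ranks it under the shipped default
preference, and checks that the planted resistance genes reach Pareto
level 1.
"""

from paretohits import default_preference, rank
from paretohits.synthetic import SyntheticSpec, assemble_feature_table, simulate_all

spec = SyntheticSpec(n_genes=200, n_planted=4, seed=42)
data = simulate_all(spec)

ft = assemble_feature_table(
    data["screens"], data["graph"], data["corpus"], data["cohort"],
    rnaseq=data["rnaseq"], tractability=data["tractability"],
    essentiality=data["essentiality"], seed=42,
)
print(f"feature table: {len(ft)} genes x {len(ft.features)} features")

out = rank(ft, default_preference())
lvl1 = out.level(1)
planted = set(spec.planted_genes)
print(f"Pareto level 1: {len(lvl1)} genes")
print("planted drivers recovered at level 1:",
      sorted(planted & set(lvl1)), "of", sorted(planted))
# The planted genes carry consistent screen hits, elevated anchor
# co-mentions, positive clinical enrichment, and strong RNA-seq signal,
# so no other gene can dominate them on every objective at once.
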