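"""Generate one complete synthetic study and write its input files.

The generator produces everything the downstream analyses consume: a 48-tip
ultrametric isolate tree with an outgroup, an orthogroup-by-genome
copy-number matrix with 20 planted trait-associated orthogroups, replicate
qPCR abundances, COG annotations with one enriched category, plant
phenotypes, and a tree-derived ANI matrix.
"""

import pangls as pg

config = pg.SimConfig(seed=1)
study = pg.simulate_study(config)
paths = pg.write_study(study, "scratch/example_study")

print(f"tree tips:          {study['tree'].n_tips} (incl. outgroup)")
print(f"copy-number matrix: {study['matrix'].shape[0]} orthogroups x "
      f"{study['matrix'].shape[1]} genomes")
print(f"planted orthogroups: {len(study['planted'])} "
      f"(true slope {config.beta_true})")
print(f"qPCR rows:          {study['qpcr'].shape[0]} "
      f"({config.n_replicates} replicates x 2 conditions per isolate)")
print("files written:", ", ".join(p.name for p in paths.values()))

# The planted orthogroups are the ground truth the association screen should
# rediscover; everything else is independent of the trait by construction.
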