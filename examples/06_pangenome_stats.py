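"""Descriptive pangenome statistics: ANI levels, fluidity, rarefaction.

Pairs of genomes are binned by ANI (genus < 95%, species 95-99%, strain
> 99%); genome fluidity summarizes gene-content dissimilarity per pair; and
pan/core rarefaction curves are fit to Heaps' power law and an exponential
decay.  gamma < 1 in the Heaps fit marks an open pangenome.
"""

import pangls as pg

study = pg.simulate_study(pg.SimConfig(seed=6))
matrix, ani = study["matrix"], study["ani"]

summary = pg.pangenome_summary(matrix)
print(f"pan-genome {summary['pan_size']} orthogroups, "
      f"core {summary['core_size']}, {summary['n_genomes']} genomes")

pairs = pg.fluidity_by_level(matrix, ani)
print("\ngenome fluidity by ANI level (mean over pairs):")
print(pairs.groupby("level")["ratio"].agg(["mean", "count"]).round(3))

rare = pg.rarefy_pangenome(matrix, n_perm=100, seed=1)
heaps = pg.fit_heaps_law(rare.curves["N"], rare.curves["pan_mean"])
decay = pg.fit_core_decay(rare.curves["N"], rare.curves["core_mean"])
print(f"\nHeaps fit: pan(N) = {heaps['kappa']:.1f} * N^{heaps['gamma']:.3f}"
      f"  (gamma < 1: open pangenome)")
print(f"core fit:  core(N) = {decay['A']:.1f} * exp(-N/{decay['tau']:.2f})"
      f" + {decay['omega']:.1f}")
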