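"""Simulate a virus community and classify each taxon's temporal dynamics.

Builds a 5-year monthly abundance table with known annual / biannual /
erratic taxa, then runs the periodicity screen (exact and rank-robust
Fisher's g, harmonic likelihood-ratio test) and prints the confusion
between planted and recovered dynamics classes.
"""

import pandas as pd

from viralphenology.periodicity import periodicity_table
from viralphenology.synthetic import SimConfig, simulate_dataset

cfg = SimConfig(n_taxa=60, class_probs=(0.4, 0.2, 0.4), seed=11)
truth, table = simulate_dataset(cfg)
print(f"simulated {len(table.taxa)} taxa x {len(table.samples)} monthly samples "
      f"({cfg.n_years} years, ~{100 * cfg.miss_prob:.0f}% months unsampled)")

result, _ = periodicity_table(table, seed=11)
result["true_class"] = [truth.classes[t] for t in result["taxon_id"]]
print("\nplanted class (rows) vs recovered label (columns):")
print(pd.crosstab(result["true_class"], result["label"]))

seasonal = result[result["label"] != "nonseasonal"]
print(f"\n{len(seasonal)} taxa significant at p < 0.001 (rank-robust g test).")
print("Erratic taxa should land in 'nonseasonal': their spikes carry no",
      "stable 12- or 6-month cycle; annual/biannual taxa should be recovered.")
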