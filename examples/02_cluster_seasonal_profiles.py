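"""Cluster seasonal taxa by their z-scored monthly profiles.

Seasonal profiles (mean abundance per calendar month, z-scored) are
clustered with PAM k-medoids; the number of clusters is chosen by the
minimum Davies-Bouldin index.  Prints the DB curve, the chosen k, and each
cluster's peak month/season.
"""

from viralphenology.clustering import (
    MONTHS,
    peak_month,
    season_of_month,
    seasonal_profile,
    select_k,
)
from viralphenology.periodicity import normalize, periodicity_table, regularize
from viralphenology.synthetic import SimConfig, simulate_dataset

cfg = SimConfig(n_taxa=60, class_probs=(0.8, 0.1, 0.1), seed=23)
truth, table = simulate_dataset(cfg)

labels, series = periodicity_table(table, seed=23)
seasonal_taxa = labels.loc[labels["label"].isin(["annual", "biannual"]), "taxon_id"]

norm = normalize(table)
profiles = []
for i, taxon in enumerate(norm.taxa):
    if taxon not in set(seasonal_taxa):
        continue
    prof = seasonal_profile(series[taxon])
    if not prof.degenerate:
        profiles.append(prof)
print(f"{len(profiles)} seasonal taxa enter clustering")

sol = select_k(profiles, range(2, 9), seed=23)
print("Davies-Bouldin by k:",
      {k: round(v, 3) for k, v in sorted(sol.db_by_k.items())})
print(f"selected k = {sol.k} (minimum DB = {sol.db_index:.3f})")

prof_by_id = {p.taxon_id: p for p in profiles}
for c, medoid in sorted(sol.medoids.items()):
    size = sum(1 for v in sol.assignments.values() if v == c)
    pm = peak_month(prof_by_id[medoid])
    print(f"cluster {c}: {size} taxa, medoid {medoid}, "
          f"peaks in {MONTHS[pm]} ({season_of_month(pm)})")
print("Each cluster is a cohort of viruses peaking in the same season;",
      "the medoid is the exemplar profile.")
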