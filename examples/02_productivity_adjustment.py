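"""Correcting pollen counts for differential pollen productivity.

High pollen producers (tree taxa in particular) flood the rain and hide rare
types. Dividing each taxon's count by its pollen productivity estimate (PPE)
and resampling to 520 grains rebalances the assemblage before richness is
compared across sites.
"""

from pollendiv import (
    adjust_counts,
    partition_datasets,
    rarefy_dataset,
    report_mean_richness,
    resample_adjusted,
)
from pollendiv.synthetic_data import simulate_study

pollen, survey, ppe, truth = simulate_study("two-region", seed=1)
partition = partition_datasets(pollen)

raw = rarefy_dataset(pollen, depth=943, n_reps=100, rng_seed=1)
adjusted = adjust_counts(pollen, ppe)
adj = resample_adjusted(adjusted, depth=520, n_reps=100, rng_seed=1)

raw_means = report_mean_richness(raw.as_mapping(), partition)
adj_means = report_mean_richness(adj.as_mapping(), partition)

print(f"{len(adjusted.adjusted_taxa)} pollen types adjusted by a PPE, "
      f"{len(adjusted.unadjusted_taxa)} kept raw (no estimate available)")
print("mean richness per subset, raw@943 vs PPE-adjusted@520:")
for key in ("region_poor_forest", "region_poor_open",
            "region_rich_forest", "region_rich_open"):
    print(f"  {key:22s} {raw_means[key]:5.1f}  ->  {adj_means[key]:5.1f}")
print("The adjustment demotes the over-producing tree types, so the two")
print("depths are not directly comparable; what matters is the ranking of")
print("sites, which productivity correction can reshuffle.")
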