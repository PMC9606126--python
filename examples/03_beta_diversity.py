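"""Total-variance beta diversity (BD_Total) with local contributions (LCBD).

BD_Total is the total variance of the site-by-taxon presence/absence table,
computed from square-root-transformed Jaccard dissimilarities; LCBD_i is the
share of that variance contributed by site i, with permutation p-values
flagging sites of unusual composition.
"""

import numpy as np

from pollendiv import (
    beta_div_presence,
    lcbd_permutation_test,
    partition_datasets,
)
from pollendiv.synthetic_data import simulate_study

pollen, survey, ppe, truth = simulate_study("two-region", seed=1)
partition = partition_datasets(pollen)
presence = pollen.presence_matrix()
index = {s: i for i, s in enumerate(pollen.site_ids)}

print("pollen BD_Total per dataset (sqrt-Jaccard):")
for key, site_ids in partition.datasets.items():
    rows = [index[s] for s in site_ids]
    res = beta_div_presence(presence[rows])
    print(f"  {key:22s} n={res.n_sites:2d}  BD_Total={res.bd_total:.3f}")

sites = partition["region_rich_complete"]
rows = [index[s] for s in sites]
res = beta_div_presence(presence[rows])
pvals = lcbd_permutation_test(presence[rows], n_perm=199, rng_seed=1)
top = np.argsort(-res.lcbd)[:3]
print("three largest local contributions in the rich complete dataset:")
for i in top:
    print(f"  {sites[i]:6s} LCBD={res.lcbd[i]:.4f} p={pvals[i]:.3f}")
print("Complete datasets mix compositionally distinct forest and open")
print("communities, so their BD_Total exceeds that of either subset.")
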