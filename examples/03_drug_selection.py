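"""Picking a diverse, informative drug subset from a response screen.

Builds a fixture screen of 60 drugs × 60 cell lines (some with too much
missingness or near-constant response), applies the missing/distinct filter,
standardizes each drug by mean / mean absolute deviation, clusters the
profiles with CLARA k-medoids, and reports the medoids of the largest
clusters as the representative subset.
"""

import numpy as np

import pgxlearn as pg

rng = np.random.default_rng(0)
n_drugs = 60
missing = rng.integers(0, 9, size=n_drugs)  # some drugs exceed the 5-missing cap
distinct = rng.integers(20, 50, size=n_drugs)  # some fall below 29 distinct values
distinct = np.minimum(distinct, 60 - missing)
panel = pg.generate_response_fixture(n_drugs, 60, missing, distinct, seed=4)

kept = pg.filter_drugs(panel, max_missing=5, min_distinct=29)
print(f"filter: kept {len(kept.compounds)} of {n_drugs} drugs "
      "(<=5 missing and >=29 distinct values)")

standardized = pg.standardize_panel(kept)
result = pg.cluster_drugs_clara(standardized, k=8, n_subsamples=20,
                                subsample_size=len(kept.compounds), seed=0)
print("cluster sizes:", result.cluster_sizes)
print(f"total cost (sum of distances to medoids): {result.total_cost:.1f}")

representatives = pg.select_representatives(result, n_clusters=4)
print("representatives (medoids of the 4 largest clusters):", representatives)
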