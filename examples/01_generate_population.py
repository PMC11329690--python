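"""Generate a synthetic survey population and inspect its structure.

Draws 800 persons from the default five-cluster population (cluster shares
16/38/18/24/4 %), then prints the realized cluster shares, the weighted
mean daily energy intake and the survey-weight range.  The ground-truth
cluster labels exist only because the data is synthetic — they are what
the downstream clustering is benchmarked against.
"""

import numpy as np

import dietshift as ds

spec = ds.default_spec(n_persons=800, seed=42)
intakes, nutrients, persons, truth = ds.generate_population(spec)

print(f"persons: {len(intakes)}, foods: {intakes.shape[1]}, "
      f"nutrients: {nutrients.shape[1]}")
shares = truth.value_counts(normalize=True).sort_index()
print("planted cluster shares :", np.round(spec.cluster_proportions, 3))
print("realized cluster shares:", shares.round(3).to_list())

w = persons["survey_weight"].to_numpy()
energy = nutrients["energy_kj"].to_numpy()
print(f"weighted mean energy: {np.sum(w * energy) / w.sum():.0f} kJ/day")
print(f"survey weights: min {w.min():.2f}, max {w.max():.2f}, mean {w.mean():.2f}")
# Younger men respond less in the propensity model, so they carry the
# largest weights; weights are normalized to mean 1.
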