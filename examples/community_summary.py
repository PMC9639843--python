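"""Community-level indices: weighted heterogeneity, diversity, and the p-delta trend.

delta_c is the frequency-weighted mean of the per-species heterogeneity
indices (a convex combination, so it lies between the smallest and largest
delta); H' is the Shannon-Wiener index on frequencies normalized to one;
the power-form fit summarizes how heterogeneity rises with occurrence
frequency.
"""

from quadlaw import (
    community_heterogeneity,
    frequency_heterogeneity_fit,
    shannon_diversity,
)
from quadlaw.datasets import lvhua_macroalgae

table = lvhua_macroalgae()

delta_c = community_heterogeneity(table.p, table.delta)
h = shannon_diversity(table.p)
trend = frequency_heterogeneity_fit(table.p, table.delta, form="power")

print(f"community heterogeneity delta_c = {delta_c:.4f}  (> 0: aggregated overall)")
print(f"Shannon-Wiener H' = {h:.4f}  over {len(table)} species")
print(
    f"trend: delta = {trend.a:.4f} * p^{trend.b:.4f}   "
    f"R2(log-log) = {trend.r_squared:.4f}"
)
above = [
    sp for sp, d in zip(table.species, table.delta) if d > delta_c
]
print(f"species above delta_c (drive community heterogeneity): {above}")
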