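"""Multiscale associations with spin-test nulls.

Builds receptor composite maps (entropy, E/I ratio, ionotropic/metabotropic
density), correlates a variability map against them with Hungarian spin tests
(spatial-autocorrelation-preserving nulls), summarizes the correlation profile
with a participation coefficient over scale communities, and decomposes the
variance of the variability map over the composites with dominance analysis.
"""

import numpy as np

from boldvar import (
    class_density,
    dominance_analysis,
    ei_ratio,
    hungarian_spins,
    make_parcellation,
    metric_correlation_matrix,
    participation_coefficient,
    receptor_entropy,
)
from boldvar.synthetic import simulate_receptor_panel, simulate_regional_maps

parcellation = make_parcellation(n_regions=100, seed=0)
panel = simulate_receptor_panel(parcellation, seed=1)

composites = {
    "entropy": receptor_entropy(panel),
    "ei-ratio": ei_ratio(panel),
    "ionotropic": class_density(panel, "ionotropic"),
    "metabotropic": class_density(panel, "metabotropic"),
}
# a smooth stand-in for an empirical variability map, plus two smooth
# reference maps standing in for other-scale annotations
variability, ref_a, ref_b = simulate_regional_maps(parcellation, 0.5, 3, seed=2)
variability.label = "variability"

nulls = hungarian_spins(parcellation, n_spins=1000, seed=3)
maps = [variability] + list(composites.values()) + [ref_a, ref_b]
corr, pvals = metric_correlation_matrix(maps, nulls=nulls, variability_indices=(0,))
print("correlations with the variability map (spin p in parentheses):")
for name, m in composites.items():
    print(f"  {name:13s} r = {corr.loc['variability', m.label]:+.3f} "
          f"(p = {pvals.loc['variability', m.label]:.3f})")

# how evenly the variability map's associations spread over scale communities
communities = ["variability"] + ["receptor"] * 4 + ["reference"] * 2
pc = participation_coefficient(corr.to_numpy(), communities)
print(f"participation coefficient of the variability map: {pc[0]:.3f}")

predictors = np.column_stack([m.values for m in composites.values()])
dom = dominance_analysis(predictors, variability)
dom["predictor"] = list(composites)
print("dominance analysis (share of full-model R**2 = "
      f"{dom['full_r2'].iloc[0]:.3f}):")
for _, row in dom.iterrows():
    print(f"  {row['predictor']:13s} {row['percentage']:5.1f}%")
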