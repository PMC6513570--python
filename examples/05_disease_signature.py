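"""Fit the PLS-DA morphological disease signature and rank VIP scores.

Assembles the eight per-individual features (% simple/complex/small/large,
median MCI and volume, volume density, nanotunnels per 100), fits a
2-component PLS-DA against group labels, and ranks features by variable
importance in projection. On cohorts where disease differs only in the
simple-mitochondria fraction and the nanotunnel rate, those two features
should top the VIP ranking.
"""

from mitomorph3d import assemble_features, plsda_fit, predict_group, vip_scores
from mitomorph3d.synthetic import CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(seed=3))
features = assemble_features(cohort.summaries)
model = plsda_fit(features, n_components=2)

total = 100 * model.explained_x_variance.sum()
print(f"2-component PLS-DA explains {total:.0f}% of feature variance\n")
print(vip_scores(model).round(3).to_string(index=False))
print("\n(VIP > 1 marks features contributing more than average to the")
print(" group separation; mean squared VIP is 1 by construction)\n")

calls = predict_group(model, features)
accuracy = (calls.predicted_group.values == features.groups.values).mean()
print(f"nearest-centroid resubstitution accuracy: {accuracy:.0%}")
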