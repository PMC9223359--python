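"""Derive objective indicator weights from a synthetic monitoring panel.

The entropy weight method gives more weight to indicators whose scores
vary more across evaluation units (station-years): dispersed indicators
discriminate between units, uniform ones do not.
"""

import riverhealth as rh

registry = rh.default_registry()
scenario = rh.SyntheticScenario(seed=7)  # 3 stations x 2011-2014 x 16 indicators
observations = rh.generate_observations(scenario, registry)

matrix = rh.build_score_matrix(observations, registry)
weights = rh.entropy_weights(matrix, registry)

print(rh.weights_frame(weights, registry).round(3).to_string(index=False))
print(f"\nW_natural = {weights.w_natural:.3f}, W_social = {weights.w_social:.3f}")
# Weights sum to 1; the two subsystem sums are the integrated weights the
# composite evaluation index T blends the natural and social functions with.
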