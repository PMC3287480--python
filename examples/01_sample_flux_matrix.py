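"""Sample LAD-reconciled flux distributions for control and knockout conditions.

Builds the designed toy network, draws randomized measurement targets per
sample (truncated to one sigma around each reported mean), reconciles each
draw against steady state with the least-absolute-deviation LP, and prints
the resulting flux matrix and residuals.
"""

import numpy as np

from fmb import make_toy_model, sample_flux_matrix
from fmb.synthetic import ToyModelSpec

fixture = make_toy_model(ToyModelSpec())
matrix = sample_flux_matrix(fixture.model, fixture.constraints,
                            fixture.perturbation, n_per_condition=100,
                            master_seed=7)

residuals = np.array(matrix.provenance["residuals"])
print(f"flux matrix: {matrix.n_reactions} reactions x {matrix.n_samples} samples")
print(f"mean LAD residual: {residuals.mean():.3g} mmol/gDCW/h")
imbalance = np.abs(fixture.model.S @ matrix.values).max()
print(f"worst mass imbalance: {imbalance:.3g}")

idx = {r: i for i, r in enumerate(matrix.reaction_ids)}
for cond in ("control", "perturbed"):
    mask = matrix.condition_mask(cond)
    v = matrix.values[idx["M1R1"], mask]
    print(f"knockout-target flux under {cond}: mean {v.mean():.3f}, sd {v.std():.3f}")

# A residual of 0 means every randomized target was exactly achievable; the
# knockout target carries ~1 mmol/gDCW/h in the control samples and exactly 0
# in the perturbed ones, the signature the downstream statistics detect.
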