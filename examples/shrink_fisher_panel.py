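"""Shrinkage prediction on a model-level synthetic study.

Generates two-session Fisher-Z connectivity for 50 subjects under the
measurement-error model with equal between-subject and error variance
(true shrinkage weight 0.5), estimates the voxelwise weight from the data,
and compares the raw / mean / shrinkage predictions of session 2 by MSE.
"""

import numpy as np

from fcshrink import (
    SyntheticConfig,
    generate_fisher_panel,
    lambda_map,
    mean_estimator,
    mse_per_subject,
    percent_reduction,
    raw_estimator,
    shrink,
    variance_components,
)

cfg = SyntheticConfig(
    n_subjects=50, n_voxels=2000, mu_x=0.3, sigma2_x=0.04, sigma2_u=0.04, rng_seed=1
)
panel, truth = generate_fisher_panel(cfg)

comp = variance_components(panel)
lam = lambda_map(comp)
print(f"true lambda          : {truth.lambda_true[0]:.3f}")
print(f"estimated lambda mean: {lam.values.mean():.3f} (ICC {lam.icc.mean():.3f})")

observed = panel.session("2")
for estimator in (raw_estimator(panel), mean_estimator(panel), shrink(panel, lam)):
    mse = mse_per_subject(estimator, observed).mean()
    red = percent_reduction(mse_per_subject(raw_estimator(panel), observed).mean(), mse)
    print(f"{estimator.method:<9} avg MSE {mse:.4f}  reduction vs raw {red:6.2f}%")

# The shrinkage predictor should undercut both: theory gives 0.080 (raw),
# 0.079 (mean), 0.060 (shrinkage) for these variances.
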