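"""Sparse-PCA shape scores and the volume-vs-thickness Cox comparison.

Builds a cohort whose hazard acts through a volume-neutral thickness
redistribution mode (thicker at one flank, thinner at the other). A
total-volume Cox model cannot see that mode; a model on the leading
sparse-PCA thickness scores can — and wins on AIC and concordance.
"""

import numpy as np
import pandas as pd
import trimesh

from surfmorph.geometry import SurfaceMesh
from surfmorph.ssa import fit_spca, shape_at_sd
from surfmorph.survival import SurvivalTable, run_survival_study
from surfmorph.synthetic import (
    CohortSpec,
    EffectRegion,
    SurvivalSpec,
    ellipsoid_directions,
    generate_cohort_thickness,
    generate_survival,
)

ico = trimesh.creation.icosphere(3)
template = SurfaceMesh(np.asarray(ico.vertices) * 60, np.asarray(ico.faces))
directions = ellipsoid_directions(template.vertices)

covariates = dict(CohortSpec().covariates)
covariates["shape"] = ("normal", 0.0, 1.0)
spec = CohortSpec(
    n_subjects=300,
    grid_shape=(80, 80, 80),
    noise_sd_mm=1.0,
    seed=2,
    effect_regions=[
        EffectRegion([1, 0, 0], 1.0, "shape", 3.0),
        EffectRegion([-1, 0, 0], 1.0, "shape", -3.0),
    ],
    covariates=covariates,
    survival=SurvivalSpec(baseline_hazard=0.06, log_hr={"z": 0.6}, censor_time=8.0),
)
matrix, table, _ = generate_cohort_thickness(spec, directions)
survival = generate_survival(spec, pd.DataFrame({"z": table["shape"].to_numpy()}))
survival["time"] = np.maximum(survival["time"], 1e-6)

model = fit_spca(matrix, k=4, sparsity=0.0, seed=2)
print("explained variance by PC:", np.round(model.explained_variance_ratio * 100, 1), "%")
scores = pd.DataFrame(model.scores, columns=[f"PC{j+1}" for j in range(4)])
scores = (scores - scores.mean()) / scores.std(ddof=1)

study = run_survival_study(
    pd.DataFrame({"age": table["age"], "asat_volume_l": matrix.mean(axis=1)}),
    SurvivalTable(survival),
    scores,
    adjustment=["age"],
    volume_col="asat_volume_l",
)
print("\nthickness model hazard ratios:")
print(study["thickness"].summary_frame().round(3).to_string())
print("\ncomparison:", {k: round(v, 3) if isinstance(v, float) else v for k, v in study["comparison"].items()})

# +/-3 SD reconstruction of the risk-carrying mode for interpretation
j = int(np.argmax(np.abs(np.log(study["thickness"].hazard_ratios[[f"PC{j+1}" for j in range(4)]]))))
mean_field = matrix.mean(axis=0)
up = shape_at_sd(model, mean_field, j, +3.0)
down = shape_at_sd(model, mean_field, j, -3.0)
print(f"\nPC{j+1} +/-3 SD changes thickness by up to {np.abs(up - down).max()/2:.1f} mm")
# Expect: the informative PC has HR ~ e^0.6 ~ 1.8 and survives FDR; the
# thickness model beats the volume model on both AIC and c-index.
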