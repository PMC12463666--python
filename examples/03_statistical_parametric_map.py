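"""Mass-univariate regression with TFCE + permutation + FDR.

Plants a +0.5 mm-per-SD age effect on 20% of the surface, fits the
vertex-wise model, and shows that the significant area recovers the
planted region while a null covariate stays quiet.
"""

import numpy as np
import trimesh

from surfmorph.geometry import SurfaceMesh, vertex_adjacency
from surfmorph.spm import DesignMatrix, SPMConfig, run_spm
from surfmorph.synthetic import CohortSpec, EffectRegion, ellipsoid_directions, generate_cohort_thickness
from surfmorph.thickness import CohortMatrix

ico = trimesh.creation.icosphere(4)
template = SurfaceMesh(np.asarray(ico.vertices) * 60, np.asarray(ico.faces))
directions = ellipsoid_directions(template.vertices)

theta = float(np.arccos(1 - 2 * 0.2))  # cap covering 20% of the sphere
spec = CohortSpec(
    n_subjects=200,
    noise_sd_mm=1.0,
    seed=11,
    effect_regions=[EffectRegion([0, 0, 1], theta, "age", 0.5, profile="flat")],
)
matrix, table, truth = generate_cohort_thickness(spec, directions)

design = DesignMatrix(table[["age", "hgs_kg"]], continuous=["age", "hgs_kg"])
result = run_spm(
    design,
    CohortMatrix(matrix),
    vertex_adjacency(template),
    SPMConfig(n_permutations=500, seed=1),
)
print(result.summary.round(3).to_string(index=False))

detected = result.sig_pos["age"]
support = truth.effect_support("age")
dice = 2 * (detected & support).sum() / (detected.sum() + support.sum())
print(f"\nDice overlap of detected vs planted region: {dice:.2f}")
print(f"median coefficient over detected region: {np.median(result.beta_mm['age'][detected]):.3f} mm/SD")
# Expect a positive significance area near 20% for age with a median
# coefficient near the planted 0.5 mm/SD, and ~0% area for grip strength.
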