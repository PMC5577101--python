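"""Detect a matrix-reorganisation phenotype from branch counts alone.

Simulates paired wells: a densely meshed control matrix versus an altered
matrix with a quarter of the mesh fibrils at twice the width (same overall
amount of signal, different organisation), then tests whether the branch
count separates the two phenotypes.
"""

import dataclasses

import numpy as np

from ecmscreen import (
    FibrilSpec,
    GroupData,
    analyze_well_image,
    generate_fibril_image,
    generate_phenotype_pair,
    students_t,
)

base = FibrilSpec(n_major_fibres=4, n_mesh_fibres=24, image_size=384, curvature=20.0)
control_counts, altered_counts = [], []
for seed in range(8):
    control, altered = generate_phenotype_pair(dataclasses.replace(base, seed=seed))
    altered = dataclasses.replace(altered, seed=seed + 1000)
    for spec, counts in ((control, control_counts), (altered, altered_counts)):
        well, _ = generate_fibril_image(spec)
        counts.append(analyze_well_image(well)[0].n_branches)

result = students_t(
    GroupData("control", np.asarray(control_counts, float)),
    GroupData("altered", np.asarray(altered_counts, float)),
)
print(f"control branches : {control_counts}  (mean {np.mean(control_counts):.1f})")
print(f"altered branches : {altered_counts}  (mean {np.mean(altered_counts):.1f})")
print(f"t = {result.t:.2f}, two-sided p = {result.p_two_sided:.2e}")
# A significant reduction says the matrix is organised into fewer, less
# interconnected fibrils - an effect invisible to total-intensity endpoints.
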