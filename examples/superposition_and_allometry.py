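"""J-matrix superposition and Boas-coordinate allometry diagnostics.

A Procrustes fit projects out position, orientation and scale through the
four rows of the J matrix built from the mean form.  The Boas variant keeps
size in the coordinates, so regressing each landmark on Centroid Size shows
whether the standard registration (rows 3-4 of J) suits the data: for pure
isotropic growth the regression vectors point radially out of the centroid.
"""

import numpy as np

from asymmorph import (
    LandmarkConfiguration,
    LandmarkSample,
    boas_allometry,
    gpa,
    standardize_mean,
)

rng = np.random.default_rng(0)
base = rng.normal(size=(8, 2))
ref = standardize_mean(LandmarkConfiguration(base, [f"L{i+1}" for i in range(8)]))
print("standardized mean: sum x =", round(ref.mu[0::2].sum(), 12),
      " centroid size =", round(float(np.sqrt((ref.mu**2).sum())), 12))
print("J J^T deviation from I:", float(np.max(np.abs(ref.J @ ref.J.T - np.eye(4)))))

# growth series: isotropic scaling plus one landmark growing off-radially
field = ref.mu.copy()
idx = 2
pos = ref.coords[idx]
r = np.linalg.norm(pos)
tang = np.array([-pos[1], pos[0]]) / r
field[2 * idx : 2 * idx + 2] += np.tan(np.deg2rad(30)) * r * tang
scales = 1.0 + 0.1 * rng.standard_normal(150)
sample = LandmarkSample(
    [
        LandmarkConfiguration(
            (ref.mu + (c - 1) * field).reshape(-1, 2) + rng.normal(scale=0.004, size=(8, 2)),
            ref.labels, f"s{i}",
        )
        for i, c in enumerate(scales)
    ]
)

fit = gpa(sample, scale=False)  # Boas: no scaling step
res = boas_allometry(fit, fit.centroid_sizes)
print("\nper-landmark misalignment of growth vectors vs radial (degrees):")
for lab, m in zip(res.labels, np.rad2deg(res.misalignment)):
    print(f"  {lab}: {m:5.1f}")
print(f"-> landmark {res.labels[idx]} carries the injected off-radial growth")
print("   (30 degrees before the rotation fit absorbs its torque); a large")
print("   misalignment flags landmarks the standard J-matrix misregisters.")
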