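"""Thorax phantom to capacitance vector: the forward simulation chain.

Rasterizes a randomized thorax with pathologies, solves the 32 excitation
fields, and prints the simulated normalized measurement vector's shape and
reciprocity error.
"""

import numpy as np

from cceit import band, dataset, forward, phantom

scene = phantom.assign_pathologies(phantom.sample_thorax(3), rng=3)
print("lung labels:", scene.lung_labels)

cmap, eps = phantom.rasterize(scene)
print(f"conductivity image {cmap.values.shape}, "
      f"range {cmap.values.min():.2f}..{cmap.values.max():.2f} S/m")

layout = band.equidistant_layout()
S = forward.sensitivity_for_layout(layout)
print(f"sensitivity matrix {S.shape} (992 electrode pairs x 4096 pixels)")

C = forward.simulate_capacitance(S, eps.ravel())
C_low, C_high = dataset.reference_vectors(S)
Cn = dataset.normalize(C, C_low, C_high)
Cn_noisy = dataset.add_noise(Cn, 30.0, rng=0)

swap = forward.ORDERING.swapped()
print(f"measurements: {len(Cn)} channels, "
      f"reciprocity error pre-noise {np.abs(Cn - Cn[swap]).max():.2e}")
print(f"normalized range {Cn.min():.3f}..{Cn.max():.3f}; "
      "0 = uniform air reference, 1 = uniform tissue reference")

# deterministic sanity-check reconstruction from the linear model
x = forward.landweber_baseline(Cn, np.real(S), iterations=100, nonneg=False)
print(f"Landweber baseline image {x.shape}, "
      f"peak at pixel {np.unravel_index(np.argmax(np.abs(x)), x.shape)}")
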