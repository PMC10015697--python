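"""Semivariogram estimation and ordinary kriging of coverage proportions.

Generates noisy samples of a smooth coverage surface at scattered planar
locations, fits a spherical semivariogram by weighted least squares, and
interpolates the surface at unsampled points with uncertainty.
"""

import numpy as np

from spatbiv import PointSample, empirical_semivariogram, fit_variogram, ordinary_kriging

rng = np.random.default_rng(12)
xy = rng.uniform(0, 10, (60, 2))
surface = 0.4 + 0.3 * np.sin(xy[:, 0] / 3.0) * np.cos(xy[:, 1] / 3.0)
points = [PointSample(x, y, v + rng.normal(0, 0.02)) for (x, y), v in zip(xy, surface)]

emp = empirical_semivariogram(points, n_bins=12)
vgm = fit_variogram(emp, model="spherical")
print(f"fitted variogram: nugget={vgm.nugget:.4f}, "
      f"partial sill={vgm.partial_sill:.4f}, range={vgm.range_:.2f}")

for target in [(5.0, 5.0), (1.0, 9.0)]:
    (pred,) = ordinary_kriging(points, vgm, [target])
    print(f"Z{target} = {pred.value:.3f}  (kriging sd {np.sqrt(pred.variance):.3f}, "
          f"weight sum {pred.weights.sum():.6f})")
# Weights summing to 1 is the ordinary-kriging unbiasedness constraint; the
# kriging sd quantifies interpolation uncertainty away from the samples.
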