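"""Forward scattering from a dielectric cylinder, checked against the
analytic eigenfunction series.

Builds a homogeneous cylinder (eps_r = 2, radius 2 cm) centred in a 25 cm
imaging domain, simulates the multi-static scattered field at 3 GHz with the
method-of-moments CG-FFT solver, and compares the receiver samples with the
exact Bessel/Hankel series solution.  The printed relative RMS error is the
discretization error of the 64x64 pulse-basis grid (a fraction of a percent
when the interior wavelength is well resolved).
"""

import numpy as np

from qmwi import ImagingGrid, PermittivityScene, circular_config
from qmwi.forward import cylinder_scattered_field, scattered_field

grid = ImagingGrid(64, 64, 0.25)
config = circular_config(n_tx=8, n_rx=241, radius=1.67, frequencies=[3e9])
scene = PermittivityScene.homogeneous(grid).with_disc(
    center=(0.0, 0.0), radius=0.02, eps_eq=2.0, antialias=True
)

es = scattered_field(scene, config, tol=1e-8)[:, :, 0]
ref = cylinder_scattered_field(0.02, 2.0, 1.0, 3e9, config)
rel_rms = np.linalg.norm(es - ref) / np.linalg.norm(ref)

print(f"scattered field shape (receivers x transmitters): {es.shape}")
print(f"peak |Es| at the receivers: {np.abs(es).max():.3e}")
print(f"relative RMS error vs analytic cylinder series: {100 * rel_rms:.2f}%")
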