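"""Differential stroke imaging with a procedural head phantom.

Builds a layered head phantom (skin / skull / CSF / grey / white tissues with
Cole-Cole dispersion, +-10% inter-subject variability) immersed in a lossy
matching medium, inserts one stroke, and simulates the 16-antenna 0.5-1.25 GHz
measurement.  The OSM indicator is computed from the differential data
(stroke minus healthy baseline) using the numerical Green's function of the
nominal healthy head; its peak localizes the stroke to within ~2 cm.
"""

import numpy as np

from qmwi.forward import scattered_field
from qmwi.osm import compute_indicator_stack, differential_data, numerical_green_table
from qmwi.synth import (
    brain_config,
    brain_grid,
    nominal_healthy_scenes,
    sample_head_phantom,
    tissue_contrast,
    TISSUES,
)

grid = brain_grid(32)
config = brain_config()

print("stroke-tissue contrast amplitudes vs the matching medium at 1 GHz:")
for name in ("ischemic-surrogate", "blood"):
    print(f"  {name}: |tau| = {abs(tissue_contrast(TISSUES[name], 1e9)):.3f}")

background = nominal_healthy_scenes(grid, config.frequencies)
tables = [numerical_green_table(background[fi], config, fi, tol=1e-5)
          for fi in range(config.n_freq)]

sample = sample_head_phantom(101, grid, "hemorrhagic", config.frequencies)
es = differential_data(
    scattered_field(None, config, tol=1e-5, dispersive_scenes=sample.stroke_scenes),
    scattered_field(None, config, tol=1e-5, dispersive_scenes=sample.healthy_scenes),
)
stack = compute_indicator_stack(es, tables, config, green_norm=True)

cx, cy = sample.spec.stroke.center
x, y = grid.axes()
print(f"\ntrue stroke: hemorrhagic, centre ({100*cx:+.1f}, {100*cy:+.1f}) cm, "
      f"radius {100*sample.spec.stroke.radius:.1f} cm")
for fi, f in enumerate(config.frequencies):
    img = stack.images()[fi]
    iy, ix = np.unravel_index(np.argmax(img), img.shape)
    err = np.hypot(x[ix] - cx, y[iy] - cy)
    print(f"  {f/1e9:.2f} GHz indicator peak: ({100*x[ix]:+.1f}, {100*y[iy]:+.1f}) cm "
          f"-> {100*err:.1f} cm from the stroke centre")
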