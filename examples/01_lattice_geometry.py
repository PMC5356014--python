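"""Lattice geometry of an asynchronously sampled time-stretch imager.

Computes the warped-lattice numbers for the reference instrument: a
5 GSa/s digitizer free-running against an 11.6142 MHz mode-locked laser,
with spectral encoding at 7.1 μm/nm and 400 ps/nm of dispersion.
"""

import math

from pixelsr import AcquisitionConfig, geometry, min_subpixel_factor

cfg = AcquisitionConfig(f=5e9, F=11.6142e6, C_x=7.1, C_t=0.4,
                        v_y=2.0905, B=10e9, d_opt=2.0)
g = geometry(cfg)

print(g.report())
q = min_subpixel_factor(cfg.f, cfg.B)
print(f"\nmin sub-pixel factor q = {q} (effective rate {q * cfg.f / 1e9:.0f} GSa/s,"
      f" HR pitch {g.dx / q:.3f} um)")

# What the numbers mean: the fast-axis pixel is ~20x wider than the
# slow-axis pixel (aspect ratio ~0.05), but the clock mismatch drifts each
# line by ~half a pixel, shearing the lattice at tan(theta) ~ -10 — so
# interleaving neighboring lines can shrink the fast-axis pixel by
# gain = 1/cos(theta) ~ 10x without any extra hardware.
print(f"\npixel aspect ratio {g.rho:.3f}, lattice shear tan(theta) = "
      f"{math.tan(g.theta):.2f}, potential fast-axis gain {g.gain:.1f}x")
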