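"""Closed-form benchmarks for solver verification.

The thick-walled cylinder under internal pressure (Lame problem) in
plane strain, which the straight-tube fixture reproduces: a tube held
axially and circumferentially at both ends deforms in plane strain, so
the FE solution can be compared with

    sigma_r(r)     = p a^2 / (b^2 - a^2) * (1 - b^2 / r^2)
    sigma_theta(r) = p a^2 / (b^2 - a^2) * (1 + b^2 / r^2)
    u_r(r) = (1 + nu) p a^2 / (E (b^2 - a^2)) * ((1 - 2 nu) r + b^2 / r)

with internal pressure p, inner/outer radii a/b.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lame_stresses", "lame_radial_displacement"]


def lame_stresses(r, a: float, b: float, p: float):
    """Radial and hoop stress of the pressurized thick-walled cylinder."""
    r = np.asarray(r, dtype=float)
    k = p * a**2 / (b**2 - a**2)
    return k * (1.0 - b**2 / r**2), k * (1.0 + b**2 / r**2)


def lame_radial_displacement(r, a: float, b: float, p: float, e: float, nu: float):
    """Plane-strain radial displacement, same units as the inputs."""
    r = np.asarray(r, dtype=float)
    k = (1.0 + nu) * p * a**2 / (e * (b**2 - a**2))
    return k * ((1.0 - 2.0 * nu) * r + b**2 / r)
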