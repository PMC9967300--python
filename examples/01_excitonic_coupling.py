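"""Excitonic coupling of an idealised squaraine dimer.

Builds two extended dipoles by hand — an SQ-H2 pair (|mu| = 12.99 D,
1.4 nm bridge) stacked face to face at 0.6 nm — and evaluates the
exciton hopping parameter J_mn with the four-point-charge extended
dipole formula, next to the point-dipole reference.
"""

import numpy as np

from sqdimer import (
    CouplingParameters,
    ExtendedDipole,
    extended_dipole_coupling,
    point_dipole_coupling,
)


def dipole(center, axis, length=1.4, mu=12.99):
    center, axis = np.asarray(center, float), np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    return ExtendedDipole(center=center, mu_hat=axis,
                          r=center + length / 2 * axis, s=center - length / 2 * axis,
                          length=length, mu_mag=mu)


p = CouplingParameters(refractive_index=1.33, energy_unit="cm_inv")

cofacial_m = dipole((0, 0, 0), (1, 0, 0))
cofacial_n = dipole((0, 0, 0.6), (1, 0, 0))
head_tail_n = dipole((3.0, 0, 0), (1, 0, 0))

J_h = extended_dipole_coupling(cofacial_m, cofacial_n, p).J_mn
J_j = extended_dipole_coupling(cofacial_m, head_tail_n, p).J_mn
J_pt = point_dipole_coupling(cofacial_m, cofacial_n, p)

print(f"cofacial (H) pair at 0.6 nm:   J_mn = {J_h:8.1f} cm^-1")
print(f"head-to-tail (J) pair at 3 nm: J_mn = {J_j:8.1f} cm^-1")
print(f"point-dipole reference (H):    J    = {J_pt:8.1f} cm^-1")
print()
print("A positive J marks H-type (face-to-face) coupling, negative J-type.")
print("At 0.6 nm the bridges (1.4 nm) are long compared with the gap, so the")
print("extended-dipole value sits far below the point-dipole estimate —")
print("exactly why the extended form is used at stacking distances.")
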