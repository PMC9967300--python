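"""Exciton hopping parameter J_mn in the extended dipole approximation.

Each transition dipole is replaced by two opposite point charges
q = mu/l at the pi-bridge termini r (positive, the end mu_hat points
toward) and s (negative), separated by the bridge length l.  The
coupling between dyes m and n is then a sum of four Coulomb terms:

    J_mn = J_o * ( 1/|r1-r2| - 1/|r1-s2| - 1/|s1-r2| + 1/|s1-s2| )
    J_o  = mu_m * mu_n / (4 pi eps0 n^2 l_m l_n)

with n the refractive index of the medium.  The prefactor generalises
the homodimer |mu|^2 to the product mu_m * mu_n, to which it reduces
exactly for identical dyes.  With this sign convention a cofacial
(H-aggregate) pair has J_mn > 0 and a head-to-tail (J-aggregate) pair
J_mn < 0.

Units: |mu| in Debye, lengths in nm; output in cm^-1 (default) or meV.
The conversion constant — the energy of 1 D^2 / nm^3 against 4 pi eps0
— is evaluated from CODATA constants at import, not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import constants

from .dyes import ExtendedDipole
from .orientation import DimerGeometry

__all__ = [
    "K_CM_PER_D2_NM3",
    "K_MEV_PER_D2_NM3",
    "CouplingParameters",
    "CouplingResult",
    "coupling_prefactor",
    "extended_dipole_coupling",
    "point_dipole_coupling",
    "coupling_series",
    "coupling_table",
]

_DEBYE_CM = 1e-21 / constants.c  # 1 Debye in C*m (exact SI definition)


def _k_joule() -> float:
    """Energy in J of 1 D^2 / (4 pi eps0 * 1 nm^3)."""
    return _DEBYE_CM**2 / (4 * np.pi * constants.epsilon_0 * 1e-27)


#: 1 D^2/nm^3 in wavenumbers (~5.034 cm^-1).
K_CM_PER_D2_NM3 = _k_joule() / (constants.h * constants.c * 100.0)
#: 1 D^2/nm^3 in meV.
K_MEV_PER_D2_NM3 = _k_joule() / constants.e * 1e3

ENERGY_UNITS = ("cm_inv", "meV")
_MIN_PAIR_DISTANCE = 1e-4  # nm


@dataclass(frozen=True)
class CouplingParameters:
    """Medium and unit choices for the coupling calculation.

    refractive_index defaults to 1.33 (aqueous buffer); the screening
    enters as 1/n^2.
    """

    refractive_index: float = 1.33
    energy_unit: str = "cm_inv"

    def __post_init__(self) -> None:
        if self.refractive_index <= 0:
            raise ValueError("refractive index must be positive")
        if self.energy_unit not in ENERGY_UNITS:
            raise ValueError(
                f"energy_unit must be one of {ENERGY_UNITS}, got {self.energy_unit!r}"
            )

    @property
    def K(self) -> float:
        """1 D^2/nm^3 in the configured energy unit."""
        return K_CM_PER_D2_NM3 if self.energy_unit == "cm_inv" else K_MEV_PER_D2_NM3


@dataclass(frozen=True)
class CouplingResult:
    frame_index: int
    J_o: float
    J_mn: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.J_o) and np.isfinite(self.J_mn)):
            raise ValueError(f"non-finite coupling at frame {self.frame_index}")


def coupling_prefactor(
    mu_mag_m: float,
    mu_mag_n: float,
    l_m: float,
    l_n: float,
    p: CouplingParameters = CouplingParameters(),
) -> float:
    """Prefactor J_o = K * mu_m mu_n / (n^2 l_m l_n), energy_unit * nm."""
    if min(mu_mag_m, mu_mag_n) <= 0:
        raise ValueError("dipole magnitudes must be positive")
    if min(l_m, l_n) <= 0:
        raise ValueError("bridge lengths must be positive")
    return p.K * mu_mag_m * mu_mag_n / (p.refractive_index**2 * l_m * l_n)


def extended_dipole_coupling(
    dm: ExtendedDipole,
    dn: ExtendedDipole,
    p: CouplingParameters = CouplingParameters(),
    frame_index: int = 0,
) -> CouplingResult:
    """Four-term extended-dipole coupling between two dyes."""
    pairs = {
        "r1-r2": (dm.r, dn.r),
        "r1-s2": (dm.r, dn.s),
        "s1-r2": (dm.s, dn.r),
        "s1-s2": (dm.s, dn.s),
    }
    dists = {}
    for label, (a, b) in pairs.items():
        d = float(np.linalg.norm(a - b))
        if d <= _MIN_PAIR_DISTANCE:
            raise ValueError(
                f"near-coincident bridge endpoints |{label}| = {d:.2e} nm "
                f"(frame {frame_index})"
            )
        dists[label] = d
    J_o = coupling_prefactor(dm.mu_mag, dn.mu_mag, dm.length, dn.length, p)
    geom = (
        1.0 / dists["r1-r2"]
        - 1.0 / dists["r1-s2"]
        - 1.0 / dists["s1-r2"]
        + 1.0 / dists["s1-s2"]
    )
    return CouplingResult(frame_index=frame_index, J_o=J_o, J_mn=J_o * geom)


def point_dipole_coupling(
    dm: ExtendedDipole,
    dn: ExtendedDipole,
    p: CouplingParameters = CouplingParameters(),
) -> float:
    """Point-dipole reference: K mu_m mu_n kappa / (n^2 R^3), sign-aware.

    This is the l -> 0 limit of the extended-dipole form and the classic
    dipole-dipole interaction with the signed orientation factor
    kappa = mu_hat_m.mu_hat_n - 3 (mu_hat_m.R_hat)(mu_hat_n.R_hat).
    """
    dvec = dn.center - dm.center
    R = float(np.linalg.norm(dvec))
    if R <= 1e-6:
        raise ValueError("coincident dye centres")
    R_hat = dvec / R
    kappa = float(np.dot(dm.mu_hat, dn.mu_hat)) - 3.0 * float(
        np.dot(dm.mu_hat, R_hat)
    ) * float(np.dot(dn.mu_hat, R_hat))
    return p.K * dm.mu_mag * dn.mu_mag * kappa / (p.refractive_index**2 * R**3)


def coupling_series(
    dipoles_m: list[ExtendedDipole],
    dipoles_n: list[ExtendedDipole],
    p: CouplingParameters = CouplingParameters(),
    frame_indices: list[int] | None = None,
) -> list[CouplingResult]:
    """Per-frame couplings for two aligned dipole series."""
    if len(dipoles_m) != len(dipoles_n):
        raise ValueError(
            f"series not aligned: {len(dipoles_m)} vs {len(dipoles_n)} frames"
        )
    if frame_indices is None:
        frame_indices = list(range(len(dipoles_m)))
    return [
        extended_dipole_coupling(dm, dn, p, frame_index=k)
        for dm, dn, k in zip(dipoles_m, dipoles_n, frame_indices)
    ]


def coupling_table(
    results: list[CouplingResult],
    dipoles_m: list[ExtendedDipole] | None = None,
    dipoles_n: list[ExtendedDipole] | None = None,
) -> pd.DataFrame:
    """Per-frame J table; endpoint distances included for audit when available."""
    df = pd.DataFrame(
        {
            "frame_index": [r.frame_index for r in results],
            "J_o": [r.J_o for r in results],
            "J_mn": [r.J_mn for r in results],
        }
    )
    if dipoles_m is not None and dipoles_n is not None:
        for label, am, an in (
            ("d_r1_r2", "r", "r"),
            ("d_r1_s2", "r", "s"),
            ("d_s1_r2", "s", "r"),
            ("d_s1_s2", "s", "s"),
        ):
            df[label] = [
                float(np.linalg.norm(getattr(dm, am) - getattr(dn, an)))
                for dm, dn in zip(dipoles_m, dipoles_n)
            ]
    return df
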