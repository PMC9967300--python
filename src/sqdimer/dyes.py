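"""Extended-dipole representation of a squaraine dye.

A squaraine (SQ) dye is modelled geometrically by three landmark groups:
the four carbons of the central squarate ring, and the two terminal
benzene rings at the ends of the pi-conjugation bridge.  The dye centre
is the mass-weighted centre of the squarate carbons; the transition
dipole direction mu_hat points from that centre toward the centre of the
benzene ring furthest from the covalent DNA linker (the dye long axis);
and the bridge termini r and s sit at the two ring centres, separated by
the bridge length l.  Transition-dipole magnitudes |mu| (Debye) come
from a small parameter table; the packaged defaults are TDDFT values for
the SQ-H2, SQ-Cl2 and SQ-Me2 variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .trajectory import Frame, SelectionConfig

__all__ = [
    "ExtendedDipole",
    "DyeParameters",
    "DEFAULT_DYE_PARAMETERS",
    "extract_extended_dipole",
    "dipole_vector",
]

#: TDDFT transition-dipole magnitudes, Debye, for the packaged SQ variants.
DEFAULT_DYE_PARAMETERS: Mapping[str, float] = {
    "SQ-H2": 12.99,
    "SQ-Cl2": 13.41,
    "SQ-Me2": 13.73,
}

_UNIT_TOL = 1e-9
_DEGENERATE_TOL = 1e-6


class DyeParameters:
    """Dye name -> |mu| in Debye."""

    def __init__(self, magnitudes: Mapping[str, float] | None = None):
        self.magnitudes = dict(magnitudes if magnitudes is not None else DEFAULT_DYE_PARAMETERS)
        for name, mu in self.magnitudes.items():
            if mu <= 0:
                raise ValueError(f"dye {name!r}: |mu| must be positive, got {mu}")

    def __getitem__(self, name: str) -> float:
        try:
            return self.magnitudes[name]
        except KeyError:
            raise KeyError(
                f"unknown dye {name!r}; known: {sorted(self.magnitudes)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.magnitudes

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DyeParameters":
        return cls(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.magnitudes, sort_keys=True))


@dataclass(frozen=True)
class ExtendedDipole:
    """One dye in one frame, reduced to its extended-dipole geometry.

    Attributes
    ----------
    center:
        Mass-weighted centre of the four squarate carbons, nm.
    mu_hat:
        Unit transition-dipole direction (centre -> far ring centre).
    r, s:
        Bridge termini: centres of the far and near benzene rings, nm.
        ``r`` is the terminus mu_hat points toward.
    length:
        Bridge length |r - s|, nm.
    mu_mag:
        Transition-dipole magnitude, Debye.
    """

    center: np.ndarray
    mu_hat: np.ndarray
    r: np.ndarray
    s: np.ndarray
    length: float
    mu_mag: float

    def __post_init__(self) -> None:
        for name in ("center", "mu_hat", "r", "s"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if abs(np.linalg.norm(self.mu_hat) - 1.0) > _UNIT_TOL:
            raise ValueError("mu_hat is not a unit vector")
        if self.length <= 0:
            raise ValueError(f"bridge length must be positive, got {self.length}")
        if self.mu_mag <= 0:
            raise ValueError(f"|mu| must be positive, got {self.mu_mag}")
        if float(np.dot(self.mu_hat, self.r - self.s)) <= 0:
            raise ValueError("r must be the bridge terminus mu_hat points toward")


def extract_extended_dipole(
    frame: Frame,
    sel: SelectionConfig,
    params: DyeParameters,
    dye_name: str,
) -> ExtendedDipole:
    """Build the extended dipole of one dye from a single frame.

    The squarate centre is mass-weighted; the benzene ring centres are
    unweighted geometric centres of the configured ring atoms (the rings
    are carbon-only selections by convention, so weighting is immaterial
    there).
    """
    dye_sel = sel[dye_name]
    # mass-weighted CoM of the squarate carbons: all four are carbon, so
    # the weights are equal and the plain mean is exact
    c = frame.coords[list(dye_sel.squarate_carbons)].mean(axis=0)
    far = frame.coords[list(dye_sel.benzene_ring_far)].mean(axis=0)
    near = frame.coords[list(dye_sel.benzene_ring_near)].mean(axis=0)
    axis = far - c
    norm = np.linalg.norm(axis)
    if norm < _DEGENERATE_TOL:
        raise ValueError(
            f"dye {dye_name!r}, frame {frame.frame_index}: far ring centre "
            f"coincides with the squarate centre (|far - c| = {norm:.2e} nm)"
        )
    return ExtendedDipole(
        center=c,
        mu_hat=axis / norm,
        r=far,
        s=near,
        length=float(np.linalg.norm(far - near)),
        mu_mag=params[dye_name],
    )


def dipole_vector(d: ExtendedDipole) -> np.ndarray:
    """Full transition-dipole vector mu = |mu| * mu_hat, in Debye."""
    return d.mu_mag * d.mu_hat
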