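"""Residue-residue contact maps over a trajectory.

Two residues are in contact in a frame when their mass-weighted centres
of mass are within a cutoff (default 1.2 nm, the electrostatic cutoff
of the production simulations this analysis targets; the boundary is
inclusive).  The contact probability is the fraction of frames in
contact, so a pair within the cutoff for the entire trajectory scores
1.0 and a never-contacting pair 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .trajectory import Frame, ResidueMap, Trajectory

__all__ = [
    "ContactMatrix",
    "residue_com_series",
    "frame_contacts",
    "contact_probability",
    "dye_contact_summary",
]

DEFAULT_CUTOFF_NM = 1.2


@dataclass
class ContactMatrix:
    """Symmetric residue x residue contact-probability matrix."""

    residue_ids: list[int]
    P: np.ndarray
    cutoff: float
    n_frames_counted: int

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        n = len(self.residue_ids)
        if self.P.shape != (n, n):
            raise ValueError(f"P must be {n}x{n}, got {self.P.shape}")
        if not np.allclose(self.P, self.P.T):
            raise ValueError("P must be symmetric")
        if np.any((self.P < 0) | (self.P > 1)):
            raise ValueError("contact probabilities must lie in [0, 1]")

    def probability(self, rid_i: int, rid_j: int) -> float:
        i = self.residue_ids.index(rid_i)
        j = self.residue_ids.index(rid_j)
        return float(self.P[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.residue_ids, columns=self.residue_ids)


def _com_weights(rmap: ResidueMap, masses: np.ndarray) -> np.ndarray:
    """(n_residues, n_atoms) matrix W with W @ coords = per-residue CoM."""
    n_atoms = masses.shape[0]
    W = np.zeros((len(rmap), n_atoms))
    for row, rid in enumerate(rmap.residue_ids):
        idx = list(rmap[rid].atom_indices)
        if not idx:
            raise ValueError(f"residue {rid} has no atoms")
        m = masses[idx]
        W[row, idx] = m / m.sum()
    return W


def residue_com_series(traj: Trajectory, rmap: ResidueMap) -> np.ndarray:
    """Per-frame residue centres of mass, shape (n_frames, n_residues, 3)."""
    W = _com_weights(rmap, traj.masses)
    return np.einsum("ra,fac->frc", W, traj.coords_array())


def frame_contacts(
    frame: Frame,
    rmap: ResidueMap,
    atoms,
    cutoff: float = DEFAULT_CUTOFF_NM,
) -> np.ndarray:
    """Boolean residue-contact matrix for one frame (diagonal True)."""
    masses = np.array([a.mass for a in atoms])
    W = _com_weights(rmap, masses)
    coms = W @ frame.coords
    d = squareform(pdist(coms))
    return d <= cutoff


def contact_probability(
    traj: Trajectory,
    rmap: ResidueMap,
    cutoff: float = DEFAULT_CUTOFF_NM,
) -> ContactMatrix:
    """Fraction of frames each residue pair spends within the cutoff."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    coms = residue_com_series(traj, rmap)  # (F, R, 3)
    diff = coms[:, :, None, :] - coms[:, None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    P = (d <= cutoff).mean(axis=0)
    np.fill_diagonal(P, 1.0)
    return ContactMatrix(
        residue_ids=rmap.residue_ids,
        P=P,
        cutoff=cutoff,
        n_frames_counted=traj.n_frames,
    )


def dye_contact_summary(
    cm: ContactMatrix,
    rmap: ResidueMap,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-dye count and identity of non-dye residues contacted at >= threshold.

    Returns one row per dye residue with the number of non-dye residues
    whose contact probability meets the threshold, plus their ids and
    strands — the quantity used to compare how much each dimer placement
    interacts with the surrounding scaffold.
    """
    dyes = rmap.dye_residues()
    if not dyes:
        raise ValueError("residue map contains no dye residues")
    rows = []
    for dye in dyes:
        partners = [
            rid
            for rid in rmap.residue_ids
            if rmap[rid].label != "dye" and cm.probability(dye, rid) >= threshold
        ]
        rows.append(
            {
                "dye_residue": dye,
                "n_contacts": len(partners),
                "contact_residues": partners,
                "contact_strands": [rmap[r].strand for r in partners],
            }
        )
    return pd.DataFrame(rows)
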