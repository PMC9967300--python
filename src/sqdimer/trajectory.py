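"""Trajectory data model and file I/O.

All coordinates are stored internally in nanometres and times in
nanoseconds.  Unit conversion from the on-disk formats (PDB and XYZ are
Angstrom-based; MDAnalysis normalises GRO to Angstrom as well) happens
only inside the readers/writers, never downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "ResidueEntry",
    "ResidueMap",
    "DyeSelection",
    "SelectionConfig",
    "load_trajectory",
    "trajectory_from_reader",
    "write_pdb",
    "residue_center_of_mass",
    "slice_trajectory",
]

ANGSTROM_TO_NM = 0.1
PS_TO_NS = 1e-3

RESIDUE_LABELS = ("nucleotide", "linker", "dye", "other")
STRANDS = ("A", "B", "C", "D", "none")


@dataclass(frozen=True)
class AtomRecord:
    """Static per-atom bookkeeping (identity, element, mass, residue)."""

    atom_index: int
    atom_name: str
    element: str
    mass: float
    residue_id: int

    def __post_init__(self) -> None:
        if self.atom_index < 0:
            raise ValueError(f"atom_index must be >= 0, got {self.atom_index}")
        if self.mass <= 0:
            raise ValueError(
                f"atom {self.atom_index} ({self.atom_name}): mass must be positive, "
                f"got {self.mass}"
            )
        if self.residue_id < 1:
            raise ValueError(f"residue_id must be >= 1, got {self.residue_id}")


@dataclass
class Frame:
    """One snapshot: an (n_atoms, 3) coordinate array in nm and a time in ns."""

    frame_index: int
    time: float
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(
                f"frame {self.frame_index}: coords must be (n_atoms, 3), "
                f"got shape {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"frame {self.frame_index}: non-finite coordinates")
        if self.time < 0:
            raise ValueError(f"frame {self.frame_index}: negative time {self.time}")


class Trajectory:
    """Ordered frames over a fixed atom set.

    Parameters
    ----------
    atoms:
        One :class:`AtomRecord` per atom, in coordinate-array order.
    frames:
        Frames in time order; every frame must carry exactly
        ``len(atoms)`` coordinates and times must be non-decreasing.
    """

    def __init__(self, atoms: Sequence[AtomRecord], frames: Sequence[Frame]):
        self.atoms = list(atoms)
        self.frames = list(frames)
        self._validate()

    def _validate(self) -> None:
        if not self.atoms:
            raise ValueError("trajectory has no atoms")
        if not self.frames:
            raise ValueError("trajectory has no frames")
        indices = [a.atom_index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise ValueError("duplicate atom indices")
        n = len(self.atoms)
        for f in self.frames:
            if f.coords.shape[0] != n:
                raise ValueError(
                    f"frame {f.frame_index}: expected {n} atoms, "
                    f"got {f.coords.shape[0]}"
                )
        times = [f.time for f in self.frames]
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times are not non-decreasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords_array(self) -> np.ndarray:
        """Stack all frames into an (n_frames, n_atoms, 3) array (nm)."""
        return np.stack([f.coords for f in self.frames])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __repr__(self) -> str:
        return f"Trajectory(n_atoms={self.n_atoms}, n_frames={self.n_frames})"


@dataclass
class ResidueEntry:
    atom_indices: tuple[int, ...]
    label: str
    strand: str = "none"

    def __post_init__(self) -> None:
        self.atom_indices = tuple(int(i) for i in self.atom_indices)
        if self.label not in RESIDUE_LABELS:
            raise ValueError(f"unknown residue label {self.label!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.label == "dye" and not self.atom_indices:
            raise ValueError("dye residue with empty atom selection")


class ResidueMap:
    """Residue id -> (atom indices, label, strand), with disjointness checks."""

    def __init__(self, entries: Mapping[int, ResidueEntry]):
        self.entries = dict(sorted(entries.items()))
        seen: set[int] = set()
        for rid, e in self.entries.items():
            overlap = seen.intersection(e.atom_indices)
            if overlap:
                raise ValueError(
                    f"residue {rid}: atom indices {sorted(overlap)} already assigned"
                )
            seen.update(e.atom_indices)
        self._check_contiguous_per_strand()

    def _check_contiguous_per_strand(self) -> None:
        by_strand: dict[str, list[int]] = {}
        for rid, e in self.entries.items():
            by_strand.setdefault(e.strand, []).append(rid)
        for strand, rids in by_strand.items():
            if strand == "none":
                continue
            rids = sorted(rids)
            if rids != list(range(rids[0], rids[0] + len(rids))):
                raise ValueError(f"residue IDs on strand {strand} not contiguous: {rids}")

    @property
    def residue_ids(self) -> list[int]:
        return list(self.entries)

    def dye_residues(self) -> list[int]:
        return [rid for rid, e in self.entries.items() if e.label == "dye"]

    def __getitem__(self, rid: int) -> ResidueEntry:
        return self.entries[rid]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[int]:
        return iter(self.entries)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            int(rid): {
                "atom_indices": list(e.atom_indices),
                "label": e.label,
                "strand": e.strand,
            }
            for rid, e in self.entries.items()
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ResidueMap":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            {
                int(rid): ResidueEntry(
                    atom_indices=tuple(v["atom_indices"]),
                    label=v["label"],
                    strand=v.get("strand", "none"),
                )
                for rid, v in payload.items()
            }
        )


@dataclass
class DyeSelection:
    """Atom selections (0-based indices) defining one dye's geometry.

    ``benzene_ring_far`` is the terminal ring furthest from the covalent
    linker; the transition dipole direction points from the squarate
    centre toward this ring's centre.  The far/near assignment is static
    configuration — covalent topology does not change along a trajectory,
    and per-frame inference could flip the dipole direction spuriously.
    """

    squarate_carbons: tuple[int, ...]
    benzene_ring_far: tuple[int, ...]
    benzene_ring_near: tuple[int, ...]
    dye_residue_id: int

    def __post_init__(self) -> None:
        self.squarate_carbons = tuple(int(i) for i in self.squarate_carbons)
        self.benzene_ring_far = tuple(int(i) for i in self.benzene_ring_far)
        self.benzene_ring_near = tuple(int(i) for i in self.benzene_ring_near)
        if len(self.squarate_carbons) != 4:
            raise ValueError(
                f"exactly 4 squarate carbons required, got {len(self.squarate_carbons)}"
            )
        for name, ring in (
            ("benzene_ring_far", self.benzene_ring_far),
            ("benzene_ring_near", self.benzene_ring_near),
        ):
            if len(ring) < 5:
                raise ValueError(f"{name} needs >= 5 atoms, got {len(ring)}")
        if set(self.benzene_ring_far) & set(self.benzene_ring_near):
            raise ValueError("far and near ring selections overlap")


class SelectionConfig:
    """Named dye selections, e.g. ``{"dye_m": DyeSelection(...), ...}``."""

    def __init__(self, dyes: Mapping[str, DyeSelection]):
        if not dyes:
            raise ValueError("no dye selections configured")
        self.dyes = dict(dyes)

    def __getitem__(self, name: str) -> DyeSelection:
        return self.dyes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.dyes)

    @property
    def dye_names(self) -> list[str]:
        return list(self.dyes)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            name: {
                "squarate_carbons": list(sel.squarate_carbons),
                "benzene_ring_far": list(sel.benzene_ring_far),
                "benzene_ring_near": list(sel.benzene_ring_near),
                "dye_residue_id": sel.dye_residue_id,
            }
            for name, sel in self.dyes.items()
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelectionConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls({name: DyeSelection(**v) for name, v in payload.items()})


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_FORMATS = ("pdb_multimodel", "gro", "xyz")
_EXT_TO_FORMAT = {".pdb": "pdb_multimodel", ".gro": "gro", ".xyz": "xyz"}


def _validate_pdb_model_counts(path: Path) -> None:
    """Pre-scan MODEL blocks so a short frame is reported by index."""
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = 0
            elif rec in ("ATOM", "HETATM"):
                if current is None:  # file without MODEL records: one implicit model
                    current = 0
                current += 1
            elif rec == "ENDMDL":
                if current is not None:
                    counts.append(current)
                    current = None
    if current is not None:
        counts.append(current)
    if not counts or all(c == 0 for c in counts):
        raise ValueError(f"{path}: no atoms found")
    ref = counts[0]
    for i, c in enumerate(counts):
        if c != ref:
            raise ValueError(
                f"{path}: frame {i} has {c} atoms, expected {ref} (from frame 0)"
            )


def load_trajectory(path: str | Path, format: str | None = None) -> Trajectory:
    """Read a multi-frame coordinate file into a :class:`Trajectory`.

    Supported formats: ``pdb_multimodel`` (MODEL/ENDMDL records), ``gro``
    (concatenated frames) and ``xyz`` (multi-frame).  Coordinates are
    converted to nm and per-frame times, when the file carries them, to ns.
    Atom masses are assigned from the element via MDAnalysis' standard
    element table.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    if format is None:
        format = _EXT_TO_FORMAT.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")

    if format == "pdb_multimodel":
        _validate_pdb_model_counts(path)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass/element guessing chatter
        u = mda.Universe(str(path))

    names = [str(n) for n in u.atoms.names]
    try:
        elements = [str(e) for e in u.atoms.elements]
    except Exception:
        elements = [n[0] for n in names]
    masses = np.asarray(u.atoms.masses, dtype=float)
    if np.any(masses <= 0):
        # unguessable elements (e.g. pseudo-atoms) get unit mass
        masses = np.where(masses > 0, masses, 1.0)
    resids = np.asarray(u.atoms.resids, dtype=int)

    atoms = [
        AtomRecord(i, names[i], elements[i], float(masses[i]), int(resids[i]))
        for i in range(len(u.atoms))
    ]
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # readers without dt guess one
        for k, ts in enumerate(u.trajectory):
            t = float(ts.time) * PS_TO_NS if ts.time is not None else 0.0
            frames.append(
                Frame(frame_index=k, time=max(t, 0.0),
                      coords=ts.positions * ANGSTROM_TO_NM)
            )
    return Trajectory(atoms, frames)


def trajectory_from_reader(
    atoms: Sequence[AtomRecord],
    reader: Callable[[], Iterable[tuple[float, np.ndarray]]],
) -> Trajectory:
    """Build a Trajectory from any callable yielding (time_ns, coords_nm) tuples.

    This is the plug-in contract for binary formats (XTC/DCD/...): the caller
    adapts their reader of choice; the core stays text-format only.
    """
    frames = [
        Frame(frame_index=k, time=float(t), coords=np.asarray(xyz, dtype=float))
        for k, (t, xyz) in enumerate(reader())
    ]
    if not frames:
        raise ValueError("reader produced no frames")
    return Trajectory(atoms, frames)


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB (nm -> A on the way out).

    Plain fixed-width records are emitted directly: the layout is simple
    and writing through a Universe would require rebuilding topology
    attributes the Trajectory does not carry.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write(f"MODEL     {f.frame_index + 1:4d}\n")
            for a, xyz in zip(traj.atoms, f.coords):
                x, y, z = xyz / ANGSTROM_TO_NM
                name = a.atom_name[:4]
                # columns per PDB v3.3 ATOM record
                fh.write(
                    f"ATOM  {a.atom_index + 1:5d} {name:<4s} RES A{a.residue_id:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                    f"{a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def residue_center_of_mass(
    frame: Frame,
    residue_atoms: Iterable[int],
    atoms: Sequence[AtomRecord],
) -> np.ndarray:
    """Mass-weighted mean position (nm) of a group of atoms in one frame."""
    idx = np.fromiter(residue_atoms, dtype=int)
    if idx.size == 0:
        raise ValueError("empty atom selection for centre of mass")
    masses = np.array([atoms[i].mass for i in idx])
    xyz = frame.coords[idx]
    return masses @ xyz / masses.sum()


def slice_trajectory(traj: Trajectory, skip_fraction: float, stride: int) -> Trajectory:
    """Drop an initial equilibration fraction, then subsample by stride.

    The first ``ceil(skip_fraction * n_frames)`` frames are removed and
    every ``stride``-th remaining frame kept, preserving order and all
    atom metadata.  Expressing equilibration as a fraction (default use:
    0.05, the analogue of skipping 0.1 us of a 2 us run) makes the rule
    length-independent.
    """
    if not 0 <= skip_fraction < 1:
        raise ValueError(f"skip_fraction must be in [0, 1), got {skip_fraction}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    n = traj.n_frames
    start = int(np.ceil(skip_fraction * n))
    kept = traj.frames[start::stride]
    if not kept:
        raise ValueError(
            f"slicing with skip_fraction={skip_fraction}, stride={stride} "
            f"leaves no frames (had {n})"
        )
    return Trajectory(traj.atoms, kept)
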