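"""GROMOS clustering and ensemble summaries.

GROMOS clustering is the greedy neighbour-count algorithm: given the
pairwise RMSD matrix over the dye-atom selection, repeatedly take the
frame with the most neighbours within the cutoff (ties broken by lowest
frame index), form a cluster of it and its neighbours, remove them, and
continue until no frames remain.  Clusters holding more than a minimum
fraction of all frames (default 5%) are retained; smaller ones are
treated as transition states and discarded.

Two ensemble summaries are produced for each metric and for J_mn:

* time_series — mean and population standard deviation over all frames;
* gromos — geometry averaged within each retained cluster (centres and
  bridge endpoints averaged, mean dipole directions renormalised), the
  metrics and coupling evaluated on each cluster-average geometry, and
  mean/sd taken across the cluster values (unweighted by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coupling import CouplingParameters, extended_dipole_coupling
from .dyes import DyeParameters, ExtendedDipole, extract_extended_dipole
from .orientation import dimer_geometry
from .trajectory import SelectionConfig, Trajectory

__all__ = [
    "Cluster",
    "ClusterSet",
    "EnsembleSummary",
    "Histogram2D",
    "pairwise_rmsd",
    "gromos_cluster",
    "filter_clusters",
    "time_series_summary",
    "gromos_summary",
    "histogram2d",
    "summary_table",
]

DEFAULT_RMSD_CUTOFF_NM = 0.05
DEFAULT_MIN_CLUSTER_FRACTION = 0.05

METRIC_NAMES = ("R", "alpha", "theta_m", "theta_n", "kappa_sq", "kappa_prime", "J_mn")


# ---------------------------------------------------------------------------
# Pairwise RMSD
# ---------------------------------------------------------------------------


def pairwise_rmsd(
    traj: Trajectory,
    atom_selection: list[int] | np.ndarray,
    superpose: bool = True,
) -> np.ndarray:
    """All-pairs RMSD (nm) over a selection, optionally after superposition.

    RMSD(i, j) = sqrt(mean over selected atoms of |x_i - x_j|^2), with
    frame j optimally rotated/translated onto frame i over the same
    selection (unweighted Kabsch) when ``superpose`` is true.

    The superposed branch never materialises rotated coordinates: with
    both frames centred, rmsd^2 = (|X|^2 + |Y|^2 - 2 tr Sigma') / n
    where tr Sigma' is the reflection-corrected sum of singular values
    of the covariance X^T Y.  The SVDs are evaluated in row-batches, so
    the cost is n_frames batched 3x3 SVD calls.
    """
    idx = np.asarray(atom_selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty atom selection for RMSD")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for a pairwise RMSD matrix")
    X = traj.coords_array()[:, idx, :]  # (F, A, 3)
    F, A, _ = X.shape
    out = np.zeros((F, F))

    if not superpose:
        # ||x_i - x_j||^2 = |x_i|^2 + |x_j|^2 - 2 x_i.x_j, summed over atoms
        flat = X.reshape(F, -1)
        sq = np.einsum("ij,ij->i", flat, flat)
        g = flat @ flat.T
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * g, 0.0)
        out = np.sqrt(d2 / A)
        np.fill_diagonal(out, 0.0)
        return out

    Xc = X - X.mean(axis=1, keepdims=True)
    sq = np.einsum("fij,fij->f", Xc, Xc)
    for i in range(F - 1):
        Y = Xc[i + 1 :]  # (B, A, 3)
        H = np.einsum("am,ban->bmn", Xc[i], Y)  # covariance per pair
        U, S, Vt = np.linalg.svd(H)
        det = np.linalg.det(U @ Vt)
        S_corr = S[:, 0] + S[:, 1] + np.sign(det) * S[:, 2]
        d2 = np.maximum(sq[i] + sq[i + 1 :] - 2 * S_corr, 0.0)
        out[i, i + 1 :] = np.sqrt(d2 / A)
    out = out + out.T
    return out


# ---------------------------------------------------------------------------
# GROMOS clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cluster:
    center_frame: int
    member_frames: frozenset[int]
    fraction: float

    def __post_init__(self) -> None:
        if self.center_frame not in self.member_frames:
            raise ValueError("cluster centre must be a member")


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    n_frames_total: int
    discarded_fraction: float = 0.0

    def fractions(self) -> list[float]:
        return [c.fraction for c in self.clusters]

    def assignments(self) -> pd.DataFrame:
        rows = []
        for k, c in enumerate(self.clusters):
            for f in sorted(c.member_frames):
                rows.append({"frame_index": f, "cluster": k, "is_center": f == c.center_frame})
        return pd.DataFrame(rows).sort_values("frame_index").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.clusters)


def gromos_cluster(m: np.ndarray, cutoff: float = DEFAULT_RMSD_CUTOFF_NM) -> ClusterSet:
    """Greedy neighbour-count clustering of an RMSD matrix.

    Ties in the neighbour count are broken toward the lowest frame
    index, making the procedure fully deterministic.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("RMSD matrix must be square")
    n = m.shape[0]
    neighbors = m <= cutoff
    np.fill_diagonal(neighbors, True)
    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any():
        counts = (neighbors & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the first (lowest) index on ties
        members = np.flatnonzero(neighbors[center] & remaining)
        clusters.append(
            Cluster(
                center_frame=center,
                member_frames=frozenset(int(x) for x in members),
                fraction=members.size / n,
            )
        )
        remaining[members] = False
    return ClusterSet(clusters=clusters, n_frames_total=n)


def filter_clusters(
    cs: ClusterSet, min_fraction: float = DEFAULT_MIN_CLUSTER_FRACTION
) -> ClusterSet:
    """Retain clusters holding strictly more than ``min_fraction`` of frames."""
    kept = [c for c in cs.clusters if c.fraction > min_fraction]
    if not kept:
        raise ValueError(
            f"all {len(cs.clusters)} clusters are at or below the {min_fraction:.0%} "
            "fraction; review the RMSD cutoff"
        )
    discarded = sum(c.fraction for c in cs.clusters if c.fraction <= min_fraction)
    return ClusterSet(
        clusters=kept,
        n_frames_total=cs.n_frames_total,
        discarded_fraction=discarded,
    )


# ---------------------------------------------------------------------------
# Ensemble summaries
# ---------------------------------------------------------------------------


@dataclass
class EnsembleSummary:
    """Mean +/- sd of each metric, tagged by estimation method."""

    method: str  # "time_series" | "gromos"
    stats: dict[str, tuple[float, float]]  # metric -> (mean, sd)

    def __post_init__(self) -> None:
        for name, (_, sd) in self.stats.items():
            if sd < 0:
                raise ValueError(f"negative sd for {name}")


def time_series_summary(values) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation of a series."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    return float(v.mean()), float(v.std(ddof=0))


def _average_dipole(dipoles: list[ExtendedDipole]) -> ExtendedDipole:
    """Cluster-average geometry: mean positions, renormalised mean direction."""
    c = np.mean([d.center for d in dipoles], axis=0)
    r = np.mean([d.r for d in dipoles], axis=0)
    s = np.mean([d.s for d in dipoles], axis=0)
    mu = np.mean([d.mu_hat for d in dipoles], axis=0)
    norm = np.linalg.norm(mu)
    if norm < 1e-6:
        raise ValueError(
            "mean dipole direction nearly vanishes over the cluster; the cluster "
            "mixes opposing orientations and has no meaningful average geometry"
        )
    return ExtendedDipole(
        center=c,
        mu_hat=mu / norm,
        r=r,
        s=s,
        length=float(np.linalg.norm(r - s)),
        mu_mag=dipoles[0].mu_mag,
    )


def gromos_summary(
    cs: ClusterSet,
    traj: Trajectory,
    sel: SelectionConfig,
    params: DyeParameters,
    dye_m: str,
    dye_n: str,
    coupling_params: CouplingParameters = CouplingParameters(),
    fold: str = "as_printed",
    weighted: bool = False,
) -> tuple[EnsembleSummary, pd.DataFrame]:
    """Per-cluster average geometries, their metrics/coupling, and the summary.

    Returns the method-tagged summary plus a per-cluster table.  With
    ``weighted`` the across-cluster mean/sd are weighted by cluster
    fraction instead of unweighted.
    """
    if not cs.clusters:
        raise ValueError("empty cluster set")
    if cs.n_frames_total != traj.n_frames:
        raise ValueError(
            f"cluster set built on {cs.n_frames_total} frames but trajectory "
            f"has {traj.n_frames}"
        )
    per_cluster: dict[str, list[float]] = {k: [] for k in METRIC_NAMES}
    rows = []
    for k, cluster in enumerate(cs.clusters):
        # member indices are positions in the clustered trajectory
        dm = _average_dipole(
            [
                extract_extended_dipole(traj.frames[i], sel, params, dye_m)
                for i in sorted(cluster.member_frames)
            ]
        )
        dn = _average_dipole(
            [
                extract_extended_dipole(traj.frames[i], sel, params, dye_n)
                for i in sorted(cluster.member_frames)
            ]
        )
        g = dimer_geometry(dm, dn, frame_index=cluster.center_frame, fold=fold)
        J = extended_dipole_coupling(dm, dn, coupling_params).J_mn
        values = {
            "R": g.R,
            "alpha": g.alpha,
            "theta_m": g.theta_m,
            "theta_n": g.theta_n,
            "kappa_sq": g.kappa_sq,
            "kappa_prime": g.kappa_prime,
            "J_mn": J,
        }
        for name, v in values.items():
            per_cluster[name].append(v)
        rows.append({"cluster": k, "fraction": cluster.fraction, **values})
    w = np.array([c.fraction for c in cs.clusters])
    w = w / w.sum() if weighted else np.full(len(cs.clusters), 1.0 / len(cs.clusters))
    stats = {}
    for name, vals in per_cluster.items():
        v = np.asarray(vals)
        mean = float(w @ v)
        stats[name] = (mean, float(np.sqrt(w @ (v - mean) ** 2)))
    return EnsembleSummary(method="gromos", stats=stats), pd.DataFrame(rows)


def summary_table(summaries: list[EnsembleSummary]) -> pd.DataFrame:
    """Long-form table: one row per (method, metric)."""
    rows = []
    for s in summaries:
        for metric, (mean, sd) in s.stats.items():
            rows.append({"method": s.method, "metric": metric, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 2D histograms
# ---------------------------------------------------------------------------


@dataclass
class Histogram2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    x_label: str = "x"
    y_label: str = "y"

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i in range(self.counts.shape[0]):
            for j in range(self.counts.shape[1]):
                rows.append(
                    {
                        "x_low": self.x_edges[i],
                        "x_high": self.x_edges[i + 1],
                        "y_low": self.y_edges[j],
                        "y_high": self.y_edges[j + 1],
                        "count": int(self.counts[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def histogram2d(
    x,
    y,
    bins: int | tuple = 50,
    x_label: str = "x",
    y_label: str = "y",
) -> Histogram2D:
    """Joint histogram of two per-frame series (count-preserving)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"series lengths differ: {x.shape} vs {y.shape}")
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    return Histogram2D(x_edges=xe, y_edges=ye, counts=counts, x_label=x_label, y_label=y_label)
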