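"""3D structure analyses: clusters, purity, rosettograms, f_d, R_g.

Clusters are single-linkage connected components of the "within cutoff"
graph under minimum-image distances (two particles belong to one cluster
if a chain of sub-cutoff links connects them).  The conventional cutoff is
3 sigma (90 nm for 30 nm beads).  Following the field's convention a
"cluster" has at least two members; singletons are counted when reporting
the fraction of particles in clusters.

A rosettogram has one row per cluster and one column per high-affinity
bead in fiber order; a filled pixel marks that bead's presence in the
cluster, and runs of abutting pixels in a row are loops ("petals") of a
rosette around one cluster.  The disorganized fraction f_d is the fraction
of high-affinity beads that do not share a cluster with either of their
nearest-neighbor high-affinity beads along the fiber — low f_d means
rosette-like, locally organized folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .engine import Trajectory

__all__ = [
    "ClusterSet",
    "Rosettogram",
    "find_clusters",
    "cluster_timeseries",
    "cluster_purity",
    "rosettogram",
    "disorganized_fraction",
    "radius_of_gyration",
]

#: conventional clustering cutoff: 3 sigma = 90 nm for 30 nm beads
DEFAULT_CLUSTER_CUTOFF = 3.0


def _wrap(p: np.ndarray, L: float) -> np.ndarray:
    w = np.mod(p, L)
    w[w >= L] -= L  # guard against w == L from rounding
    return w


def _min_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


@dataclass
class ClusterSet:
    """Single-linkage clustering of one snapshot's participant set.

    ``participants`` are global particle ids; ``labels`` the component
    label of each participant.  ``colors`` (optional) carries one color
    label per participant for purity and rosettogram coloring.
    """

    time: float
    participants: np.ndarray
    labels: np.ndarray
    cutoff: float
    colors: list[str] | None = None

    def clusters(self, min_size: int = 2) -> list[np.ndarray]:
        """Member *positions within participants* per cluster, size >= min_size,
        ordered by smallest member id."""
        out = []
        for lab in np.unique(self.labels):
            idx = np.nonzero(self.labels == lab)[0]
            if len(idx) >= min_size:
                out.append(idx)
        out.sort(key=lambda idx: int(self.participants[idx].min()))
        return out

    def sizes(self, min_size: int = 2) -> np.ndarray:
        return np.array([len(c) for c in self.clusters(min_size)], dtype=int)

    def mean_size(self) -> float:
        """Mean size over clusters of >= 2; 1.0 when everything is a singleton."""
        s = self.sizes()
        return float(s.mean()) if len(s) else 1.0

    def fraction_clustered(self) -> float:
        s = self.sizes()
        return float(s.sum() / len(self.participants)) if len(self.participants) else 0.0


def find_clusters(
    positions: np.ndarray,
    box_edge: float,
    cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    participants: np.ndarray | None = None,
    time: float = 0.0,
    colors: list[str] | None = None,
) -> ClusterSet:
    """Single-linkage clusters of ``participants`` at strict distance < cutoff.

    ``positions`` holds all particle coordinates (unwrapped or wrapped);
    ``participants`` selects the subset to cluster (default: everything).
    """
    if cutoff >= box_edge / 2:
        raise ValueError("cutoff must be below half the box edge")
    if participants is None:
        participants = np.arange(len(positions))
    participants = np.asarray(participants, dtype=int)
    p = _wrap(np.asarray(positions, dtype=float)[participants], box_edge)
    n = len(p)
    labels = np.arange(n)
    if n:
        tree = cKDTree(p, boxsize=box_edge)
        pairs = np.array(sorted(tree.query_pairs(cutoff)), dtype=int).reshape(-1, 2)
        if len(pairs):
            d = np.linalg.norm(_min_image(p[pairs[:, 0]] - p[pairs[:, 1]],
                                          box_edge), axis=1)
            pairs = pairs[d < cutoff]  # strict inequality
        if len(pairs):
            m = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                           shape=(n, n))
            _, labels = connected_components(m, directed=False)
    return ClusterSet(time=time, participants=participants, labels=labels,
                      cutoff=cutoff, colors=colors)


def cluster_timeseries(
    traj: Trajectory,
    participants: np.ndarray,
    cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    steady_fraction: float = 0.2,
) -> pd.DataFrame:
    """Mean cluster size and clustered fraction per snapshot.

    Returns a DataFrame with columns ``time``, ``mean_size``,
    ``fraction_clustered``; ``.attrs['steady']`` carries averages over the
    final ``steady_fraction`` of snapshots (the steady-state window).
    """
    if len(participants) == 0:
        raise ValueError("empty participant set")
    rows = []
    for f in range(traj.n_frames):
        cs = find_clusters(traj.positions[f].astype(float), traj.box_edge,
                           cutoff, participants, time=traj.times[f])
        rows.append((traj.times[f], cs.mean_size(), cs.fraction_clustered()))
    df = pd.DataFrame(rows, columns=["time", "mean_size", "fraction_clustered"])
    n_last = max(1, int(np.ceil(steady_fraction * len(df))))
    tail = df.iloc[-n_last:]
    df.attrs["steady"] = {
        "mean_size": float(tail["mean_size"].mean()),
        "fraction_clustered": float(tail["fraction_clustered"].mean()),
    }
    return df


def cluster_purity(clusterset: ClusterSet) -> pd.DataFrame:
    """Per-cluster color purity plus summary fractions.

    Purity = (count of the dominant color) / (cluster size), over clusters
    of >= 2.  ``.attrs['summary']`` reports the fraction of pure clusters
    (purity == 1) and the fraction with purity >= 0.8.
    """
    if clusterset.colors is None:
        raise ValueError("clusterset carries no colors")
    colors = np.asarray(clusterset.colors)
    rows = []
    for idx in clusterset.clusters(min_size=2):
        vals, counts = np.unique(colors[idx], return_counts=True)
        k = int(np.argmax(counts))
        rows.append((len(idx), vals[k], counts[k] / len(idx)))
    df = pd.DataFrame(rows, columns=["size", "dominant_color", "purity"])
    if len(df):
        summary = {
            "fraction_pure": float((df["purity"] == 1.0).mean()),
            "fraction_ge80": float((df["purity"] >= 0.8).mean()),
        }
    else:
        summary = {"fraction_pure": float("nan"), "fraction_ge80": float("nan")}
    df.attrs["summary"] = summary
    return df


@dataclass
class Rosettogram:
    """Cluster x high-affinity-bead incidence matrix.

    ``matrix[r, c] == 0`` marks absence; a positive value marks presence,
    the value being 1 + the index of the coloring species (so single-species
    rosettograms are 0/1).  ``bead_ids`` gives the column -> bead mapping in
    fiber order.  ``f_d`` is the disorganized fraction.
    """

    matrix: np.ndarray
    bead_ids: np.ndarray
    f_d: float
    color_names: list[str] = field(default_factory=lambda: ["bound"])

    @property
    def n_clusters(self) -> int:
        return self.matrix.shape[0]

    def petals_per_row(self) -> np.ndarray:
        """Number of runs of abutting pixels in each row."""
        out = []
        for row in self.matrix:
            filled = row > 0
            out.append(int(np.sum(filled[1:] & ~filled[:-1]) + (1 if filled[0] else 0)))
        return np.array(out, dtype=int)

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.matrix, columns=self.bead_ids).to_csv(
            path, sep="\t", index_label="cluster"
        )


def disorganized_fraction(clusterset: ClusterSet, binding_beads: np.ndarray) -> float:
    """Fraction of high-affinity beads not co-clustered with a fiber neighbor.

    ``binding_beads`` lists the high-affinity bead ids in fiber order; the
    clusterset must have been computed over (at least) those beads.  A bead
    counts as organized if it shares a cluster (size >= 2) with the previous
    or the next binding bead along the fiber.
    """
    binding_beads = np.asarray(binding_beads, dtype=int)
    if len(binding_beads) < 2:
        raise ValueError("need at least two high-affinity beads")
    id2pos = {int(p): i for i, p in enumerate(clusterset.participants)}
    labels = clusterset.labels
    sizes = np.bincount(labels)
    organized = 0
    for k, b in enumerate(binding_beads):
        lab = labels[id2pos[int(b)]]
        if sizes[lab] < 2:
            continue
        nbrs = []
        if k > 0:
            nbrs.append(binding_beads[k - 1])
        if k < len(binding_beads) - 1:
            nbrs.append(binding_beads[k + 1])
        if any(labels[id2pos[int(nb)]] == lab for nb in nbrs):
            organized += 1
    return 1.0 - organized / len(binding_beads)


def rosettogram(
    clusterset: ClusterSet,
    binding_beads: np.ndarray,
    factor_positions: np.ndarray | None = None,
    factor_species: np.ndarray | None = None,
    all_positions: np.ndarray | None = None,
    box_edge: float | None = None,
    attraction_range: float = 1.8,
    color_names: list[str] | None = None,
) -> Rosettogram:
    """Build the rosettogram of one snapshot's binding-bead clusters.

    When several factor species are present, each pixel takes the color of
    the nearest bound factor within ``attraction_range`` of the bead (ties
    broken toward the smaller species index); otherwise pixels are binary.
    """
    binding_beads = np.asarray(binding_beads, dtype=int)
    id2pos = {int(p): i for i, p in enumerate(clusterset.participants)}
    clusters = [c for c in clusterset.clusters(min_size=2)]
    # keep clusters containing at least one binding bead; order rows by the
    # first (fiber-order) binding bead they contain
    bead_set = set(int(b) for b in binding_beads)
    col_of = {int(b): c for c, b in enumerate(binding_beads)}
    rows = []
    for idx in clusters:
        ids = clusterset.participants[idx]
        cols = sorted(col_of[int(i)] for i in ids if int(i) in bead_set)
        if cols:
            rows.append(cols)
    rows.sort(key=lambda cols: cols[0])

    # per-bead color index from the nearest in-range factor
    bead_color = np.zeros(len(binding_beads), dtype=int)  # 0 -> species 0
    if factor_positions is not None and len(factor_positions) and box_edge:
        if factor_species is None:
            factor_species = np.zeros(len(factor_positions), dtype=int)
        bp = _wrap(np.asarray(all_positions, dtype=float)[binding_beads], box_edge)
        fp = _wrap(np.asarray(factor_positions, dtype=float), box_edge)
        tree = cKDTree(fp, boxsize=box_edge)
        for c, p in enumerate(bp):
            hits = tree.query_ball_point(p, attraction_range)
            if hits:
                d = np.linalg.norm(_min_image(fp[hits] - p, box_edge), axis=1)
                order = np.lexsort((factor_species[hits], d))
                bead_color[c] = int(factor_species[np.array(hits)[order[0]]])
    matrix = np.zeros((len(rows), len(binding_beads)), dtype=int)
    for r, cols in enumerate(rows):
        for c in cols:
            matrix[r, c] = 1 + bead_color[c]
    f_d = disorganized_fraction(clusterset, binding_beads)
    return Rosettogram(matrix=matrix, bead_ids=binding_beads, f_d=f_d,
                       color_names=color_names or ["bound"])


def radius_of_gyration(traj: Trajectory, subset: np.ndarray | None = None) -> pd.DataFrame:
    """R_g time series over a bead subset (default: all beads).

    Uses the trajectory's unwrapped coordinates; R_g of coordinates folded
    into the box would be meaningless for a fiber larger than the box.
    """
    if subset is None:
        subset = np.arange(traj.n_beads)
    subset = np.asarray(subset, dtype=int)
    rgs = []
    for f in range(traj.n_frames):
        p = traj.positions[f, subset].astype(float)
        com = p.mean(axis=0)
        rgs.append(float(np.sqrt(((p - com) ** 2).sum(axis=1).mean())))
    df = pd.DataFrame({"time": traj.times, "rg": rgs})
    n_last = max(2, len(df) // 4)
    tail = df.iloc[-n_last:]
    mean = float(tail["rg"].mean())
    # drift = linear trend over the final quarter, as a fraction of the mean
    if mean > 0 and len(tail) > 2:
        slope = np.polyfit(tail["time"], tail["rg"], 1)[0]
        drift = abs(slope) * (tail["time"].iloc[-1] - tail["time"].iloc[0]) / mean
    else:
        drift = 0.0
    df.attrs["steady"] = {"mean": mean, "drift": float(drift)}
    return df
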