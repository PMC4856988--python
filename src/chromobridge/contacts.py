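"""Hi-C-style contact maps, P(s) scaling and domain-boundary calling.

A contact is scored between two beads whose centers lie within a threshold
distance (convention: 5 sigma = 150 nm; the high-resolution variant uses
3 sigma = 90 nm without binning), counted per snapshot and aggregated over
a trajectory.  Contacts of ``bin_beads`` adjacent beads are pooled into
bins (convention: 40 beads).

Boundary detection works on the "Janus" signals: for each bin, the total
contacts it makes to the left and to the right within a window.  Their
difference crosses zero with positive slope at a domain boundary; the peaks
of the difference's derivative form the sharper "insulation" signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .engine import Trajectory
from .structure import DEFAULT_CLUSTER_CUTOFF, find_clusters

__all__ = [
    "ContactMap",
    "BoundarySet",
    "ScalingFit",
    "contact_map",
    "contact_probability",
    "fit_scaling",
    "janus_profiles",
    "difference_plot",
    "insulation_signal",
    "find_boundaries",
    "boundary_concordance",
    "permutation_null",
    "inter_fiber_contact_fraction",
]

#: default contact threshold, sigma (150 nm at 30 nm/bead)
DEFAULT_CONTACT_THRESHOLD = 5.0
#: high-resolution threshold, sigma (90 nm)
HIRES_CONTACT_THRESHOLD = 3.0


def _wrap(p: np.ndarray, L: float) -> np.ndarray:
    w = np.mod(p, L)
    w[w >= L] -= L
    return w


@dataclass
class ContactMap:
    """Symmetric binned contact-count matrix with its provenance."""

    matrix: np.ndarray
    bin_beads: int
    threshold: float  # sigma
    n_snapshots: int
    n_beads: int
    bead_bp: int | None = None  # genomic bp per bead, when known
    start_bp: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("contact matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("contact counts must be nonnegative")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def total_contacts(self) -> float:
        return float(self.matrix.sum())

    def bin_to_bead(self, b: int | np.ndarray):
        return np.asarray(b) * self.bin_beads

    def save_tsv(self, path: str) -> None:
        header = (f"# chromobridge contact map\n"
                  f"# bin_beads={self.bin_beads} threshold_sigma={self.threshold} "
                  f"n_snapshots={self.n_snapshots} n_beads={self.n_beads} "
                  f"bead_bp={self.bead_bp or 0} start_bp={self.start_bp}\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.matrix, fmt="%.6g", delimiter="\t")

    @classmethod
    def load_tsv(cls, path: str) -> "ContactMap":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = float(v)
        matrix = np.loadtxt(path, comments="#", delimiter="\t")
        return cls(
            matrix=matrix,
            bin_beads=int(meta.get("bin_beads", 1)),
            threshold=float(meta.get("threshold_sigma", DEFAULT_CONTACT_THRESHOLD)),
            n_snapshots=int(meta.get("n_snapshots", 1)),
            n_beads=int(meta.get("n_beads", matrix.shape[0])),
            bead_bp=int(meta["bead_bp"]) or None if "bead_bp" in meta else None,
            start_bp=int(meta.get("start_bp", 0)),
        )


def _frame_contact_pairs(p: np.ndarray, L: float, threshold: float) -> np.ndarray:
    tree = cKDTree(_wrap(p, L), boxsize=L)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    return pairs


def contact_map(
    traj: Trajectory,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    bin_beads: int = 40,
    frames: np.ndarray | None = None,
    bead_bp: int | None = None,
) -> ContactMap:
    """Aggregate bead–bead contacts over snapshots into a binned map.

    Every bead pair (i < j) with minimum-image distance <= threshold adds
    one count to its bin pair (both triangles; intra-bin pairs land on the
    diagonal once).  ``frames`` restricts aggregation to a snapshot subset,
    e.g. the steady-state window.
    """
    if threshold >= traj.box_edge / 2:
        raise ValueError("contact threshold must be below half the box edge")
    if bin_beads < 1:
        raise ValueError("bin_beads must be >= 1")
    nb = traj.n_beads
    n_bins = (nb + bin_beads - 1) // bin_beads
    m = np.zeros((n_bins, n_bins))
    frame_ids = range(traj.n_frames) if frames is None else frames
    count = 0
    for f in frame_ids:
        p = traj.positions[f, :nb].astype(float)
        pairs = _frame_contact_pairs(p, traj.box_edge, threshold)
        count += 1
        if len(pairs) == 0:
            continue
        bi = pairs[:, 0] // bin_beads
        bj = pairs[:, 1] // bin_beads
        np.add.at(m, (bi, bj), 1.0)
        off = bi != bj
        np.add.at(m, (bj[off], bi[off]), 1.0)
    # symmetrize diagonal convention: diagonal already counts each intra-bin
    # pair once; off-diagonal counts appear in both triangles.
    return ContactMap(matrix=m, bin_beads=bin_beads, threshold=threshold,
                      n_snapshots=count, n_beads=nb, bead_bp=bead_bp)


def contact_probability(
    traj: Trajectory,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    frames: np.ndarray | None = None,
    fiber: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """P(s): mean contact frequency vs bead separation along one fiber.

    Returns ``(s, P)`` for s = 1..n-1, with P(s) = contacts at separation s
    divided by (number of bead pairs at that separation x snapshots).
    """
    a, b = fiber if fiber is not None else (0, traj.n_beads)
    n = b - a
    counts = np.zeros(n, dtype=float)
    frame_ids = range(traj.n_frames) if frames is None else frames
    nf = 0
    for f in frame_ids:
        p = traj.positions[f, a:b].astype(float)
        pairs = _frame_contact_pairs(p, traj.box_edge, threshold)
        nf += 1
        if len(pairs):
            s = np.abs(pairs[:, 1] - pairs[:, 0])
            np.add.at(counts, s, 1.0)
    s = np.arange(1, n)
    norm = (n - s).astype(float) * max(nf, 1)
    return s, counts[1:] / norm


@dataclass(frozen=True)
class ScalingFit:
    """Power-law fit P(s) ~ s^alpha over a separation range."""

    alpha: float
    stderr: float
    s_min: int
    s_max: int
    regime: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha):
            raise ValueError("non-finite exponent")
        if self.s_min >= self.s_max:
            raise ValueError("s_min must be below s_max")


def fit_scaling(s: np.ndarray, p: np.ndarray, s_range: tuple[float, float],
                regime: str = "") -> ScalingFit:
    """Least-squares log-log fit of the contact-probability decay exponent.

    Requires at least three strictly positive P values in the range and a
    non-degenerate decay; a flat/step P(s) (e.g. a rigid rod) is rejected
    with a diagnostic.
    """
    s = np.asarray(s, dtype=float)
    p = np.asarray(p, dtype=float)
    mask = (s >= s_range[0]) & (s <= s_range[1]) & (p > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"cannot fit scaling on [{s_range[0]}, {s_range[1]}]: "
            f"only {int(mask.sum())} positive P(s) points"
        )
    x = np.log(s[mask])
    y = np.log(p[mask])
    if np.ptp(y) < 1e-12:
        raise ValueError("degenerate P(s): no decay over the fit range")
    (alpha, _), cov = np.polyfit(x, y, 1, cov=True)
    return ScalingFit(alpha=float(alpha), stderr=float(np.sqrt(cov[0, 0])),
                      s_min=int(s_range[0]), s_max=int(s_range[1]),
                      regime=regime)


# ---------------------------------------------------------------------------
# boundary detection

def janus_profiles(cmap: ContactMap | np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin contact sums to the left and to the right within a window."""
    m = cmap.matrix if isinstance(cmap, ContactMap) else np.asarray(cmap, float)
    n = m.shape[0]
    if window < 1 or window > n:
        raise ValueError("window must be between 1 and the map size")
    left = np.zeros(n)
    right = np.zeros(n)
    for i in range(n):
        left[i] = m[i, max(0, i - window): i].sum()
        right[i] = m[i, i + 1: min(n, i + 1 + window)].sum()
    return left, right


def difference_plot(cmap: ContactMap | np.ndarray, window: int) -> np.ndarray:
    """Janus difference signal: contacts to the right minus to the left."""
    left, right = janus_profiles(cmap, window)
    return right - left


def _smooth(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return x
    kernel = np.ones(k) / k
    return np.convolve(x, kernel, mode="same")


def insulation_signal(difference: np.ndarray) -> np.ndarray:
    """First derivative of the difference plot (the 'insulator' signal)."""
    return np.gradient(difference)


@dataclass
class BoundarySet:
    """Sorted, deduplicated boundary positions with method provenance."""

    positions: np.ndarray  # bead units unless bead_bp set on creation
    method: str
    window: int
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        order = np.argsort(pos)
        pos = pos[order]
        keep = np.ones(len(pos), dtype=bool)
        keep[1:] = np.diff(pos) > 0
        self.positions = pos[keep]
        scores = np.asarray(self.scores, dtype=float)
        if len(scores) == len(pos):
            self.scores = scores[order][keep]

    def __len__(self) -> int:
        return len(self.positions)

    def to_bed(self, path: str, chrom: str = "fiber", bead_bp: int = 1,
               start_bp: int = 0) -> None:
        with open(path, "w") as fh:
            for k, p in enumerate(self.positions):
                bp = start_bp + int(p * bead_bp)
                score = self.scores[k] if len(self.scores) == len(self.positions) else 0.0
                fh.write(f"{chrom}\t{bp}\t{bp + 1}\tboundary_{k}\t{score:.4g}\n")


def find_boundaries(
    cmap: ContactMap,
    method: str = "difference-zero-crossing",
    window: int | None = None,
    smooth_bins: int = 5,
) -> BoundarySet:
    """Call domain boundaries on a binned contact map.

    ``difference-zero-crossing``: bins where the (smoothed) Janus
    difference crosses zero with positive slope.  ``insulation-peak``:
    local maxima of the derivative of the difference.  Positions are
    returned in bead units (bin edge closest to the crossing).
    """
    if method not in ("difference-zero-crossing", "insulation-peak"):
        raise ValueError(f"unknown boundary method {method!r}")
    n = cmap.n_bins
    if window is None:
        window = max(1, min(n // 4, max(1, 100 // cmap.bin_beads)))
    diff = _smooth(difference_plot(cmap, window), smooth_bins)
    positions = []
    scores = []
    if method == "difference-zero-crossing":
        for i in range(n - 1):
            if diff[i] < 0 <= diff[i + 1]:
                slope = diff[i + 1] - diff[i]
                # linear interpolation of the crossing inside [i, i+1]
                frac = -diff[i] / slope if slope > 0 else 0.5
                positions.append((i + frac + 0.5) * cmap.bin_beads)
                scores.append(slope)
    else:
        insul = insulation_signal(diff)
        peaks, props = find_peaks(insul, height=0.0)
        for p, h in zip(peaks, props["peak_heights"]):
            positions.append((p + 0.5) * cmap.bin_beads)
            scores.append(float(h))
    return BoundarySet(positions=np.array(positions), method=method,
                       window=window, scores=np.array(scores))


def boundary_concordance(
    predicted: BoundarySet | np.ndarray,
    reference: BoundarySet | np.ndarray,
    tolerance: float,
) -> float:
    """Fraction of reference boundaries recovered by the predicted set.

    Greedy nearest-first one-to-one matching: candidate pairs are matched
    in order of increasing distance, each boundary used at most once, and
    a pair counts when its distance is within ``tolerance`` (same units as
    the positions).
    """
    a = predicted.positions if isinstance(predicted, BoundarySet) else np.asarray(predicted, float)
    b = reference.positions if isinstance(reference, BoundarySet) else np.asarray(reference, float)
    if len(b) == 0:
        raise ValueError("empty reference boundary set")
    if len(a) == 0:
        return 0.0
    d = np.abs(a[:, None] - b[None, :])
    cand = [(d[i, j], i, j) for i in range(len(a)) for j in range(len(b))
            if d[i, j] <= tolerance]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = 0
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched += 1
    return matched / len(b)


def permutation_null(
    reference: BoundarySet | np.ndarray,
    n_boundaries: int,
    span: float,
    tolerance: float,
    n_perm: int = 200,
    seed: int = 0,
) -> float:
    """Mean concordance of randomly placed boundary sets of the same size."""
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_perm):
        rand = rng.uniform(0, span, size=n_boundaries)
        vals.append(boundary_concordance(rand, reference, tolerance))
    return float(np.mean(vals))


def inter_fiber_contact_fraction(
    traj: Trajectory,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    binding_beads: np.ndarray | None = None,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    frames: np.ndarray | None = None,
) -> dict[str, float]:
    """Fraction of contacts joining different fibers.

    Returns the fraction over all bead contacts and, when ``binding_beads``
    is given, over contacts made by binding beads that are currently in
    clusters (size >= 2 at ``cluster_cutoff``).
    """
    if len(traj.fiber_slices) < 2:
        raise ValueError("need at least two fibers")
    fiber_of = np.empty(traj.n_beads, dtype=int)
    for k, (a, b) in enumerate(traj.fiber_slices):
        fiber_of[a:b] = k
    frame_ids = range(traj.n_frames) if frames is None else frames
    tot_all = inter_all = 0
    tot_cl = inter_cl = 0
    for f in frame_ids:
        p = traj.positions[f, : traj.n_beads].astype(float)
        pairs = _frame_contact_pairs(p, traj.box_edge, threshold)
        if len(pairs) == 0:
            continue
        cross = fiber_of[pairs[:, 0]] != fiber_of[pairs[:, 1]]
        tot_all += len(pairs)
        inter_all += int(cross.sum())
        if binding_beads is not None:
            cs = find_clusters(traj.positions[f].astype(float), traj.box_edge,
                               cluster_cutoff, participants=binding_beads)
            sizes = np.bincount(cs.labels)
            in_cluster = set(
                int(b) for b, lab in zip(cs.participants, cs.labels)
                if sizes[lab] >= 2
            )
            sel = np.array(
                [pi in in_cluster and pj in in_cluster
                 for pi, pj in pairs], dtype=bool,
            )
            tot_cl += int(sel.sum())
            inter_cl += int((cross & sel).sum())
    out = {"all_beads": inter_all / tot_all if tot_all else 0.0}
    if binding_beads is not None:
        out["clustered_binding_beads"] = inter_cl / tot_cl if tot_cl else 0.0
    return out
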