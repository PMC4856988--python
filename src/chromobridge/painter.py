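"""Genome annotation -> bead colors ("painting"), plus synthetic annotation.

Beads covering ``bead_bp`` of genome are colored from a ChromHMM-style
state track and a GC-content track:

* pink  — at least 90 bp of active-promoter/strong-enhancer states (1, 4, 5)
* light-green — at least 90 bp of transcriptional transition/elongation
  states (9, 10)
* gray  — GC fraction strictly below a threshold (or, without a GC track,
  at least 90 bp of state 13, generic heterochromatin)
* blue  — none of the above (non-binding)

One bead may carry several colors (e.g. pink and gray), and multi-color
beads keep all their affinities downstream.  The 90 bp rule pools the
total overlap of the qualifying state group within the bead by default;
``overlap_mode="contiguous"`` instead requires a single interval to
contribute 90 bp.  Coordinates are 0-based half-open (BED convention)
throughout; bead i covers [start + i*bead_bp, start + (i+1)*bead_bp).

The synthetic-annotation generator emits tracks with prescribed marginal
bead fractions so the whole painting pipeline is testable without any
genome download.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fiber import FiberSpec, toy_fiber  # re-exported: toy fibers belong to painting

__all__ = [
    "TrackGapError",
    "StateTrack",
    "GCTrack",
    "PaintConfig",
    "paint_beads",
    "paint_to_fiber",
    "gc_fraction_windows",
    "calibrate_gc_threshold",
    "synthesize_annotation",
    "synthesize_sequence",
    "write_color_table",
    "read_color_table",
    "toy_fiber",
]

_STATE_NAME_RE = re.compile(r"^(\d+)(?:_|$)")


class TrackGapError(ValueError):
    """The painted region is not fully covered by the state track."""


@dataclass
class StateTrack:
    """ChromHMM-style state intervals: (chrom, start, end, state 1-15)."""

    intervals: pd.DataFrame  # columns chrom, start, end, state

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end", "state"])
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must have start < end")
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        self.intervals = df

    @classmethod
    def from_bed(cls, path: str) -> "StateTrack":
        """Read a 4+-column BED; the name field may be '1_Active_Promoter'
        style or a plain integer state id."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"BED line has <4 columns: {line!r}")
                m = _STATE_NAME_RE.match(parts[3])
                if not m:
                    raise ValueError(f"cannot parse state id from {parts[3]!r}")
                rows.append((parts[0], int(parts[1]), int(parts[2]),
                             int(m.group(1))))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]))

    def normalized(self) -> "StateTrack":
        """Merge abutting/overlapping same-state intervals per chromosome."""
        out = []
        for (chrom, state), g in self.intervals.groupby(["chrom", "state"]):
            g = g.sort_values("start")
            cur_s, cur_e = None, None
            for s, e in zip(g["start"], g["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e, state))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                out.append((chrom, cur_s, cur_e, state))
        return StateTrack(pd.DataFrame(out, columns=["chrom", "start", "end", "state"]))

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for r in self.intervals.itertuples():
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}\n")

    def covers(self, chrom: str, start: int, end: int) -> bool:
        sel = self.intervals[self.intervals["chrom"] == chrom]
        sel = sel[(sel["end"] > start) & (sel["start"] < end)]
        if sel.empty:
            return False
        merged_end = start
        for s, e in zip(sel["start"].sort_values(), sel.sort_values("start")["end"]):
            if s > merged_end:
                return False
            merged_end = max(merged_end, e)
            if merged_end >= end:
                return True
        return merged_end >= end


@dataclass
class GCTrack:
    """Per-bead GC fraction on the bead grid; NaN marks all-N beads."""

    values: np.ndarray
    bead_bp: int
    chrom: str = "chr"
    start: int = 0
    n_fraction: np.ndarray | None = None  # fraction of N per bead

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        ok = np.isnan(v) | ((v >= 0.0) & (v <= 1.0))
        if not ok.all():
            raise ValueError("GC fractions must lie in [0, 1] (or NaN for all-N)")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PaintConfig:
    bead_bp: int = 1000
    active_states: frozenset[int] = frozenset({1, 4, 5})
    elongation_states: frozenset[int] = frozenset({9, 10})
    heterochromatin_states: frozenset[int] = frozenset({13})
    min_overlap_bp: int = 90
    gc_threshold: float | None = None  # strict "<"; None -> use state 13
    overlap_mode: str = "pooled"  # or "contiguous"
    max_n_fraction: float = 0.5  # beads with more N than this paint blue

    def __post_init__(self) -> None:
        if self.min_overlap_bp > self.bead_bp:
            raise ValueError("min_overlap_bp cannot exceed bead_bp")
        if self.overlap_mode not in ("pooled", "contiguous"):
            raise ValueError("overlap_mode must be 'pooled' or 'contiguous'")


def _state_overlap_per_bead(
    track: StateTrack, chrom: str, start: int, n_beads: int, bead_bp: int,
    states: frozenset[int], mode: str,
) -> np.ndarray:
    """Overlap (bp) of a state group with each bead.

    ``pooled`` sums all qualifying intervals inside the bead; ``contiguous``
    takes the largest single-interval overlap (intervals are merged per
    state group first, so fragmented but abutting annotation still counts
    as one run).
    """
    sel = track.intervals
    sel = sel[(sel["chrom"] == chrom) & sel["state"].isin(states)]
    end = start + n_beads * bead_bp
    out = np.zeros(n_beads)
    # merge the group's intervals so "contiguous" means a contiguous run of
    # the group, not of a single annotation row
    merged: list[tuple[int, int]] = []
    for s, e in sorted(zip(sel["start"], sel["end"])):
        s, e = max(s, start), min(e, end)
        if s >= e:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    for s, e in merged:
        b0 = (s - start) // bead_bp
        b1 = (e - 1 - start) // bead_bp
        for b in range(b0, b1 + 1):
            ws = start + b * bead_bp
            ov = min(e, ws + bead_bp) - max(s, ws)
            if mode == "pooled":
                out[b] += ov
            else:
                out[b] = max(out[b], ov)
    return out


def paint_beads(
    track: StateTrack,
    gc: GCTrack | None,
    cfg: PaintConfig,
    chrom: str,
    start: int,
    n_beads: int,
) -> list[frozenset[str]]:
    """Color sets for ``n_beads`` beads starting at ``start`` on ``chrom``."""
    end = start + n_beads * cfg.bead_bp
    if not track.covers(chrom, start, end):
        raise TrackGapError(
            f"state track does not cover {chrom}:{start}-{end}; "
            "refusing to paint through a gap"
        )
    if gc is not None and len(gc) < n_beads:
        raise TrackGapError("GC track shorter than the painted region")
    pink = _state_overlap_per_bead(track, chrom, start, n_beads, cfg.bead_bp,
                                   cfg.active_states, cfg.overlap_mode)
    green = _state_overlap_per_bead(track, chrom, start, n_beads, cfg.bead_bp,
                                    cfg.elongation_states, cfg.overlap_mode)
    if gc is not None and cfg.gc_threshold is not None:
        gray = np.asarray(gc.values[:n_beads]) < cfg.gc_threshold  # strict
        gray &= ~np.isnan(gc.values[:n_beads])
    else:
        het = _state_overlap_per_bead(track, chrom, start, n_beads,
                                      cfg.bead_bp, cfg.heterochromatin_states,
                                      cfg.overlap_mode)
        gray = het >= cfg.min_overlap_bp
    colors: list[frozenset[str]] = []
    for b in range(n_beads):
        cs: set[str] = set()
        if gc is not None and gc.n_fraction is not None \
                and gc.n_fraction[b] > cfg.max_n_fraction:
            colors.append(frozenset({"blue"}))
            continue
        if pink[b] >= cfg.min_overlap_bp:
            cs.add("pink")
        if green[b] >= cfg.min_overlap_bp:
            cs.add("lightgreen")
        if gray[b]:
            cs.add("gray")
        if not cs:
            cs.add("blue")
        colors.append(frozenset(cs))
    return colors


def paint_to_fiber(
    colors: list[frozenset[str]],
    chrom: str,
    start: int,
    bead_bp: int,
    persistence_length: float = 3.0,
) -> FiberSpec:
    """Wrap painted bead colors into a fiber with genomic coordinates."""
    return FiberSpec(colors=tuple(colors), persistence_length=persistence_length,
                     genomic_span=(chrom, start, bead_bp))


def gc_fraction_windows(sequence: str, bead_bp: int, chrom: str = "chr",
                        start: int = 0) -> GCTrack:
    """Per-bead GC fraction of a sequence string (G+C over non-N length).

    For FASTA input, pass ``pyfaidx.Fasta(path)[chrom][start:end].seq``.
    Trailing partial windows are dropped.  All-N beads get NaN.
    """
    if not re.fullmatch(r"[ACGTNacgtn]*", sequence):
        raise ValueError("sequence contains characters outside ACGTN")
    n_beads = len(sequence) // bead_bp
    vals = np.empty(n_beads)
    nfrac = np.empty(n_beads)
    for b in range(n_beads):
        w = sequence[b * bead_bp: (b + 1) * bead_bp].upper()
        n_n = w.count("N")
        denom = len(w) - n_n
        nfrac[b] = n_n / len(w)
        vals[b] = (w.count("G") + w.count("C")) / denom if denom else np.nan
    return GCTrack(values=vals, bead_bp=bead_bp, chrom=chrom, start=start,
                   n_fraction=nfrac)


def calibrate_gc_threshold(gc: GCTrack, track: StateTrack, cfg: PaintConfig,
                           chrom: str, start: int) -> float:
    """GC threshold making the gray fraction match the state-13 fraction.

    Returns the GC value such that the number of beads with GC strictly
    below it equals the number of beads carrying >= 90 bp of
    heterochromatin state.  With all-identical GC values no threshold can
    discriminate and a ValueError is raised.
    """
    n_beads = len(gc)
    het = _state_overlap_per_bead(track, chrom, start, n_beads, cfg.bead_bp,
                                  cfg.heterochromatin_states, cfg.overlap_mode)
    target = int((het >= cfg.min_overlap_bp).sum())
    vals = np.sort(gc.values[~np.isnan(gc.values)])
    if len(vals) == 0:
        raise ValueError("no usable GC values")
    if np.ptp(vals) == 0:
        raise ValueError("degenerate GC track: all values identical")
    if target >= len(vals):
        return float(vals[-1] + 1e-9)
    return float(vals[target])  # strictly-below count == target for distinct values


# ---------------------------------------------------------------------------
# synthetic annotation

_FILLER_STATE = 7  # weak-enhancer-like background, paints blue


def synthesize_annotation(
    region_bp: int,
    bead_bp: int,
    seed: int,
    pink_fraction: float = 0.04,
    green_fraction: float = 0.06,
    het_fraction: float = 0.3,
    het_block_beads: int = 40,
    mark_len_bp: tuple[int, int] = (90, 400),
    gc_mean: float = 0.45,
    gc_sd: float = 0.05,
    gc_autocorr: float = 0.7,
    gc_het_shift: float = -0.06,
    chrom: str = "chrS",
) -> tuple[StateTrack, GCTrack]:
    """Generate a ChromHMM-like track and GC profile with set bead fractions.

    ``pink_fraction``/``green_fraction`` are the fractions of beads that
    will carry >= 90 bp of states {1,4,5} / {9,10} (defaults match the
    sparse active annotation of a gene-rich human region at 1 kbp beads).
    Heterochromatin (state 13) comes in runs of ~``het_block_beads`` beads,
    and the AR(1) GC profile is depressed inside those runs so GC
    thresholding can recover them.  Deterministic under ``seed``.
    """
    if pink_fraction + green_fraction + het_fraction > 1.0 + 1e-9:
        raise ValueError("state fractions must sum to at most 1")
    rng = np.random.default_rng(seed)
    n_beads = region_bp // bead_bp
    n_pink = int(round(pink_fraction * n_beads))
    n_green = int(round(green_fraction * n_beads))

    # heterochromatin block runs
    het_mask = np.zeros(n_beads, dtype=bool)
    n_het = int(round(het_fraction * n_beads))
    while het_mask.sum() < n_het:
        blk = max(1, int(rng.geometric(1.0 / het_block_beads)))
        blk = min(blk, n_het - int(het_mask.sum()) + 5)
        at = int(rng.integers(0, max(1, n_beads - blk)))
        het_mask[at: at + blk] = True
    # trim overshoot deterministically from the end of runs
    overshoot = int(het_mask.sum()) - n_het
    if overshoot > 0:
        idx = np.nonzero(het_mask)[0][::-1][:overshoot]
        het_mask[idx] = False

    free = np.nonzero(~het_mask)[0]
    marks = rng.choice(free, size=min(n_pink + n_green, len(free)), replace=False)
    pink_beads = marks[:n_pink]
    green_beads = marks[n_pink:]

    rows = []
    for b in pink_beads:
        state = int(rng.choice([1, 4, 5]))
        ln = int(rng.integers(mark_len_bp[0], mark_len_bp[1] + 1))
        off = int(rng.integers(0, bead_bp - ln + 1))
        rows.append((chrom, b * bead_bp + off, b * bead_bp + off + ln, state))
    for b in green_beads:
        state = int(rng.choice([9, 10]))
        ln = int(rng.integers(mark_len_bp[0], mark_len_bp[1] + 1))
        off = int(rng.integers(0, bead_bp - ln + 1))
        rows.append((chrom, b * bead_bp + off, b * bead_bp + off + ln, state))
    # state-13 runs cover their beads fully
    b = 0
    while b < n_beads:
        if het_mask[b]:
            e = b
            while e < n_beads and het_mask[e]:
                e += 1
            rows.append((chrom, b * bead_bp, e * bead_bp, 13))
            b = e
        else:
            b += 1
    # fill every remaining bp with a background state so coverage is complete
    occupied = sorted((s, e) for _, s, e, _ in rows)
    cursor = 0
    fillers = []
    for s, e in occupied:
        if s > cursor:
            fillers.append((chrom, cursor, s, _FILLER_STATE))
        cursor = max(cursor, e)
    if cursor < region_bp:
        fillers.append((chrom, cursor, region_bp, _FILLER_STATE))
    track = StateTrack(pd.DataFrame(rows + fillers,
                                    columns=["chrom", "start", "end", "state"]))

    # AR(1) GC profile, depressed in heterochromatin runs
    noise = rng.normal(0.0, gc_sd * np.sqrt(1 - gc_autocorr**2), size=n_beads)
    gc_vals = np.empty(n_beads)
    prev = 0.0
    for i in range(n_beads):
        prev = gc_autocorr * prev + noise[i]
        gc_vals[i] = gc_mean + prev
    gc_vals = gc_vals + gc_het_shift * het_mask
    gc_vals = np.clip(gc_vals, 0.05, 0.95)
    gc = GCTrack(values=gc_vals, bead_bp=bead_bp, chrom=chrom, start=0,
                 n_fraction=np.zeros(n_beads))
    return track, gc


def synthesize_sequence(gc: GCTrack, seed: int) -> str:
    """A synthetic DNA sequence realizing each bead's GC fraction exactly
    (stand-in for real genome FASTA in pipeline tests)."""
    rng = np.random.default_rng(seed)
    chunks = []
    for v in gc.values:
        n_gc = int(round((0.0 if np.isnan(v) else v) * gc.bead_bp))
        letters = np.array(["N"] * gc.bead_bp if np.isnan(v) else
                           ["G"] * n_gc + ["A"] * (gc.bead_bp - n_gc))
        half = rng.random(gc.bead_bp) < 0.5
        letters = np.where((letters == "G") & half, "C", letters)
        letters = np.where((letters == "A") & half, "T", letters)
        rng.shuffle(letters)
        chunks.append("".join(letters))
    return "".join(chunks)


def write_color_table(colors: list[frozenset[str]], path: str, chrom: str,
                      start: int, bead_bp: int) -> None:
    """BED-like TSV: chrom, start, end, comma-joined color set per bead."""
    with open(path, "w") as fh:
        for b, cs in enumerate(colors):
            s = start + b * bead_bp
            fh.write(f"{chrom}\t{s}\t{s + bead_bp}\t{','.join(sorted(cs))}\n")


def read_color_table(path: str) -> tuple[list[frozenset[str]], str, int, int]:
    colors = []
    chrom, start, bead_bp = "chr", 0, 0
    with open(path) as fh:
        for k, line in enumerate(fh):
            c, s, e, cset = line.rstrip("\n").split("\t")
            if k == 0:
                chrom, start, bead_bp = c, int(s), int(e) - int(s)
            colors.append(frozenset(cset.split(",")))
    return colors, chrom, start, bead_bp
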