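"""Fiber and binding-factor specifications.

A :class:`FiberSpec` is the 1D description of a chromatin fiber: one color
set per bead (a bead may carry several colors, e.g. pink *and* gray),
optional genomic coordinates, permanent loop bonds and a persistence
length.  A :class:`FactorSpecies` describes one population of diffusing
binding proteins: its color, copy number, diameter, per-bead-color
affinities and the time at which its binding switches on.

:func:`toy_fiber` builds the standard coloring patterns used throughout:
regularly spaced or Poisson-scattered binding sites, alternating
eu/heterochromatin blocks, and binding blocks separated by non-binding
"gene deserts".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["FiberSpec", "FactorSpecies", "toy_fiber", "apply_permanent_loops",
           "loop_anchor_pairs"]

#: colors understood by the shipped recipes; configs may extend this set
DEFAULT_PALETTE = frozenset({
    "blue", "pink", "lightgreen", "gray", "yellow",
    "red", "green", "darkblue", "purple", "black",
})


@dataclass(frozen=True)
class FiberSpec:
    """1D specification of one chromatin fiber.

    ``colors[i]`` is the (possibly multi-element) color set of bead i.
    ``loop_bonds`` lists extra permanent FENE bonds between anchor beads,
    on top of the implicit backbone bonds between consecutive beads.
    ``genomic_span`` is ``(chrom, start_bp, bead_bp)`` for painted fibers,
    or None for toy fibers.
    """

    colors: tuple[frozenset[str], ...]
    loop_bonds: tuple[tuple[int, int], ...] = ()
    persistence_length: float = 3.0
    genomic_span: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        n = self.n_beads
        if n < 2:
            raise ValueError("a fiber needs at least 2 beads")
        seen: set[tuple[int, int]] = set()
        for i, j in self.loop_bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid loop anchor pair ({i}, {j})")
            if abs(i - j) == 1:
                raise ValueError(
                    f"loop anchors ({i}, {j}) are backbone neighbors (degenerate loop)"
                )
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate loop bond {key}")
            seen.add(key)

    @property
    def n_beads(self) -> int:
        return len(self.colors)

    def beads_with_color(self, color: str) -> np.ndarray:
        """Sorted indices of beads carrying ``color``."""
        return np.array(
            [i for i, cs in enumerate(self.colors) if color in cs], dtype=np.int64
        )

    def color_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cs in self.colors:
            for c in cs:
                counts[c] = counts.get(c, 0) + 1
        return counts


@dataclass(frozen=True)
class FactorSpecies:
    """One population of diffusing multivalent binding proteins."""

    color: str
    count: int
    affinity: dict[str, float] = field(default_factory=dict)  # bead color -> kT
    diameter: float = 1.0  # sigma
    activation_time: float = 1e4  # simulation time units
    max_valence: int | None = None  # None = multivalent; 1 = monovalent control

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be nonnegative")
        if self.activation_time < 0:
            raise ValueError("activation_time must be nonnegative")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.max_valence is not None and self.max_valence < 1:
            raise ValueError("max_valence must be >= 1 when set")


def _uniform(n_beads: int, base: str) -> list[set[str]]:
    return [{base} for _ in range(n_beads)]


def toy_fiber(
    pattern: str,
    n_beads: int,
    *,
    spacing: int = 20,
    rate: float | None = None,
    blocks: list[tuple[int, str]] | None = None,
    binding_color: str = "pink",
    background_color: str = "blue",
    persistence_length: float = 3.0,
    seed: int | None = None,
) -> FiberSpec:
    """Build the standard toy coloring patterns.

    Patterns
    --------
    ``regular``
        One ``binding_color`` bead every ``spacing`` beads (at 0-based
        indices spacing-1, 2*spacing-1, ...), the rest ``background_color``.
    ``poisson``
        Binding beads scattered uniformly at random with per-bead
        probability ``rate`` (default 1/spacing, i.e. the same mean linear
        density as ``regular``); requires ``seed``.
    ``blocks``
        Repeat the block list, e.g. ``[(300, "lightgreen"), (100, "pink")]``
        for alternating eu/heterochromatin, or
        ``[(400, "binding"), (100, "gray")]``-style deserts where the
        pseudo-color ``"binding"`` expands to the regular pattern of
        ``binding_color`` over ``background_color``.
    ``alternating``
        Regular pattern whose binding beads alternate between
        ``binding_color`` and the value passed via ``blocks=[(1, other)]``
        shorthand is *not* used; instead pass
        ``binding_color="pink"``/``alt_color`` via blocks: see
        :func:`alternating_binding_fiber` below for the explicit helper.
    """
    if pattern == "regular":
        colors = _uniform(n_beads, background_color)
        for i in range(spacing - 1, n_beads, spacing):
            colors[i] = {binding_color}
    elif pattern == "poisson":
        if seed is None:
            raise ValueError("poisson pattern requires a seed")
        p = rate if rate is not None else 1.0 / spacing
        rng = np.random.default_rng(seed)
        hits = rng.random(n_beads) < p
        colors = _uniform(n_beads, background_color)
        for i in np.nonzero(hits)[0]:
            colors[int(i)] = {binding_color}
    elif pattern == "blocks":
        if not blocks:
            raise ValueError("blocks pattern requires a block list")
        colors = []
        while len(colors) < n_beads:
            for length, color in blocks:
                if color == "binding":
                    for k in range(length):
                        idx = len(colors) + k
                        # regular high-affinity sites inside a binding block
                        colors.append(
                            {binding_color}
                            if (k + 1) % spacing == 0
                            else {background_color}
                        )
                else:
                    colors.extend({color} for _ in range(length))
        colors = colors[:n_beads]
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return FiberSpec(
        colors=tuple(frozenset(c) for c in colors),
        persistence_length=persistence_length,
    )


def alternating_binding_fiber(
    n_beads: int,
    spacing: int = 20,
    colors_cycle: tuple[str, ...] = ("pink", "lightgreen"),
    background_color: str = "blue",
    persistence_length: float = 3.0,
) -> FiberSpec:
    """Regularly spaced binding beads whose colors alternate along the fiber."""
    colors = _uniform(n_beads, background_color)
    k = 0
    for i in range(spacing - 1, n_beads, spacing):
        colors[i] = {colors_cycle[k % len(colors_cycle)]}
        k += 1
    return FiberSpec(
        colors=tuple(frozenset(c) for c in colors),
        persistence_length=persistence_length,
    )


def scattered_multicolor_fiber(
    n_beads: int,
    species_colors: tuple[str, ...],
    per_color_fraction: float,
    seed: int,
    background_color: str = "blue",
    persistence_length: float = 3.0,
) -> FiberSpec:
    """Cognate sites for several species scattered randomly along one fiber."""
    rng = np.random.default_rng(seed)
    colors = _uniform(n_beads, background_color)
    n_sites = int(round(per_color_fraction * n_beads))
    chosen = rng.choice(n_beads, size=min(n_sites * len(species_colors), n_beads),
                        replace=False)
    for k, i in enumerate(chosen):
        colors[int(i)] = {species_colors[k % len(species_colors)]}
    return FiberSpec(
        colors=tuple(frozenset(c) for c in colors),
        persistence_length=persistence_length,
    )


def loop_anchor_pairs(
    n_beads: int, loop_beads: int = 324, gap_beads: int = 300, end_gap: int = 150
) -> list[tuple[int, int]]:
    """Anchor pairs that pre-organize a fiber into permanent loops.

    Loops of ``loop_beads`` beads separated by ``gap_beads`` unlooped beads,
    with ``end_gap`` unlooped beads at each end.  A loop occupying beads
    [a, a + loop_beads) is closed by bonding its first and last bead.
    """
    pairs: list[tuple[int, int]] = []
    a = end_gap
    while a + loop_beads <= n_beads - end_gap:
        pairs.append((a, a + loop_beads - 1))
        a += loop_beads + gap_beads
    return pairs


def apply_permanent_loops(
    fiber: FiberSpec, anchor_pairs: list[tuple[int, int]]
) -> FiberSpec:
    """Return a fiber with permanent FENE bonds added between anchor pairs.

    Idempotent: duplicate pairs (in either order) collapse to one bond.
    Anchors adjacent on the backbone are rejected as degenerate loops.
    """
    existing = {(min(i, j), max(i, j)) for i, j in fiber.loop_bonds}
    for i, j in anchor_pairs:
        if i == j:
            raise ValueError(f"loop anchors must be distinct, got ({i}, {j})")
        if abs(i - j) == 1:
            raise ValueError(f"anchors ({i}, {j}) are backbone neighbors")
        existing.add((min(i, j), max(i, j)))
    return replace(fiber, loop_bonds=tuple(sorted(existing)))
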