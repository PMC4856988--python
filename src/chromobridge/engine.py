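"""Brownian/Langevin dynamics of chromatin fibers and binding factors.

The engine integrates bead-spring fibers (FENE bonds, Kratky–Porod
bending, WCA sterics) and diffusing binding factors (truncated-shifted LJ
attraction to cognate beads) in a periodic cubic box, in reduced units
(sigma = k_BT = bead friction = 1, so one time unit is the diffusion time
of a free bead).

The standard protocol equilibrates the system with every affinity switched
off, activates each factor species at its scheduled time, optionally
changes affinities mid-run, and samples configurations at a fixed
interval.  Positions are stored unwrapped; minimum-image convention is
applied wherever distances are needed.

Two integrators are provided and share one force kernel:

* ``"baoab"`` (default) — inertial Langevin with unit mass and friction,
  stable at dt = 0.01 tau; its long-time diffusive behaviour matches the
  overdamped limit since D = k_BT/gamma either way.
* ``"euler-maruyama"`` — first-order overdamped update, requiring a much
  smaller dt (~1e-3 tau); exact free diffusion at any dt, and with the
  thermostat off it performs plain gradient descent, which several of the
  physics checks exploit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import _kernels as K
from .fiber import FactorSpecies, FiberSpec
from .forcefield import (BondOverstretchError, ForceFieldParams,
                         realized_well_depth,
                         stiffness_for_persistence_length)

__all__ = [
    "SimulationConfig",
    "AffinityEvent",
    "SystemState",
    "Trajectory",
    "System",
    "run_protocol",
    "neighbor_search",
    "initialize_conformation",
]

INTEGRATORS = {"baoab": K.INTEGRATOR_BAOAB, "euler-maruyama": K.INTEGRATOR_EM}
DEFAULT_DT = {"baoab": 0.01, "euler-maruyama": 1e-3}


@dataclass(frozen=True)
class AffinityEvent:
    """Scheduled change of one affinity entry at a given simulation time."""

    time: float
    species_color: str
    bead_color: str
    epsilon: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("affinity events cannot be scheduled before time 0")


@dataclass
class SimulationConfig:
    fibers: list[FiberSpec]
    species: list[FactorSpecies]
    box_edge: float  # sigma
    run_time: float  # time units
    seed: int
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    dt: float | None = None
    sample_interval: float = 1000.0
    integrator: str = "baoab"
    schedule: list[AffinityEvent] = field(default_factory=list)
    phantom: bool = False  # skip all non-bonded interactions (ideal chain)

    def __post_init__(self) -> None:
        if self.integrator not in INTEGRATORS:
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.dt is None:
            self.dt = DEFAULT_DT[self.integrator]
        if self.box_edge <= 0 or self.run_time < 0:
            raise ValueError("box edge must be positive and run time nonnegative")
        for ev in self.schedule:
            if ev.time < 0:
                raise ValueError("scheduled event before time 0")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "fibers": [[sorted(c) for c in f.colors] for f in self.fibers],
                "loops": [list(map(list, f.loop_bonds)) for f in self.fibers],
                "species": [
                    (s.color, s.count, s.diameter, s.activation_time,
                     sorted(s.affinity.items()), s.max_valence)
                    for s in self.species
                ],
                "box": self.box_edge,
                "dt": self.dt,
                "run_time": self.run_time,
                "integrator": self.integrator,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SystemState:
    """Instantaneous configuration: all beads first, then all factors."""

    time: float
    positions: np.ndarray  # (N, 3), sigma units, unwrapped
    velocities: np.ndarray
    box_edge: float
    n_beads: int

    def wrapped_positions(self) -> np.ndarray:
        L = self.box_edge
        return self.positions - L * np.floor(self.positions / L)


class Trajectory:
    """Uniformly sampled snapshots of a run plus its metadata.

    ``positions`` is (n_frames, N, 3) float32, unwrapped.  Beads occupy
    particle indices ``[0, n_beads)`` (fibers concatenated in order),
    factors follow grouped by species.
    """

    def __init__(self, times: np.ndarray, positions: np.ndarray,
                 box_edge: float, n_beads: int,
                 fiber_slices: list[tuple[int, int]],
                 species_slices: dict[str, tuple[int, int]],
                 metadata: dict | None = None):
        times = np.asarray(times, dtype=float)
        if len(times) != len(positions):
            raise ValueError("times and positions disagree in length")
        if len(times) > 1:
            dtimes = np.diff(times)
            if not np.all(dtimes > 0):
                raise ValueError("snapshot times must be strictly increasing")
            if not np.allclose(dtimes, dtimes[0]):
                raise ValueError("sampling interval must be uniform")
        self.times = times
        self.positions = np.asarray(positions, dtype=np.float32)
        self.box_edge = float(box_edge)
        self.n_beads = int(n_beads)
        self.fiber_slices = [tuple(s) for s in fiber_slices]
        self.species_slices = {k: tuple(v) for k, v in species_slices.items()}
        self.metadata = dict(metadata or {})

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def bead_positions(self, frame: int) -> np.ndarray:
        return self.positions[frame, : self.n_beads].astype(float)

    def factor_positions(self, frame: int, color: str | None = None) -> np.ndarray:
        if color is None:
            return self.positions[frame, self.n_beads:].astype(float)
        a, b = self.species_slices[color]
        return self.positions[frame, a:b].astype(float)

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as h:
            h.create_dataset("times", data=self.times)
            h.create_dataset("positions", data=self.positions,
                             chunks=(1,) + self.positions.shape[1:],
                             compression="gzip", compression_opts=1)
            h.attrs["box_edge"] = self.box_edge
            h.attrs["n_beads"] = self.n_beads
            h.attrs["fiber_slices"] = json.dumps(self.fiber_slices)
            h.attrs["species_slices"] = json.dumps(self.species_slices)
            h.attrs["metadata"] = json.dumps(self.metadata)

    @classmethod
    def load(cls, path: str) -> "Trajectory":
        with h5py.File(path, "r") as h:
            return cls(
                times=h["times"][:],
                positions=h["positions"][:],
                box_edge=float(h.attrs["box_edge"]),
                n_beads=int(h.attrs["n_beads"]),
                fiber_slices=[tuple(s) for s in json.loads(h.attrs["fiber_slices"])],
                species_slices={k: tuple(v) for k, v in
                                json.loads(h.attrs["species_slices"]).items()},
                metadata=json.loads(h.attrs["metadata"]),
            )

    def export_xyz(self, path: str, frame: int = -1) -> None:
        """Write one snapshot as XYZ (element column carries b/f tags)."""
        p = self.positions[frame]
        with open(path, "w") as fh:
            fh.write(f"{len(p)}\n")
            fh.write(f"time={self.times[frame]} box={self.box_edge}\n")
            for i, (x, y, z) in enumerate(p):
                tag = "B" if i < self.n_beads else "F"
                fh.write(f"{tag} {x:.4f} {y:.4f} {z:.4f}\n")


class System:
    """Assembled particle system ready for integration."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        ff = config.forcefield
        self.n_beads = sum(f.n_beads for f in config.fibers)
        self.n_factors = sum(s.count for s in config.species)
        self.n = self.n_beads + self.n_factors

        # fiber slices, bonds, angles
        self.fiber_slices: list[tuple[int, int]] = []
        bonds: list[tuple[int, int]] = []
        angles: list[tuple[int, int, int]] = []
        kb_angle: list[float] = []
        off = 0
        for f in config.fibers:
            self.fiber_slices.append((off, off + f.n_beads))
            kb = stiffness_for_persistence_length(f.persistence_length)
            for i in range(f.n_beads - 1):
                bonds.append((off + i, off + i + 1))
            for i, j in f.loop_bonds:
                bonds.append((off + i, off + j))
            for i in range(f.n_beads - 2):
                angles.append((off + i, off + i + 1, off + i + 2))
                kb_angle.append(kb)
            off += f.n_beads
        self.bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
        self.angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
        self.kb_angle = np.array(kb_angle, dtype=float)
        self._bond_codes = None  # set once particle count is known

        # particle attributes
        self.diam = np.ones(self.n)
        self.species_of = np.full(self.n, -1, dtype=np.int64)
        self.species_slices: dict[str, tuple[int, int]] = {}
        pos = self.n_beads
        for si, s in enumerate(config.species):
            self.species_slices[s.color] = (pos, pos + s.count)
            self.species_of[pos: pos + s.count] = si
            self.diam[pos: pos + s.count] = s.diameter
            pos += s.count
        self.capped = np.array(
            [s.max_valence == 1 for s in config.species], dtype=np.bool_
        ).reshape(-1)
        if self.capped.size == 0:
            self.capped = np.zeros(1, dtype=np.bool_)

        # full (post-activation) epsilon matrix species x bead; a bead with
        # several colors takes the strongest matching affinity
        ns = max(1, len(config.species))
        self.eps_full = np.zeros((ns, self.n_beads))
        off = 0
        for f in config.fibers:
            for b, colors in enumerate(f.colors):
                for si, s in enumerate(config.species):
                    vals = [s.affinity.get(c, 0.0) for c in colors]
                    if vals:
                        self.eps_full[si, off + b] = max(vals)
            off += f.n_beads

        self.ff = ff
        rc = ff.attraction_cutoff * float(self.diam.max()) if self.n else 1.8
        self.skin = 0.6
        self.rlist = max(rc, K.WCA_CUT * (float(self.diam.max()) if self.n else 1.0)) + self.skin
        if self.rlist >= config.box_edge / 2:
            raise ValueError("box too small for the interaction range")
        # cap the cell grid: beyond ~64 cells/edge the table's memory cost
        # outweighs the scan savings (cells merely grow past rlist)
        self.ncell = min(64, max(1, int(config.box_edge / self.rlist)))
        self.nbr_table = self._neighbor_table(self.ncell)
        self._ws: dict | None = None
        # encoded sorted bond list (min*n + max) for pair-loop exclusion:
        # bonded pairs get their WCA core inside the bond term instead
        lo = np.minimum(self.bonds[:, 0], self.bonds[:, 1]) if len(self.bonds) else np.empty(0, np.int64)
        hi = np.maximum(self.bonds[:, 0], self.bonds[:, 1]) if len(self.bonds) else np.empty(0, np.int64)
        self.bond_codes = np.sort(lo * self.n + hi).astype(np.int64)

    @staticmethod
    def _neighbor_table(nc: int) -> np.ndarray:
        """27 (deduplicated, -1-padded) neighbor cell indices per cell."""
        idx = np.arange(nc)
        cx, cy, cz = np.meshgrid(idx, idx, idx, indexing="ij")
        cols = []
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for oz in (-1, 0, 1):
                    cols.append(
                        ((((cx + ox) % nc) * nc + (cy + oy) % nc) * nc
                         + (cz + oz) % nc).ravel()
                    )
        table = np.sort(np.stack(cols, axis=1).astype(np.int64), axis=1)
        if nc >= 3:
            return table  # all 27 neighbors distinct
        # tiny grids: neighbor offsets alias; deduplicate with -1 padding
        out = np.full_like(table, -1)
        for c in range(table.shape[0]):
            seen = sorted(set(table[c].tolist()))
            out[c, : len(seen)] = seen
        return out

    def _workspace(self, pair_cap: int | None = None) -> dict:
        if self._ws is None or (pair_cap and self._ws["pair_i"].size < pair_cap):
            n = self.n
            cap = pair_cap or max(80 * n, 4096)
            nc3 = self.ncell ** 3
            self._ws = {
                "head": np.empty(nc3, np.int64),
                "nxt": np.empty(n, np.int64),
                "ccoord": np.empty(n, np.int64),
                "pair_i": np.empty(cap, np.int64),
                "pair_j": np.empty(cap, np.int64),
                "pair_eps": np.empty(cap, np.float64),
                "pair_sij2": np.empty(cap, np.float64),
                "pair_f": np.empty(cap, np.int64),
                "pair_b": np.empty(cap, np.int64),
                "pair_sp": np.empty(cap, np.int64),
                "partner": np.full(n, -1, np.int64),
                "best_r2": np.zeros(n),
                "forces": np.zeros((n, 3)),
                "ref": np.zeros((n, 3)),
                "wpos": np.zeros((n, 3)),
            }
        return self._ws

    # -- initialization ----------------------------------------------------

    def initial_state(self, seed: int, relax_steps: int = 2000) -> SystemState:
        """Self-avoiding random-walk fibers + uniformly scattered factors.

        After growth, a short noise-free capped-force descent removes any
        residual soft overlaps without disturbing connectivity.
        """
        sizes = np.array([f.n_beads for f in self.config.fibers], dtype=np.int64)
        code = K.ERR_PLACEMENT
        pos = None
        for attempt in range(5):
            code, pos = K.place_system(
                sizes, self.n_factors, self.config.box_edge, 1.0, 0.8,
                (seed + 7919 * attempt) % 2**31,
            )
            if code == K.OK:
                break
        if code != K.OK:
            raise RuntimeError(
                "failed to place the system (over-dense configuration?)"
            )
        state = SystemState(
            time=0.0, positions=pos, velocities=np.zeros_like(pos),
            box_edge=self.config.box_edge, n_beads=self.n_beads,
        )
        if relax_steps > 0:
            self._integrate(state, n_steps=relax_steps, dt=2e-4, kT=0.0,
                            integrator=K.INTEGRATOR_EM,
                            eps_fb=np.zeros_like(self.eps_full),
                            fcap=100.0, sample_stride=0, frames=None,
                            step_offset=0)
            state.time = 0.0
        return state

    # -- integration -------------------------------------------------------

    _CHUNK = 1024  # steps per kernel call (noise generated per chunk)

    def _integrate(self, state, n_steps, dt, kT, integrator, eps_fb, fcap,
                   sample_stride, frames, step_offset, frame_fill=0,
                   rng=None):
        n = self.n
        eps_wca = 0.0 if self.config.phantom else self.ff.steric_epsilon
        out = frames if frames is not None else np.empty((0, n, 3), np.float32)
        empty_noise = np.empty((0, n, 3))
        done = 0
        total_written = 0
        while done < n_steps:
            m = min(self._CHUNK, n_steps - done)
            if kT > 0.0:
                if rng is None:
                    raise ValueError("thermostatted integration needs an RNG")
                noise = rng.standard_normal((m, n, 3))
            else:
                noise = empty_noise
            for _ in range(4):
                ws = self._workspace()
                code, ea, eb, step, written = K.run_chunk(
                    state.positions, state.velocities, self.config.box_edge,
                    self.diam, self.species_of, eps_fb, self.capped,
                    bool(self.capped.any()), self.bonds, self.bond_codes,
                    self.ff.steric_epsilon,
                    self.ff.fene_spring_k, self.ff.fene_max_extension,
                    self.angles, self.kb_angle, eps_wca,
                    self.ff.attraction_cutoff, dt, kT, 1.0, integrator,
                    m, step_offset + done, sample_stride, out,
                    frame_fill + total_written, self.skin, self.rlist,
                    self.ncell, self.nbr_table, ws["head"], ws["nxt"],
                    ws["ccoord"], ws["pair_i"], ws["pair_j"], ws["pair_eps"],
                    ws["pair_sij2"], ws["pair_f"], ws["pair_b"],
                    ws["pair_sp"], ws["partner"], ws["best_r2"],
                    ws["forces"], ws["ref"], ws["wpos"], noise, fcap,
                )
                if code == K.ERR_CAPACITY:
                    self._workspace(pair_cap=4 * ws["pair_i"].size)
                    continue
                break
            if code == K.ERR_BOND:
                raise BondOverstretchError(
                    self.ff.fene_max_extension, self.ff.fene_max_extension,
                    bond=(int(ea), int(eb)), step=int(step),
                )
            if code == K.ERR_NONFINITE:
                raise FloatingPointError(
                    f"non-finite coordinates for particles ({ea}, {eb}) "
                    f"at step {step}"
                )
            if code != K.OK:
                raise RuntimeError(
                    f"integration failed with code {code} at step {step}"
                )
            done += m
            total_written += written
        state.time += n_steps * dt
        return total_written

    def step(self, state: SystemState, dt: float | None = None,
             n_steps: int = 1, kT: float = 1.0,
             rng: np.random.Generator | None = None) -> SystemState:
        """Advance ``state`` in place by ``n_steps`` integrator steps.

        Affinities follow the state's clock (activation times and schedule);
        aborts with diagnostics on bond overstretch or non-finite
        coordinates.  Returns the same state object for chaining.
        """
        dt = dt if dt is not None else self.config.dt
        if rng is None:
            rng = np.random.default_rng(self.config.seed)
        eps = self.current_eps(state.time + 0.5 * dt)
        self._integrate(state, n_steps=n_steps, dt=dt, kT=kT,
                        integrator=INTEGRATORS[self.config.integrator],
                        eps_fb=eps, fcap=0.0, sample_stride=0, frames=None,
                        step_offset=0, rng=rng if kT > 0 else None)
        return state

    def current_eps(self, t: float) -> np.ndarray:
        """Epsilon matrix in force at time t (activation + schedule).

        Each species' affinity row is its configured row, with any
        scheduled events at or before t applied in time order (later
        events override); rows are zero before the species' activation
        time.  A multi-color bead takes the strongest matching entry.
        """
        rows = [dict(s.affinity) for s in self.config.species]
        for ev in sorted(self.config.schedule, key=lambda e: e.time):
            if t >= ev.time:
                for si, s in enumerate(self.config.species):
                    if s.color == ev.species_color:
                        rows[si][ev.bead_color] = ev.epsilon
        eps = np.zeros_like(self.eps_full)
        touched = any(t >= ev.time for ev in self.config.schedule)
        for si, s in enumerate(self.config.species):
            if t < s.activation_time:
                continue
            if not touched:
                eps[si] = self.eps_full[si]
                continue
            off = 0
            for f in self.config.fibers:
                for b, colors in enumerate(f.colors):
                    vals = [rows[si].get(c, 0.0) for c in colors]
                    if vals:
                        eps[si, off + b] = max(vals)
                off += f.n_beads
        return eps

    def total_energy(self, state: SystemState, eps_fb: np.ndarray | None = None) -> float:
        if eps_fb is None:
            eps_fb = self.current_eps(state.time)
        eps_wca = 0.0 if self.config.phantom else self.ff.steric_epsilon
        return float(K.total_energy(
            state.positions, state.box_edge, self.diam, self.species_of,
            eps_fb, self.bonds, self.bond_codes, self.ff.fene_spring_k,
            self.ff.fene_max_extension, self.angles, self.kb_angle,
            eps_wca, self.ff.attraction_cutoff, self.ff.steric_epsilon,
        ))

    def run(self, progress: bool = False) -> Trajectory:
        """Execute the full protocol and return the sampled trajectory."""
        cfg = self.config
        dt = cfg.dt
        n_total = int(round(cfg.run_time / dt))
        stride = max(1, int(round(cfg.sample_interval / dt)))
        event_times = sorted({s.activation_time for s in cfg.species}
                             | {ev.time for ev in cfg.schedule})
        event_steps = sorted({int(round(t / dt)) for t in event_times
                              if 0 < t < cfg.run_time})
        breakpoints = [0] + event_steps + [n_total]
        n_frames = n_total // stride + 1
        frames = np.empty((n_frames, self.n, 3), dtype=np.float32)

        rng = np.random.default_rng(cfg.seed)
        state = self.initial_state(seed=(cfg.seed * 2654435761 + 1) % 2**31)
        frames[0] = state.positions
        fill = 1
        integrator = INTEGRATORS[cfg.integrator]
        for a, b in zip(breakpoints[:-1], breakpoints[1:]):
            if b <= a:
                continue
            eps = self.current_eps((a + 0.5) * dt)
            written = self._integrate(
                state, n_steps=b - a, dt=dt, kT=1.0, integrator=integrator,
                eps_fb=eps, fcap=0.0, sample_stride=stride, frames=frames,
                step_offset=a, frame_fill=fill, rng=rng,
            )
            fill += written
        times = np.arange(n_frames) * stride * dt
        meta = {
            "seed": cfg.seed,
            "config_hash": self.config.config_hash(),
            "dt": dt,
            "integrator": cfg.integrator,
            "affinities": {f"{k[0]}->{k[1]}": v
                           for k, v in self.ff.affinity.items()},
            # realized depth = nominal epsilon minus the shift at the cutoff
            "realized_well_depths_kT": {
                f"{k[0]}->{k[1]}": round(realized_well_depth(
                    v, self.ff.attraction_cutoff), 3)
                for k, v in self.ff.affinity.items()},
            "bead_colors": [sorted(cs) for f in cfg.fibers for cs in f.colors],
        }
        return Trajectory(times[:fill], frames[:fill], cfg.box_edge,
                          self.n_beads, self.fiber_slices,
                          self.species_slices, meta)


def run_protocol(config: SimulationConfig) -> Trajectory:
    """Build the system for ``config`` and run the full protocol."""
    return System(config).run()


def initialize_conformation(fibers, n_factors: int, box_edge: float,
                            seed: int) -> SystemState:
    """Standalone initial-state generation (SAW fibers + scattered factors)."""
    cfg = SimulationConfig(
        fibers=list(fibers),
        species=[FactorSpecies(color="red", count=n_factors, affinity={},
                               activation_time=0.0)] if n_factors else [],
        box_edge=box_edge, run_time=0.0, seed=seed,
    )
    return System(cfg).initial_state(seed=seed)


def neighbor_search(state: SystemState, cutoff: float) -> np.ndarray:
    """All particle pairs with minimum-image distance <= cutoff (sigma).

    Returns an (n_pairs, 2) int array sorted lexicographically; raises for
    a cutoff of at least half the box edge (minimum image would be
    ambiguous).
    """
    L = state.box_edge
    if cutoff >= L / 2:
        raise ValueError("cutoff must be below half the box edge")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(state.positions)
    if n == 0:
        return np.empty((0, 2), dtype=np.int64)
    cap = max(64 * n, 4096)
    while True:
        pair_i = np.empty(cap, dtype=np.int64)
        pair_j = np.empty(cap, dtype=np.int64)
        npairs = K.build_pairs(state.positions, L, cutoff, pair_i, pair_j)
        if npairs >= 0:
            break
        cap *= 4
    pairs = np.stack([pair_i[:npairs], pair_j[:npairs]], axis=1)
    pairs.sort(axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]
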