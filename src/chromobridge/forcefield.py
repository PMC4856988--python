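"""Interaction potentials of the bead–spring chromatin / binder model.

All energies are in units of k_BT and lengths in units of the chromatin
bead diameter sigma.  Three potentials make up the force field:

* FENE bonds along the fiber backbone (and across permanent loop anchors),
  with maximum extension R0 = 1.6 sigma and spring constant K = 30 kT/sigma^2
  (Kremer–Grest convention).
* A Kratky–Porod bending potential U = K_B (1 - cos theta) on consecutive
  bond vectors, with K_B chosen to realize a target persistence length.
* Pair interactions: purely repulsive WCA sterics between every pair
  (chromatin:chromatin, protein:protein and non-cognate protein:chromatin),
  and a truncated-and-shifted Lennard-Jones attraction of depth set by the
  affinity matrix between a binding protein and its cognate beads, cut off
  at 1.8 sigma so energy and force vanish continuously there.

Affinities are directional: the matrix maps (factor species color,
chromatin bead color) to a nominal well depth epsilon in kT; entries absent
from the map mean pure sterics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BondOverstretchError",
    "ForceFieldParams",
    "fene_bond_energy",
    "fene_bond_force",
    "bending_energy",
    "bending_force_magnitude",
    "wca_energy",
    "attractive_lj_energy",
    "pair_energy",
    "pair_force",
    "lj_shift",
    "realized_well_depth",
    "persistence_length_continuum",
    "stiffness_for_persistence_length",
    "mean_cos_angle",
]

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


class BondOverstretchError(RuntimeError):
    """A FENE bond reached its maximum extension (integration blow-up).

    Carries the bond's particle indices and, when raised by the integrator,
    the timestep at which the overstretch occurred.
    """

    def __init__(self, r: float, r0: float, bond: tuple[int, int] | None = None,
                 step: int | None = None):
        self.r, self.r0, self.bond, self.step = r, r0, bond, step
        where = f" bond {bond}" if bond is not None else ""
        when = f" at step {step}" if step is not None else ""
        super().__init__(
            f"FENE bond overstretched{where}{when}: r = {r:.4f} >= R0 = {r0:.4f} "
            f"(reduce dt or check initial overlaps)"
        )


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field constants, in reduced units (kT, sigma).

    ``affinity`` maps ``(species_color, bead_color)`` to the nominal
    truncated-shifted LJ epsilon in kT; pairs not present interact only
    sterically.  The matrix is directional — it is keyed by the factor
    species first and never symmetrized.
    """

    fene_max_extension: float = 1.6
    fene_spring_k: float = 30.0
    bend_stiffness: float | None = None  # kT; None -> derive from persistence_length
    persistence_length: float = 3.0  # sigma
    steric_epsilon: float = 1.0
    attraction_cutoff: float = 1.8
    affinity: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fene_max_extension <= 1.0:
            raise ValueError("fene_max_extension must exceed 1 sigma")
        if self.attraction_cutoff <= 1.0:
            raise ValueError("attraction_cutoff must exceed 1 sigma")
        if self.fene_spring_k <= 0 or self.steric_epsilon <= 0:
            raise ValueError("spring constant and steric epsilon must be positive")
        for pair, eps in self.affinity.items():
            if eps < 0:
                raise ValueError(f"negative affinity for {pair}")

    @property
    def resolved_bend_stiffness(self) -> float:
        """K_B in kT: explicit value if set, else calibrated to persistence_length."""
        if self.bend_stiffness is not None:
            return self.bend_stiffness
        return stiffness_for_persistence_length(self.persistence_length)

    def epsilon(self, species_color: str, bead_color: str) -> float:
        """Nominal affinity in kT; 0.0 when the pair is not in the matrix."""
        return self.affinity.get((species_color, bead_color), 0.0)


# ---------------------------------------------------------------------------
# bonds

def fene_bond_energy(r: float, k: float = 30.0, r0: float = 1.6) -> float:
    """FENE bond energy U = -K R0^2/2 ln(1 - (r/R0)^2), in kT.

    Diverges as r -> R0; raises :class:`BondOverstretchError` at r >= R0.
    The WCA sterics acting between the bonded pair are accounted for
    separately in the pair loop, per standard Kremer–Grest usage.
    """
    if r < 0:
        raise ValueError("bond length must be nonnegative")
    if r >= r0:
        raise BondOverstretchError(r, r0)
    return -0.5 * k * r0**2 * math.log(1.0 - (r / r0) ** 2)


def fene_bond_force(r: float, k: float = 30.0, r0: float = 1.6) -> float:
    """Magnitude of the attractive FENE restoring force, -dU/dr (kT/sigma).

    Negative return value means the force pulls the bond shorter.
    """
    if r >= r0:
        raise BondOverstretchError(r, r0)
    return -k * r / (1.0 - (r / r0) ** 2)


# ---------------------------------------------------------------------------
# bending

def bending_energy(theta: float, k_bend: float) -> float:
    """Kratky–Porod bending energy U = K_B (1 - cos theta), in kT.

    ``theta`` is the angle between consecutive bond vectors (0 = straight).
    """
    c = min(1.0, max(-1.0, math.cos(theta)))
    return k_bend * (1.0 - c)


def bending_force_magnitude(theta: float, k_bend: float) -> float:
    """-dU/dtheta = -K_B sin(theta) (torque, kT/rad)."""
    return -k_bend * math.sin(theta)


def mean_cos_angle(k_bend: float) -> float:
    """Equilibrium <cos theta> of a discrete Kratky–Porod joint.

    Boltzmann average over the sphere gives the Langevin function
    coth(K) - 1/K.
    """
    if k_bend == 0:
        return 0.0
    return 1.0 / math.tanh(k_bend) - 1.0 / k_bend


def persistence_length_continuum(k_bend: float, sigma: float = 1.0) -> float:
    """Continuum (worm-like-chain) estimate l_p = K_B sigma / kT."""
    return k_bend * sigma


def stiffness_for_persistence_length(lp: float, bond_length: float = 1.0) -> float:
    """K_B (kT) such that a discrete chain realizes persistence length ``lp``.

    Inverts <cos theta>(K_B) = exp(-bond_length/lp), the discrete-chain
    tangent-correlation decay.  For lp = 3 sigma this gives K_B ~ 3.5 kT,
    a little above the continuum estimate K_B = lp/sigma.
    """
    if lp <= 0:
        raise ValueError("persistence length must be positive")
    target = math.exp(-bond_length / lp)
    return brentq(lambda k: mean_cos_angle(k) - target, 1e-6, 1e3)


# ---------------------------------------------------------------------------
# pair interactions

def _lj(r: float, eps: float, sigma: float) -> float:
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def _lj_force(r: float, eps: float, sigma: float) -> float:
    """-dU/dr of the plain LJ."""
    sr6 = (sigma / r) ** 6
    return 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r


def lj_shift(eps: float, rcut: float, sigma: float = 1.0) -> float:
    """Value of the unshifted LJ at the cutoff (subtracted to make U(rcut)=0)."""
    return _lj(rcut, eps, sigma)


def realized_well_depth(eps: float, rcut: float = 1.8, sigma: float = 1.0) -> float:
    """Depth of the truncated-shifted LJ well (positive number, kT).

    The nominal epsilon minus the (negative) shift at the cutoff; for
    rcut = 1.8 sigma this is ~0.886 eps.
    """
    r_min = 2.0 ** (1.0 / 6.0) * sigma
    return -( _lj(r_min, eps, sigma) - lj_shift(eps, rcut, sigma) )


def wca_energy(r: float, eps: float = 1.0, sigma: float = 1.0) -> float:
    """Purely repulsive WCA energy: LJ truncated-shifted at its minimum."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    rc = WCA_CUTOFF * sigma
    if r >= rc:
        return 0.0
    return _lj(r, eps, sigma) + eps


def attractive_lj_energy(
    r: float, eps: float, rcut: float = 1.8, sigma: float = 1.0
) -> float:
    """Truncated-and-shifted LJ between a factor and a cognate bead."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r >= rcut * sigma:
        return 0.0
    return _lj(r, eps, sigma) - _lj(rcut * sigma, eps, sigma)


def pair_energy(
    r: float,
    species_color: str,
    bead_color: str,
    params: ForceFieldParams,
    sigma: float = 1.0,
    palette: set[str] | None = None,
) -> float:
    """Pair energy between a factor of ``species_color`` and a bead, in kT.

    Cognate pairs (present in the affinity matrix with eps > 0) feel the
    truncated-shifted LJ; everything else is WCA.  ``palette``, when given,
    is the set of configured colors; unknown colors raise a KeyError so a
    typo in a config cannot silently become "no attraction".
    """
    if palette is not None:
        for c in (species_color, bead_color):
            if c not in palette:
                raise KeyError(f"unknown color {c!r}; configured palette: {sorted(palette)}")
    eps = params.epsilon(species_color, bead_color)
    if eps > 0:
        return attractive_lj_energy(r, eps, params.attraction_cutoff, sigma)
    return wca_energy(r, params.steric_epsilon, sigma)


def pair_force(
    r: float,
    species_color: str,
    bead_color: str,
    params: ForceFieldParams,
    sigma: float = 1.0,
) -> float:
    """-dU/dr of :func:`pair_energy` (kT/sigma); positive = repulsive."""
    eps = params.epsilon(species_color, bead_color)
    if eps > 0:
        if r >= params.attraction_cutoff * sigma:
            return 0.0
        return _lj_force(r, eps, sigma)
    if r >= WCA_CUTOFF * sigma:
        return 0.0
    return _lj_force(r, params.steric_epsilon, sigma)


def tangent_correlation(positions: np.ndarray, max_s: int) -> np.ndarray:
    """<t(i) . t(i+s)> for s = 0..max_s from one chain conformation.

    ``positions`` is (n_beads, 3); tangents are normalized bond vectors.
    Used to recover the persistence length from simulated conformations.
    """
    bonds = np.diff(positions, axis=0)
    t = bonds / np.linalg.norm(bonds, axis=1, keepdims=True)
    n = len(t)
    out = np.empty(max_s + 1)
    for s in range(max_s + 1):
        out[s] = float(np.mean(np.sum(t[: n - s] * t[s:], axis=1)))
    return out
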