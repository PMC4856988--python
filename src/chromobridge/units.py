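"""Reduced simulation units and their mapping to physical units.

The simulation works in standard coarse-grained polymer units: lengths in
multiples of the chromatin bead diameter sigma, energies in k_BT, and times
in the Brownian time tau = sigma^2/D of a single bead.  This module converts
between that system and laboratory units (nm, ms, nM, % volume fraction)
given the bead's DNA content, solvent viscosity and temperature.

A 30 nm bead carries 3 kbp of chromatin (a 30-nm fiber packs ~1 kbp per
10 nm of contour); beads with other DNA contents keep the same volume
density of DNA, so diameter scales as the cube root of content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "KB",
    "AVOGADRO",
    "UnitSystem",
    "bead_diameter_for_content",
    "physical_time_unit",
    "box_composition",
]

#: Boltzmann constant, J/K
KB = 1.380649e-23
#: Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23

#: Reference bead: 30 nm diameter carrying 3 kbp.
_REF_DIAMETER_NM = 30.0
_REF_KBP = 3.0


@dataclass(frozen=True)
class UnitSystem:
    """Physical interpretation of the reduced units.

    Parameters
    ----------
    sigma_nm:
        Chromatin bead diameter in nm (the simulation length unit).
    kbp_per_bead:
        DNA content of one bead, kbp.
    viscosity_pa_s:
        Nucleoplasm viscosity in Pa s.  Default 0.01 Pa s (10 cP,
        ten-fold that of water).
    temperature_k:
        Absolute temperature, K.
    """

    sigma_nm: float = 30.0
    kbp_per_bead: float = 3.0
    viscosity_pa_s: float = 0.01
    temperature_k: float = 300.0

    def __post_init__(self) -> None:
        for name in ("sigma_nm", "kbp_per_bead", "viscosity_pa_s", "temperature_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def kbt_joule(self) -> float:
        return KB * self.temperature_k

    @property
    def diffusion_m2_s(self) -> float:
        """Stokes–Einstein diffusion coefficient of one bead, m^2/s."""
        sigma_m = self.sigma_nm * 1e-9
        return self.kbt_joule / (3.0 * math.pi * self.viscosity_pa_s * sigma_m)

    @property
    def tau_ms(self) -> float:
        """Physical duration of one simulation time unit, ms."""
        return physical_time_unit(self)

    def nm(self, length_sigma: float) -> float:
        """Convert a length from sigma units to nm."""
        return length_sigma * self.sigma_nm

    def sigma(self, length_nm: float) -> float:
        """Convert a length from nm to sigma units."""
        return length_nm / self.sigma_nm


def bead_diameter_for_content(kbp: float) -> float:
    """Bead diameter in nm for a given DNA content in kbp.

    Keeps the volume density of DNA fixed at that of the reference
    30 nm / 3 kbp bead, so d = 30 (kbp/3)^(1/3) nm; 1 kbp gives 20.8 nm.
    """
    if kbp <= 0:
        raise ValueError("kbp must be positive")
    return _REF_DIAMETER_NM * (kbp / _REF_KBP) ** (1.0 / 3.0)


def physical_time_unit(units: UnitSystem) -> float:
    """Physical duration of one simulation time unit, in ms.

    tau = sigma^2 / D with D the Stokes–Einstein diffusion coefficient of a
    sphere of diameter sigma: D = k_BT / (3 pi eta sigma).  At 10 cP and
    300 K this gives ~0.6 ms for a 30 nm bead and ~0.2 ms for 20.8 nm.
    """
    sigma_m = units.sigma_nm * 1e-9
    return sigma_m**2 / units.diffusion_m2_s * 1e3


def box_composition(
    n_particles: int, diameter_nm: float, box_edge_nm: float
) -> tuple[float, float]:
    """Volume fraction (%) and molar concentration (nM) of n spheres in a box.

    Returns ``(volume_fraction_percent, concentration_nM)`` for
    ``n_particles`` spheres of the given diameter in a cubic box.
    """
    if diameter_nm <= 0 or box_edge_nm <= 0:
        raise ValueError("diameter and box edge must be positive")
    if n_particles < 0:
        raise ValueError("particle count must be nonnegative")
    box_volume_nm3 = box_edge_nm**3
    sphere_volume_nm3 = math.pi / 6.0 * diameter_nm**3
    volume_fraction = 100.0 * n_particles * sphere_volume_nm3 / box_volume_nm3
    box_volume_l = box_volume_nm3 * 1e-24  # 1 nm^3 = 1e-24 L
    concentration_nm = n_particles / (AVOGADRO * box_volume_l) * 1e9
    return volume_fraction, concentration_nm
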