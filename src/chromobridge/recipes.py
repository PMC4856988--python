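"""Shipped run recipes: the standard simulation setups, scalable down.

A recipe is a YAML document that fully determines a run given a seed: the
fiber coloring pattern(s), factor species with counts/affinities/activation
times, box size, schedule and analysis defaults.  ``scale_recipe`` shrinks
bead and factor counts together while scaling the box edge by the cube
root of the factor, which preserves both the chromatin and the factor
volume fractions exactly; thresholds and sigma are never scaled.

Unknown keys anywhere in a recipe are rejected (typo safety), and loading
a recipe echoes every resolved default so run logs are self-describing.
"""

from __future__ import annotations

import copy
import importlib.resources as resources
from dataclasses import dataclass

import numpy as np
import yaml

from .engine import AffinityEvent, SimulationConfig
from .fiber import (FactorSpecies, FiberSpec, alternating_binding_fiber,
                    apply_permanent_loops, loop_anchor_pairs,
                    scattered_multicolor_fiber, toy_fiber)
from .forcefield import ForceFieldParams
from .units import UnitSystem

__all__ = ["RunRecipe", "load_recipe", "builtin_recipe", "list_recipes",
           "scale_recipe", "build_config"]

_RECIPE_KEYS = {
    "name", "description", "units", "box_edge_sigma", "run_time",
    "sample_interval", "fibers", "species", "forcefield", "schedule",
    "analysis",
}
_UNIT_KEYS = {"sigma_nm", "kbp_per_bead", "viscosity_pa_s", "temperature_k"}
_FIBER_KEYS = {
    "pattern", "n_beads", "copies", "spacing", "rate", "blocks",
    "binding_color", "background_color", "colors_cycle", "species_colors",
    "per_color_fraction", "persistence_length", "loops",
}
_LOOP_KEYS = {"loop_beads", "gap_beads", "end_gap"}
_SPECIES_KEYS = {"color", "count", "affinity", "diameter", "activation_time",
                 "max_valence"}
_FF_KEYS = {"fene_max_extension", "fene_spring_k", "bend_stiffness",
            "persistence_length", "steric_epsilon", "attraction_cutoff"}
_SCHEDULE_KEYS = {"time", "species_color", "bead_color", "epsilon"}
_ANALYSIS_KEYS = {"contact_threshold_sigma", "bin_beads",
                  "cluster_cutoff_sigma", "janus_window_beads"}


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}; "
                         f"allowed: {sorted(allowed)}")


@dataclass
class RunRecipe:
    """A validated recipe plus its scale factor."""

    data: dict
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.scale <= 1):
            raise ValueError("scale factor must lie in (0, 1]")
        _check_keys(self.data, _RECIPE_KEYS, "recipe")
        _check_keys(self.data.get("units", {}), _UNIT_KEYS, "units")
        for f in self.data.get("fibers", []):
            _check_keys(f, _FIBER_KEYS, f"fiber ({f.get('pattern')})")
            if "loops" in f:
                _check_keys(f["loops"], _LOOP_KEYS, "fiber.loops")
        for s in self.data.get("species", []):
            _check_keys(s, _SPECIES_KEYS, f"species ({s.get('color')})")
        _check_keys(self.data.get("forcefield", {}), _FF_KEYS, "forcefield")
        for ev in self.data.get("schedule", []):
            _check_keys(ev, _SCHEDULE_KEYS, "schedule event")
        _check_keys(self.data.get("analysis", {}), _ANALYSIS_KEYS, "analysis")

    @property
    def name(self) -> str:
        return self.data["name"]

    @property
    def analysis(self) -> dict:
        defaults = {"contact_threshold_sigma": 5.0, "bin_beads": 40,
                    "cluster_cutoff_sigma": 3.0, "janus_window_beads": 100}
        defaults.update(self.data.get("analysis", {}))
        return defaults

    def units(self) -> UnitSystem:
        return UnitSystem(**self.data.get("units", {}))

    def resolved(self) -> dict:
        """Full recipe with every default filled in (echoed into run logs)."""
        out = copy.deepcopy(self.data)
        out["analysis"] = self.analysis
        out["scale"] = self.scale
        u = self.units()
        out["units"] = {
            "sigma_nm": u.sigma_nm, "kbp_per_bead": u.kbp_per_bead,
            "viscosity_pa_s": u.viscosity_pa_s, "temperature_k": u.temperature_k,
            "tau_ms": u.tau_ms,
        }
        return out

    def dump(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=False)


def load_recipe(path: str, scale: float = 1.0) -> RunRecipe:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    recipe = RunRecipe(data=data, scale=1.0)
    return scale_recipe(recipe, scale) if scale != 1.0 else recipe


def list_recipes() -> list[str]:
    root = resources.files("chromobridge") / "recipes"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def builtin_recipe(name: str, scale: float = 1.0) -> RunRecipe:
    root = resources.files("chromobridge") / "recipes"
    path = root / f"{name}.yaml"
    if not path.is_file():
        raise KeyError(f"no built-in recipe {name!r}; available: {list_recipes()}")
    data = yaml.safe_load(path.read_text())
    recipe = RunRecipe(data=data, scale=1.0)
    return scale_recipe(recipe, scale) if scale != 1.0 else recipe


MIN_BEADS = 100


def scale_recipe(recipe: RunRecipe, factor: float) -> RunRecipe:
    """Scale bead/factor counts by ``factor`` and the box edge by its cube
    root, preserving all volume fractions; lengths in sigma and all
    thresholds are untouched.  Refuses scales leaving fewer than
    ``MIN_BEADS`` beads."""
    if not (0 < factor <= 1):
        raise ValueError("scale factor must lie in (0, 1]")
    if factor == 1.0:
        return recipe
    data = copy.deepcopy(recipe.data)
    total_beads = 0
    for f in data.get("fibers", []):
        f["n_beads"] = int(round(f["n_beads"] * factor))
        copies = f.get("copies", 1)
        if copies > 1:
            f["copies"] = max(1, int(round(copies * factor)))
            # if copies hit the floor, shrink per-fiber length to compensate
            f["n_beads"] = int(round(f["n_beads"] * copies * factor / f["copies"] / factor))
        total_beads += f["n_beads"] * f.get("copies", 1)
    if total_beads < MIN_BEADS:
        raise ValueError(
            f"scaled recipe has {total_beads} beads (< {MIN_BEADS}); "
            "scale factor too small"
        )
    for s in data.get("species", []):
        s["count"] = int(round(s["count"] * factor))
    data["box_edge_sigma"] = recipe.data["box_edge_sigma"] * factor ** (1.0 / 3.0)
    return RunRecipe(data=data, scale=recipe.scale * factor)


def _build_fiber(f: dict, seed: int) -> list[FiberSpec]:
    pattern = f["pattern"]
    n = f["n_beads"]
    copies = f.get("copies", 1)
    lp = f.get("persistence_length", 3.0)
    fibers = []
    for c in range(copies):
        fiber_seed = (seed * 1000003 + c) % 2**31
        if pattern in ("regular", "poisson", "blocks"):
            blocks = None
            if "blocks" in f:
                blocks = [(int(b[0]), str(b[1])) for b in f["blocks"]]
            fiber = toy_fiber(
                pattern, n,
                spacing=f.get("spacing", 20),
                rate=f.get("rate"),
                blocks=blocks,
                binding_color=f.get("binding_color", "pink"),
                background_color=f.get("background_color", "blue"),
                persistence_length=lp,
                seed=fiber_seed if pattern == "poisson" else None,
            )
        elif pattern == "alternating":
            fiber = alternating_binding_fiber(
                n, spacing=f.get("spacing", 20),
                colors_cycle=tuple(f.get("colors_cycle", ["pink", "lightgreen"])),
                background_color=f.get("background_color", "blue"),
                persistence_length=lp,
            )
        elif pattern == "scattered":
            fiber = scattered_multicolor_fiber(
                n, tuple(f["species_colors"]), f["per_color_fraction"],
                seed=fiber_seed,
                background_color=f.get("background_color", "blue"),
                persistence_length=lp,
            )
        elif pattern == "uniform":
            fiber = toy_fiber("regular", n, spacing=n + 1,
                              background_color=f.get("background_color", "pink"),
                              persistence_length=lp)
        else:
            raise ValueError(f"unknown fiber pattern {pattern!r}")
        if "loops" in f:
            lo = f["loops"]
            anchors = loop_anchor_pairs(
                n, loop_beads=lo.get("loop_beads", 324),
                gap_beads=lo.get("gap_beads", 300),
                end_gap=lo.get("end_gap", 150),
            )
            fiber = apply_permanent_loops(fiber, anchors)
        fibers.append(fiber)
    return fibers


def build_config(recipe: RunRecipe, seed: int, run_time: float | None = None,
                 sample_interval: float | None = None) -> SimulationConfig:
    """Materialize a recipe into an engine configuration."""
    data = recipe.data
    fibers: list[FiberSpec] = []
    for k, f in enumerate(data.get("fibers", [])):
        fibers.extend(_build_fiber(f, seed + 7 * k))
    species = [
        FactorSpecies(
            color=s["color"], count=s["count"],
            affinity=dict(s.get("affinity", {})),
            diameter=s.get("diameter", 1.0),
            activation_time=s.get("activation_time", 1e4),
            max_valence=s.get("max_valence"),
        )
        for s in data.get("species", [])
    ]
    ff_kwargs = dict(data.get("forcefield", {}))
    affinity = {}
    for s in species:
        for color, eps in s.affinity.items():
            affinity[(s.color, color)] = eps
    ff = ForceFieldParams(affinity=affinity, **ff_kwargs)
    schedule = [AffinityEvent(**ev) for ev in data.get("schedule", [])]
    return SimulationConfig(
        fibers=fibers,
        species=species,
        box_edge=data["box_edge_sigma"],
        run_time=run_time if run_time is not None else data["run_time"],
        sample_interval=sample_interval if sample_interval is not None
        else data.get("sample_interval", 1000.0),
        seed=seed,
        forcefield=ff,
        schedule=schedule,
    )
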