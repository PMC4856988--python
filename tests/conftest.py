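"""Shared fixtures: desk-scale simulation runs reused across test modules.

The heavy trajectories are session-scoped and computed lazily; every test
that needs a clustered steady state shares them. Conditions (scale 0.2 of
the standard setups, activation after a 500-tau equilibration, sampling
every 250 tau, steady window = final 20%) are the package's documented
desk-scale study conditions — see docs/methods.md.
"""

from dataclasses import replace

import numpy as np
import pytest

from chromobridge.engine import SimulationConfig, run_protocol
from chromobridge.fiber import FactorSpecies, scattered_multicolor_fiber
from chromobridge.recipes import build_config, builtin_recipe

FIVE_COLORS = ("red", "green", "darkblue", "purple", "black")


def desk_config(recipe_name: str, seed: int, scale: float, run_time: float,
                activation: float = 500.0, sample: float = 250.0,
                max_valence: int | None = None) -> SimulationConfig:
    """Scaled recipe with the test suite's shortened schedule."""
    cfg = build_config(builtin_recipe(recipe_name, scale=scale), seed=seed,
                       run_time=run_time, sample_interval=sample)
    cfg.species = [replace(s, activation_time=activation,
                           max_valence=max_valence) for s in cfg.species]
    return cfg


@pytest.fixture(scope="session")
def fig1a_trajs():
    """Regular binding sites, one species: the main clustering runs.

    Two seeds; the cluster-size claims are averages over seeds, as in the
    original multi-run protocol."""
    return [run_protocol(desk_config("fig1a", seed=s, scale=0.2,
                                     run_time=12000.0))
            for s in (101, 102)]


@pytest.fixture(scope="session")
def fig2a_traj():
    """Alternating pink/light-green sites, red + green factors."""
    return run_protocol(desk_config("fig2a", seed=103, scale=0.2,
                                    run_time=4000.0))


@pytest.fixture(scope="session")
def fivecolor_traj():
    """Five species on cognate sites scattered along two fibers."""
    # 13 copies/species preserves the full system's factor:bead ratio
    # (500 per 40000 beads) at the two-fiber desk scale
    fibers = [scattered_multicolor_fiber(500, FIVE_COLORS, 0.01,
                                         seed=300 + i) for i in range(2)]
    species = [FactorSpecies(color=c, count=13, affinity={c: 7.1},
                             activation_time=500.0) for c in FIVE_COLORS]
    cfg = SimulationConfig(fibers=fibers, species=species, box_edge=29.3,
                           run_time=5000.0, seed=104,
                           sample_interval=250.0)
    return run_protocol(cfg)


@pytest.fixture(scope="session")
def fig3c_traj():
    """Alternating eu/heterochromatin blocks (300 light-green / 100 pink)."""
    return run_protocol(desk_config("fig3c", seed=105, scale=0.2,
                                    run_time=8000.0))


@pytest.fixture(scope="session")
def homogeneous_trio():
    """Three independent short runs of the homogeneous-fiber control."""
    return [run_protocol(desk_config("fig3a", seed=s, scale=0.2,
                                     run_time=1500.0, activation=300.0))
            for s in (201, 202, 203)]


@pytest.fixture(scope="session")
def monovalent_traj():
    """Valence-capped factors: the no-clustering control."""
    return run_protocol(desk_config("fig1a", seed=106, scale=0.1,
                                    run_time=1500.0, activation=250.0,
                                    max_valence=1))


def steady_frames(traj, fraction=0.2):
    n_last = max(1, int(np.ceil(fraction * traj.n_frames)))
    return np.arange(traj.n_frames - n_last, traj.n_frames)
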