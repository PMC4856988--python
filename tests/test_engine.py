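"""Engine physics: initialization, integrators, neighbor search, protocol."""

import numpy as np
import pytest
from scipy.optimize import brentq

import chromobridge._kernels as K
from chromobridge.engine import (AffinityEvent, SimulationConfig, System,
                                 SystemState, Trajectory, neighbor_search,
                                 run_protocol)
from chromobridge.fiber import (FactorSpecies, FiberSpec,
                                apply_permanent_loops, loop_anchor_pairs,
                                toy_fiber)
from chromobridge.forcefield import (BondOverstretchError, fene_bond_force,
                                     wca_energy)


def free_gas_config(n=200, box=60.0, seed=1, run_time=20.0, dt=1e-3,
                    integrator="euler-maruyama"):
    return SimulationConfig(
        fibers=[],
        species=[FactorSpecies(color="red", count=n, affinity={},
                               activation_time=0.0)],
        box_edge=box, run_time=run_time, seed=seed, dt=dt,
        sample_interval=run_time / 20, integrator=integrator,
        phantom=True,  # ideal gas: pure free diffusion
    )


class TestInitialization:
    def test_saw_bond_lengths_and_no_overlaps(self):
        fib = toy_fiber("regular", 1000)
        cfg = SimulationConfig(fibers=[fib], species=[], box_edge=58.5,
                               run_time=0.0, seed=3)
        sys_ = System(cfg)
        st = sys_.initial_state(seed=12)
        bl = np.linalg.norm(np.diff(st.positions[:1000], axis=0), axis=1)
        assert 0.9 < bl.mean() < 1.1
        pairs = neighbor_search(st, 0.8)
        # exclude bonded neighbors (they sit near the FENE+WCA minimum)
        nonbonded = [p for p in pairs if abs(p[0] - p[1]) != 1]
        assert len(nonbonded) == 0

    def test_same_seed_is_bit_identical(self):
        fib = toy_fiber("regular", 200)
        cfg = SimulationConfig(fibers=[fib], species=[], box_edge=40.0,
                               run_time=0.0, seed=3)
        a = System(cfg).initial_state(seed=7).positions
        b = System(cfg).initial_state(seed=7).positions
        np.testing.assert_array_equal(a, b)

    def test_multi_fiber_connectivity_preserved(self):
        # scaled version of the 20-fiber geometry: per-fiber chains intact
        fibs = [toy_fiber("regular", 250) for _ in range(4)]
        cfg = SimulationConfig(fibers=fibs, species=[], box_edge=40.0,
                               run_time=0.0, seed=5)
        st = System(cfg).initial_state(seed=5)
        assert st.positions.shape == (1000, 3)
        for k in range(4):
            seg = st.positions[k * 250:(k + 1) * 250]
            bl = np.linalg.norm(np.diff(seg, axis=0), axis=1)
            assert bl.max() < 1.6
        w = st.wrapped_positions()
        assert (w >= 0).all() and (w < 40.0).all()

    def test_overdense_box_fails_loudly(self):
        fib = toy_fiber("regular", 3000)
        cfg = SimulationConfig(fibers=[fib], species=[], box_edge=12.0,
                               run_time=0.0, seed=1)
        with pytest.raises((RuntimeError, ValueError)):
            System(cfg).initial_state(seed=1)


class TestFreeDiffusion:
    def test_msd_is_6dt_within_5_percent(self):
        # Euler-Maruyama free diffusion is exact at any dt: MSD = 6 D t
        cfg = free_gas_config(n=300, run_time=20.0, dt=1e-2)
        traj = run_protocol(cfg)
        p = traj.positions.astype(float)
        disp = p[1:] - p[0]
        t = traj.times[1:]
        msd = (disp ** 2).sum(axis=2).mean(axis=1)
        ratio = msd / (6.0 * t)
        assert np.abs(ratio.mean() - 1.0) < 0.05

    def test_baoab_diffusion_matches_at_long_times(self):
        cfg = free_gas_config(n=300, run_time=40.0, dt=1e-2,
                              integrator="baoab")
        traj = run_protocol(cfg)
        p = traj.positions.astype(float)
        disp = p[-1] - p[0]
        t = traj.times[-1]
        msd = (disp ** 2).sum(axis=1).mean()
        assert msd == pytest.approx(6.0 * t, rel=0.1)


class TestQuench:
    def test_zero_temperature_energy_decreases_monotonically(self):
        # two cognate particles inside the attraction well, noise off
        fib = FiberSpec(colors=(frozenset({"pink"}), frozenset({"blue"})))
        sp = FactorSpecies(color="red", count=1, affinity={"pink": 8.0},
                           activation_time=0.0)
        cfg = SimulationConfig(fibers=[fib], species=[sp], box_edge=30.0,
                               run_time=0.0, seed=1, integrator="euler-maruyama")
        sys_ = System(cfg)
        pos = np.array([[10.0, 10, 10], [11.0, 10, 10], [10.0, 11.6, 10]])
        st = SystemState(time=0.0, positions=pos.copy(),
                         velocities=np.zeros_like(pos), box_edge=30.0, n_beads=2)
        eps = sys_.current_eps(1.0)
        energies = [sys_.total_energy(st, eps)]
        for _ in range(60):
            sys_._integrate(st, n_steps=5, dt=2e-4, kT=0.0,
                            integrator=K.INTEGRATOR_EM, eps_fb=eps, fcap=0.0,
                            sample_stride=0, frames=None, step_offset=0)
            energies.append(sys_.total_energy(st, eps))
        diffs = np.diff(energies)
        assert (diffs <= 1e-10).all()

    def test_bonded_dimer_relaxes_to_force_balance(self):
        fib = FiberSpec(colors=(frozenset({"blue"}), frozenset({"blue"})))
        cfg = SimulationConfig(fibers=[fib], species=[], box_edge=30.0,
                               run_time=0.0, seed=1, integrator="euler-maruyama")
        sys_ = System(cfg)
        pos = np.array([[10.0, 10, 10], [11.3, 10, 10]])
        st = SystemState(time=0.0, positions=pos.copy(),
                         velocities=np.zeros_like(pos), box_edge=30.0, n_beads=2)
        eps = np.zeros((1, 2))
        for _ in range(100):
            sys_._integrate(st, n_steps=50, dt=2e-4, kT=0.0,
                            integrator=K.INTEGRATOR_EM, eps_fb=eps, fcap=0.0,
                            sample_stride=0, frames=None, step_offset=0)
        r = np.linalg.norm(st.positions[1] - st.positions[0])

        def net_force(x):
            # FENE pull (negative) + WCA push (positive)
            f = fene_bond_force(x)
            h = 1e-7
            f -= (wca_energy(x + h) - wca_energy(x - h)) / (2 * h)
            return f

        r_eq = brentq(net_force, 0.8, 1.2)
        assert r == pytest.approx(r_eq, abs=1e-4)
        assert abs(net_force(r)) < 1e-3

    def test_thermostat_temperature(self):
        cfg = free_gas_config(n=400, run_time=10.0, dt=1e-2, integrator="baoab")
        sys_ = System(cfg)
        rng = np.random.default_rng(0)
        st = sys_.initial_state(seed=2)
        sys_._integrate(st, n_steps=1000, dt=0.01, kT=1.0,
                        integrator=K.INTEGRATOR_BAOAB,
                        eps_fb=np.zeros_like(sys_.eps_full), fcap=0.0,
                        sample_stride=0, frames=None, step_offset=0, rng=rng)
        v2 = (st.velocities ** 2).mean()  # per component, m = 1, kT = 1
        assert v2 == pytest.approx(1.0, rel=0.08)


class TestNeighborSearch:
    def test_matches_bruteforce_for_multiple_cutoffs(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 20, size=(500, 3))
        st = SystemState(time=0, positions=p, velocities=np.zeros_like(p),
                         box_edge=20.0, n_beads=500)
        for cutoff in (1.5, 1.8, 5.0):
            got = {tuple(q) for q in neighbor_search(st, cutoff)}
            d = p[:, None, :] - p[None, :, :]
            d -= 20.0 * np.round(d / 20.0)
            dist = np.sqrt((d ** 2).sum(-1))
            expected = {(i, j) for i in range(500) for j in range(i + 1, 500)
                        if dist[i, j] <= cutoff}
            assert got == expected

    def test_pair_across_periodic_boundary(self):
        p = np.array([[0.5, 10, 10], [19.5, 10, 10]])
        st = SystemState(time=0, positions=p, velocities=np.zeros_like(p),
                         box_edge=20.0, n_beads=2)
        assert [tuple(q) for q in neighbor_search(st, 1.1)] == [(0, 1)]

    def test_empty_system(self):
        st = SystemState(time=0, positions=np.empty((0, 3)),
                         velocities=np.empty((0, 3)), box_edge=20.0, n_beads=0)
        assert len(neighbor_search(st, 2.0)) == 0

    def test_cutoff_above_half_box_rejected(self):
        p = np.zeros((2, 3))
        st = SystemState(time=0, positions=p, velocities=np.zeros_like(p),
                         box_edge=10.0, n_beads=2)
        with pytest.raises(ValueError):
            neighbor_search(st, 5.0)


class TestProtocol:
    def test_bookkeeping_snapshot_count_and_times(self):
        fib = toy_fiber("regular", 100)
        sp = FactorSpecies(color="red", count=5,
                           affinity={"pink": 8.0, "blue": 4.0},
                           activation_time=500.0)
        cfg = SimulationConfig(fibers=[fib], species=[sp], box_edge=30.0,
                               run_time=2000.0, seed=4, sample_interval=200.0)
        traj = run_protocol(cfg)
        assert traj.n_frames == 11  # t = 0, 200, ..., 2000
        assert (np.diff(traj.times) > 0).all()
        np.testing.assert_allclose(np.diff(traj.times), 200.0)

    def test_deterministic_replay_is_bit_identical(self):
        fib = toy_fiber("regular", 100)
        sp = FactorSpecies(color="red", count=5,
                           affinity={"pink": 8.0, "blue": 4.0},
                           activation_time=100.0)
        cfg = SimulationConfig(fibers=[fib], species=[sp], box_edge=30.0,
                               run_time=400.0, seed=11, sample_interval=100.0)
        t1 = run_protocol(cfg)
        t2 = run_protocol(cfg)
        np.testing.assert_array_equal(t1.positions, t2.positions)

    def test_affinity_activation_and_schedule(self):
        fib = toy_fiber("regular", 40, spacing=10)
        red = FactorSpecies(color="red", count=2, affinity={"pink": 8.0},
                            activation_time=100.0)
        green = FactorSpecies(color="green", count=2, affinity={},
                              activation_time=0.0)
        cfg = SimulationConfig(
            fibers=[fib], species=[red, green], box_edge=20.0, run_time=0.0,
            seed=1,
            schedule=[AffinityEvent(time=200.0, species_color="green",
                                    bead_color="pink", epsilon=12.0)],
        )
        sys_ = System(cfg)
        pink = fib.beads_with_color("pink")
        eps0 = sys_.current_eps(50.0)
        assert eps0.sum() == 0.0  # nothing active yet
        eps1 = sys_.current_eps(150.0)
        assert (eps1[0, pink] == 8.0).all() and eps1[1].sum() == 0.0
        eps2 = sys_.current_eps(250.0)
        assert (eps2[1, pink] == 12.0).all()  # switched-on stronger binding

    def test_negative_event_time_rejected(self):
        with pytest.raises(ValueError):
            AffinityEvent(time=-1.0, species_color="red", bead_color="pink",
                          epsilon=1.0)

    def test_bond_overstretch_diagnostics(self):
        fib = FiberSpec(colors=(frozenset({"blue"}),) * 3)
        cfg = SimulationConfig(fibers=[fib], species=[], box_edge=20.0,
                               run_time=0.0, seed=1)
        sys_ = System(cfg)
        pos = np.array([[5.0, 5, 5], [6.59, 5, 5], [8.2, 5, 5]])
        st = SystemState(time=0.0, positions=pos,
                         velocities=np.zeros_like(pos), box_edge=20.0,
                         n_beads=3)
        with pytest.raises(BondOverstretchError) as err:
            sys_._integrate(st, n_steps=1, dt=1e-3, kT=0.0,
                            integrator=K.INTEGRATOR_EM,
                            eps_fb=np.zeros((1, 3)), fcap=0.0,
                            sample_stride=0, frames=None, step_offset=0)
        assert err.value.bond == (1, 2)


class TestPermanentLoops:
    def test_fig3d_anchor_pattern(self):
        anchors = loop_anchor_pairs(5000, loop_beads=324, gap_beads=300,
                                    end_gap=150)
        assert anchors[0] == (150, 473)
        assert anchors[1] == (774, 1097)
        # loops fit between the 150-bead end gaps
        assert all(a >= 150 and b <= 4850 for a, b in anchors)
        spans = [b - a + 1 for a, b in anchors]
        assert set(spans) == {324}

    def test_loops_become_fene_bonds_in_engine(self):
        fib = apply_permanent_loops(toy_fiber("regular", 100), [(10, 60)])
        cfg = SimulationConfig(fibers=[fib], species=[], box_edge=30.0,
                               run_time=0.0, seed=1)
        sys_ = System(cfg)
        assert sys_.bonds.shape[0] == 100  # 99 backbone + 1 loop
        assert [10, 60] in sys_.bonds.tolist()

    def test_duplicate_anchor_pair_is_idempotent(self):
        fib = toy_fiber("regular", 100)
        once = apply_permanent_loops(fib, [(10, 60)])
        twice = apply_permanent_loops(once, [(60, 10), (10, 60)])
        assert once.loop_bonds == twice.loop_bonds

    def test_adjacent_anchors_rejected(self):
        with pytest.raises(ValueError):
            apply_permanent_loops(toy_fiber("regular", 100), [(10, 11)])

    def test_empty_anchor_list_is_identity(self):
        fib = toy_fiber("regular", 100)
        assert apply_permanent_loops(fib, []).colors == fib.colors


def test_trajectory_roundtrip(tmp_path):
    fib = toy_fiber("regular", 50, spacing=10)
    sp = FactorSpecies(color="red", count=3, affinity={"pink": 8.0},
                       activation_time=50.0)
    cfg = SimulationConfig(fibers=[fib], species=[sp], box_edge=20.0,
                           run_time=200.0, seed=2, sample_interval=50.0)
    traj = run_protocol(cfg)
    path = str(tmp_path / "t.h5")
    traj.save(path)
    back = Trajectory.load(path)
    np.testing.assert_array_equal(back.positions, traj.positions)
    assert back.species_slices == traj.species_slices
    assert back.metadata["seed"] == 2
    xyz = tmp_path / "last.xyz"
    traj.export_xyz(str(xyz))
    assert xyz.read_text().startswith("53\n")
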